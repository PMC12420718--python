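"""Independent brute-force classifier used as an oracle in tests.

Written as direct inequality chains, deliberately separate from the
production band logic in descorecard.classify.
"""

from __future__ import annotations

from typing import Optional


def brute_force_classify(
    x: float, y: float, t_low: float, t_high: float, mode: str = "full"
) -> tuple[Optional[str], Optional[str]]:
    """Return (quadrant, region letter) or (None, None) if not reported."""
    ax, ay = abs(x), abs(y)

    # quadrant by signs, zero counting as positive
    if x >= 0 and y >= 0:
        q = "Q1"
    elif x < 0 and y >= 0:
        q = "Q2"
    elif x < 0 and y < 0:
        q = "Q3"
    else:
        q = "Q4"

    if ax < t_low and ay < t_low:
        return (None, None)
    if mode == "fourway":
        return (q, None)

    if ax >= t_high and ay >= t_high:
        r = "A"
    elif ax >= t_high and t_low <= ay < t_high:
        r = "C"
    elif t_low <= ax < t_high and ay >= t_high:
        r = "B"
    elif ax >= t_high and ay < t_low:
        r = "D"
    elif ax < t_low and ay >= t_high:
        r = "E"
    elif t_low <= ax < t_high and t_low <= ay < t_high:
        r = "M"
    elif t_low <= ax < t_high and ay < t_low:
        r = "S"
    elif ax < t_low and t_low <= ay < t_high:
        r = "R"
    else:  # pragma: no cover - the cases above are exhaustive
        raise AssertionError(f"unclassifiable point ({x}, {y})")

    if mode == "standard" and r in ("M", "S", "R"):
        return (None, None)
    return (q, r)
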