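import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from descorecard import (
    FixtureSpec,
    ScorecardCollection,
    ScorecardConfig,
    build_scorecard,
    enumerate_scorecard_pairs,
    generate_fixture,
)


@pytest.fixture(scope="session")
def full_config():
    return ScorecardConfig(t_low=2.0, t_high=3.0, alpha=0.05, mode="full")


@pytest.fixture(scope="session")
def planted_fixture():
    """Small planted study: 4 comparisons, 2 genes per cell per pair,
    3 recurrent genes, 200 noise genes."""
    spec = FixtureSpec(
        n_comparisons=4, genes_per_cell=2, noise_genes=200,
        recurrent_genes=3, t_low=2.0, t_high=3.0, alpha=0.05, seed=7,
    )
    return spec, generate_fixture(spec)


@pytest.fixture(scope="session")
def planted_collection(planted_fixture, full_config):
    _, result = planted_fixture
    scorecards = [
        build_scorecard(a, b, full_config)
        for a, b in enumerate_scorecard_pairs(result.comparisons)
    ]
    return ScorecardCollection(scorecards, study_label="planted")
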