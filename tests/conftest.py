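import pytest

from phageweapons import (
    CommunityParams,
    CompetitionSetup,
    LifeHistoryTraits,
    NutrientParams,
    load_preset,
    run_competition_pair,
)

#: Baseline ("fixed") life-history traits used throughout the tests.
FIXED = dict(pi=0.5, kappa=1e-4, lam=0.505, alpha=1e-8, delta=0.05, beta=100.0)


@pytest.fixture(scope="session")
def fixed_traits() -> LifeHistoryTraits:
    return LifeHistoryTraits(**FIXED)


@pytest.fixture(scope="session")
def phi2_traits() -> LifeHistoryTraits:
    return load_preset("phi2")["traits"]


@pytest.fixture(scope="session")
def phi4_traits() -> LifeHistoryTraits:
    return load_preset("phi4")["traits"]


@pytest.fixture(scope="session")
def community() -> CommunityParams:
    return CommunityParams(r=0.9, mu=-4e-10)


@pytest.fixture(scope="session")
def nutrient() -> NutrientParams:
    return NutrientParams()


@pytest.fixture(scope="session")
def pair_fixed_01(fixed_traits, community):
    """One baseline competition pair at f0 = 0.1, shared across tests."""
    setup = CompetitionSetup(focal_fraction=0.1)
    return run_competition_pair(setup, fixed_traits, community)
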