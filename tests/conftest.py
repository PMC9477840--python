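import numpy as np
import pytest

from saomnet import (
    ActorCovariate,
    DirectedNetwork,
    DyadCovariate,
    HouseholdAssignment,
    VillageData,
)


def make_random_village(n: int, seed: int = 0) -> VillageData:
    """A village with arbitrary (already-standardised) covariates for
    exercising the effects machinery on small random instances."""
    rng = np.random.default_rng(seed)
    labels = [f"a{i}" for i in range(n)]
    hh = HouseholdAssignment(rng.integers(0, max(2, n // 3), n))
    acov = {}
    for name in ("age", "melanin", "bmi", "household_size", "household_wealth"):
        acov[name] = ActorCovariate(name, rng.normal(size=n), "zscore")
    acov["gender"] = ActorCovariate("gender", rng.integers(0, 2, n).astype(float))
    acov["ethnicity"] = ActorCovariate("ethnicity", rng.integers(0, 2, n).astype(float))
    dcov = {}
    for name in ("consanguineal", "affinal", "distance", "godparent", "infidelity"):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dcov[name] = DyadCovariate(name, m, symmetric=True)
    rr = rng.normal(size=(n, n))
    dcov["relative_wealth_rank"] = DyadCovariate("relative_wealth_rank", rr - rr.T)
    return VillageData(None, None, None, acov, dcov, hh, set(), labels)


def random_net(n: int, rng: np.random.Generator, p: float | None = None) -> DirectedNetwork:
    p = rng.uniform(0.15, 0.7) if p is None else p
    x = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(x, 0)
    return DirectedNetwork(x)


@pytest.fixture(scope="session")
def village8():
    return make_random_village(8, seed=3)


@pytest.fixture(scope="session")
def synthetic_village40():
    """One noise-free synthetic village with its generating model."""
    from saomnet import VillageRecipe, generate_village

    recipe = VillageRecipe(n=40, households=12, burnin_rate=150.0,
                           noise_false_negative=0.0, noise_false_positive=0.0)
    return generate_village(recipe, seed=3)
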