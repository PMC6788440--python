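import numpy as np
import pandas as pd
import pytest

import elevdiv as ed
from elevdiv.datasets import toy_survey


@pytest.fixture(scope="session")
def toy_ds():
    return toy_survey()


@pytest.fixture(scope="session")
def preset_sim():
    """One paper-like synthetic survey shared across tests (fixed seed)."""
    cfg = ed.paperlike_preset()
    ds, truth = ed.simulate_survey(cfg, seed=11)
    return cfg, ds, truth


def random_incidence(rng, n_sites=6, n_species=15, p=0.45) -> pd.DataFrame:
    """Random presence/absence table with no empty sites or species."""
    x = rng.uniform(size=(n_sites, n_species)) < p
    for j in np.flatnonzero(~x.any(axis=0)):  # give empty species one site
        x[rng.integers(n_sites), j] = True
    for i in np.flatnonzero(~x.any(axis=1)):  # give empty sites one species
        x[i, rng.integers(n_species)] = True
    idx = pd.MultiIndex.from_tuples(
        [("M", f"s{i}") for i in range(n_sites)], names=["mountain", "location"]
    )
    return pd.DataFrame(x, index=idx, columns=[f"sp{j}" for j in range(n_species)])


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
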