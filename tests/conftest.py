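"""Shared fixtures: small synthetic proteomes and noise-free experiments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import heatsol as hs

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_proteome():
    """200-protein proteome with default study conditions."""
    return hs.generate_proteome(hs.GeneratorParams(n_proteins=200), seed=7)


@pytest.fixture(scope="session")
def big_proteome():
    """2,000-protein proteome for distribution-level checks."""
    return hs.generate_proteome(hs.GeneratorParams(n_proteins=2000), seed=7)


@pytest.fixture(scope="session")
def noisefree_course(small_proteome):
    return hs.simulate_solubility_course(
        small_proteome, noise=hs.NoiseParams.none(), seed=11)


def profiles_from_matrix(values: np.ndarray,
                         timepoints=(0.0, 1.0, 2.0, 3.0, 5.0),
                         ids=None) -> hs.SolubilityProfiles:
    """Build SolubilityProfiles from a (protein, time, replicate) array."""
    values = np.asarray(values, dtype=float)
    n, n_t, n_r = values.shape
    ids = ids if ids is not None else [f"P{i}" for i in range(n)]
    cols = pd.MultiIndex.from_product(
        [list(timepoints)[:n_t], range(1, n_r + 1)],
        names=["time_h", "replicate"])
    s = pd.DataFrame(values.reshape(n, n_t * n_r),
                     index=pd.Index(ids, name="protein_id"), columns=cols)
    mean_s = s.T.groupby(level="time_h").mean().T
    return hs.SolubilityProfiles(s=s, mean_s=mean_s)
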