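import logging

import numpy as np
import pytest

import elevpart as ep

logging.getLogger("elevpart").setLevel(logging.ERROR)


@pytest.fixture()
def toy_occ():
    """5 sites x 4 species with assorted range extents."""
    inc = np.array(
        [
            [1, 0, 0, 1],
            [1, 1, 0, 0],
            [0, 1, 0, 1],
            [0, 0, 1, 0],
            [1, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return ep.OccurrenceMatrix(
        sites=[f"s{i}" for i in range(5)],
        species=[f"sp{j}" for j in range(4)],
        incidence=inc,
        elevations=np.array([100.0, 200.0, 300.0, 400.0, 500.0]),
    )


@pytest.fixture(scope="session")
def study_like():
    """One study-scale synthetic dataset (73 sites, 191 species), MDE-true."""
    truth = ep.study_like_preset(seed=42)
    occ, cov, specimens, truth = ep.generate(truth)
    return occ, cov, specimens, truth


def random_occurrence(rng, n_sites, n_species):
    """Random valid incidence matrix (each species gets >= 1 presence)."""
    inc = (rng.random((n_sites, n_species)) < 0.3).astype(np.int8)
    for j in range(n_species):
        if inc[:, j].sum() == 0:
            inc[rng.integers(n_sites), j] = 1
    return ep.OccurrenceMatrix(
        sites=[f"s{i}" for i in range(n_sites)],
        species=[f"sp{j}" for j in range(n_species)],
        incidence=inc,
        elevations=np.arange(n_sites, dtype=float) * 19.0 + 923.0,
    )
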