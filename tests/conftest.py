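import numpy as np
import pytest
from hypothesis import settings

from cysred.synthetic import NoiseModel, TruthTable, enumerate_analytes
from cysred.topology import build_disulfide_map, example_igg1

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mab():
    return example_igg1()


@pytest.fixture(scope="session")
def bond_map(mab):
    return build_disulfide_map(mab)


@pytest.fixture(scope="session")
def analytes(mab):
    return enumerate_analytes(mab)


@pytest.fixture(scope="session")
def truth(analytes):
    return TruthTable.from_classes(analytes)


@pytest.fixture()
def no_noise():
    return NoiseModel(area_cv=0.0, ppm_jitter_sd=0.0, idotp_range=(1.0, 1.0))


def mc_sasa_oracle(coords, radii, probe, n_samples=100_000, seed=0):
    """Monte-Carlo rejection SASA oracle, independent of the implementation.

    For each atom, sample points uniformly on its expanded sphere and count
    the fraction not inside any other atom's expanded sphere.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        free = np.ones(n_samples, bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * free.mean()
    return out
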