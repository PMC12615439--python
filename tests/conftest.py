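import numpy as np
import pytest

from mpmcollagen import (
    AcquisitionMeta,
    PhantomSpec,
    WavelengthGrid,
)


@pytest.fixture(scope="session")
def default_grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def default_meta() -> AcquisitionMeta:
    return AcquisitionMeta()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """A fast 128x128 phantom used by most image-pipeline tests."""
    return PhantomSpec(height=128, width=128, n_fibers=20, n_cells=8, seed=11)


def brute_force_otsu(img: np.ndarray, bins: int = 256) -> float:
    """Independent oracle: exhaustive between-class-variance maximization.

    Loops over every interior histogram bin edge whose left neighbor bin is
    nonempty (edges inside empty runs repeat the partition of the run's first
    edge), computes the two class weights and means directly, and returns the
    first edge attaining the maximal between-class variance.
    """
    img = np.asarray(img, dtype=float).ravel()
    counts, edges = np.histogram(img, bins=bins, range=(img.min(), img.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_edge = -np.inf, None
    for i in range(1, bins):
        n0, n1 = counts[:i].sum(), counts[i:].sum()
        if counts[i - 1] == 0 or n1 == 0:
            continue
        w0 = n0 / counts.sum()
        w1 = n1 / counts.sum()
        mu0 = (counts[:i] * centers[:i]).sum() / n0
        mu1 = (counts[i:] * centers[i:]).sum() / n1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_edge = var, edges[i]
    return float(best_edge)
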