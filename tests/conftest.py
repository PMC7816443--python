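import numpy as np
import pytest

from dtisurf import dataio, surf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_grid():
    """40x40 grid with one Gaussian blob (spatial std 2.5) at (20, 17)."""
    rows, cols = np.mgrid[0:40, 0:40]
    return np.exp(-((rows - 20) ** 2 + (cols - 17) ** 2) / (2 * 2.5**2)), (20, 17)


@pytest.fixture
def padded_blob(blob_grid):
    """Reflection-padded blob grid with its integral image."""
    grid, center = blob_grid
    pad = 30
    padded = np.pad(grid, pad, mode="reflect")
    return surf.integral_image(padded), pad, center


def make_pssm(scores, protein_id="P1"):
    return dataio.PSSM(protein_id=protein_id, scores=np.asarray(scores, dtype=float))


@pytest.fixture
def tiny_network():
    return dataio.InteractionNetwork(
        drugs=("d1", "d2"),
        targets=("t1", "t2"),
        positive_edges=frozenset({("d1", "t1"), ("d1", "t2"), ("d2", "t1")}),
    )
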