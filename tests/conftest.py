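import numpy as np
import pytest

from knpemi.fem_engine import build_structured_mesh

UM = 1e-6


@pytest.fixture(scope="session")
def model_a_mesh():
    """Model A geometry (60x60 um box, one axon) at 2 um resolution."""
    return build_structured_mesh(
        (60 * UM, 60 * UM), (2 * UM, 2 * UM),
        [((6 * UM, 56 * UM), (28 * UM, 34 * UM))],
    )


@pytest.fixture(scope="session")
def small_cell_mesh():
    """Small 20x20 um box with one centered 8x4 um cell at 1 um resolution."""
    return build_structured_mesh(
        (20 * UM, 20 * UM), (1 * UM, 1 * UM),
        [((6 * UM, 14 * UM), (8 * UM, 12 * UM))],
    )


@pytest.fixture(scope="session")
def tiny_cell_mesh():
    """Coarse 6x6 box with a 2x2 cell: 72 triangles, cheap oracle comparisons."""
    return build_structured_mesh(
        (6.0, 6.0), (1.0, 1.0), [((2.0, 4.0), (2.0, 4.0))]
    )


@pytest.fixture(scope="session")
def plain_square_mesh():
    """Unit square, 32x32, no cells (for quadrature/norm checks)."""
    return build_structured_mesh((1.0, 1.0), (1.0 / 32, 1.0 / 32))
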