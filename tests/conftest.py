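import numpy as np
import pytest

from subtray import TrayGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def default_geometry():
    return TrayGeometry()


@pytest.fixture(scope="session")
def tiny_geometry():
    """Four complete cells, no edge region: exhaustively enumerable."""
    return TrayGeometry(inner_diameter=8.0, cell_side=2.0,
                        n_complete_cells=4, equivalent_cells=4.0)
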