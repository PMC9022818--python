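import numpy as np
import pytest

from fcdyn import (
    BinaryNetwork,
    SimSpec,
    TaskDesign,
    WindowSpec,
    simulate_roi_timeseries,
    sliding_window_fc,
)


@pytest.fixture(scope="session")
def block_design() -> TaskDesign:
    """The canonical 5x30s task / 5x30s rest design at TR = 1 s."""
    return TaskDesign(condition=(0, 1) * 5, durations=(30,) * 10, tr=1.0)


@pytest.fixture(scope="session")
def block_fc(block_design):
    """A windowed FC series for one simulated subject of that design."""
    ts = simulate_roi_timeseries(SimSpec(design=block_design, seed=42))
    return sliding_window_fc(ts, WindowSpec(window_size=17, step_size=1))


def graph(edges, n) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adjacency=adj)


@pytest.fixture
def k4():
    return graph([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], 4)


@pytest.fixture
def star4():
    """4-node star: node 0 is the centre."""
    return graph([(0, 1), (0, 2), (0, 3)], 4)


@pytest.fixture
def triangle():
    return graph([(0, 1), (1, 2), (0, 2)], 3)


@pytest.fixture
def two_triangles():
    return graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)
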