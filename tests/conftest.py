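import numpy as np
import pytest

from dfftcourt import CourtGrid, Frame, calibrate_discretization


@pytest.fixture(scope="session")
def grid():
    return CourtGrid()


@pytest.fixture(scope="session")
def rule(grid):
    return calibrate_discretization(grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_frame(rng, grid, play_id=0, t_to_shot=0.0, outcome=0, margin=1.0):
    """A valid frame with all agents uniform inside the grid."""
    def pts(k):
        return np.column_stack([
            rng.uniform(grid.x_min + margin, grid.x_max - margin, k),
            rng.uniform(grid.y_min + margin, grid.y_max - margin, k)])
    return Frame(play_id=play_id, t_to_shot=t_to_shot, offense=pts(5),
                 defense=pts(5), ball=pts(1)[0], outcome=outcome)


@pytest.fixture()
def make_frame(rng, grid):
    def _make(**kw):
        return random_frame(rng, grid, **kw)
    return _make
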