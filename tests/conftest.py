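import numpy as np
import pytest

from sinupath import TrajectoryPath


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_345():
    """Two-segment right-angle path with total length 7 and displacement 5."""
    return TrajectoryPath.from_xy("p345", [0, 3, 3], [0, 0, 4])


def make_crw(rng, n_steps, sigma, step=1.0, traj_id="crw", family="wrapped_normal"):
    """Constant-step correlated random walk with i.i.d. turning angles."""
    if family == "wrapped_normal":
        angles = rng.normal(0.0, sigma, n_steps)
    else:
        angles = rng.vonmises(0.0, sigma, n_steps)
    headings = np.cumsum(angles)
    x = np.concatenate([[0.0], np.cumsum(step * np.cos(headings))])
    y = np.concatenate([[0.0], np.cumsum(step * np.sin(headings))])
    return TrajectoryPath.from_xy(traj_id, x, y)


def alternating_path(n_steps=20, step=1.0):
    """Constant-step path turning +90/-90 alternately: c = 0, b = 0."""
    # headings alternate between 0 and +90 degrees
    headings = np.where(np.arange(n_steps) % 2 == 0, 0.0, np.pi / 2)
    x = np.concatenate([[0.0], np.cumsum(step * np.cos(headings))])
    y = np.concatenate([[0.0], np.cumsum(step * np.sin(headings))])
    return TrajectoryPath.from_xy("alt", x, y)
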