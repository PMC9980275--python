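import pytest

from laplacemem import RhoGrid, make_s_grid
from laplacemem.experiment import ExperimentConfig, run_experiment
from laplacemem.demos import stream_for


@pytest.fixture(scope="session")
def grid64():
    """Default grid: smax = 1/dt = 10, smin = 0.01, 64 points (s=1 at n=21)."""
    return make_s_grid(0.01, 10.0, 64)


@pytest.fixture(scope="session")
def s1_index():
    """Index of the exact s = 1 grid point on grid64."""
    return 21


@pytest.fixture(scope="session")
def alphabet():
    return ("x", "y")


def train(spec_or_sched, rho, grid=None, **cfg_kwargs):
    """Run a schedule through the experiment driver and return the result."""
    cfg = ExperimentConfig(
        grid=grid if grid is not None else make_s_grid(0.01, 10.0, 64),
        rho=rho if isinstance(rho, RhoGrid) else RhoGrid.single(rho),
        track_future=cfg_kwargs.pop("track_future", False),
        **cfg_kwargs)
    return run_experiment(stream_for(spec_or_sched), cfg)


@pytest.fixture(scope="session")
def trainer():
    return train
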