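import numpy as np
import pytest

from drynet.preprocess import TimeCourseMatrix, hermite_interpolate


@pytest.fixture
def times5():
    return np.array([0.0, 6.0, 12.0, 24.0, 48.0])


@pytest.fixture
def toy_expr(times5):
    """Six-gene toy matrix exercising floor/fold-change edge cases."""
    values = np.array(
        [
            [2.0, 3.0, 4.0, 5.0, 6.0],      # below floor
            [10.0, 2.0, 2.0, 2.0, 2.0],     # boundary: max = zeta, fold = 5
            [100.0, 90.0, 95.0, 92.0, 98.0],  # high but flat
            [50.0, 10.0, 4.0, 2.0, 1.0],    # strong decay
            [1.0, 2.0, 30.0, 2.0, 1.0],     # pulse
            [8.0, 8.0, 8.0, 8.0, 8.0],      # constant below floor
        ]
    )
    return TimeCourseMatrix([f"g{i}" for i in range(6)], times5, values)


@pytest.fixture
def two_gene_traj(times5):
    """Noiseless trajectories where dX1/dt = 0.8*x2 - 0.1 by construction."""
    t = np.linspace(0, 48, 200)
    x2 = 5.0 + 3.0 * np.sin(t / 8.0) + 0.05 * t
    # x1 via cumulative integration of 0.8*x2 - 0.1
    dt = np.diff(t)
    x1 = np.concatenate([[10.0], 10.0 + np.cumsum((0.8 * x2[:-1] - 0.1) * dt)])
    from drynet.preprocess import DenseTrajectories

    return DenseTrajectories(["g1", "g2"], t, np.vstack([x1, x2]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
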