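import numpy as np
import pandas as pd
import pytest

from killitox import MovementHMMParams


@pytest.fixture(scope="session")
def three_state_params() -> MovementHMMParams:
    """Well-separated 3-state movement parameters used across HMM tests."""
    return MovementHMMParams(
        transition_matrix=[[0.90, 0.08, 0.02], [0.10, 0.80, 0.10], [0.05, 0.15, 0.80]],
        step_params=[[0.2, 0.1], [1.0, 0.4], [3.0, 1.0]],
        angle_params=[[0.0, 0.5], [0.0, 2.0], [0.0, 8.0]],
    )


@pytest.fixture
def square_path() -> pd.DataFrame:
    """Unit-square traversal: four 90-degree left turns."""
    xs = [0, 1, 1, 0, 0]
    ys = [0, 0, 1, 1, 0]
    return pd.DataFrame(
        {"larva_id": "L1", "t_s": np.arange(5.0), "x_mm": xs, "y_mm": ys}
    )


def make_traj(x, y, dt=1.0, larva="L1"):
    x = np.asarray(x, dtype=float)
    return pd.DataFrame(
        {"larva_id": larva, "t_s": np.arange(len(x)) * dt, "x_mm": x, "y_mm": np.asarray(y, float)}
    )
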