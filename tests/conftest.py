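import numpy as np
import pytest

from woundkinetics import (
    FKParameters,
    Grid1D,
    RenderConfig,
    make_scratch_initial_condition,
    render_timelapse,
    simulate_fk_1d,
)
from woundkinetics.kinetics import LN2


@pytest.fixture(scope="session")
def study_params():
    """Control-condition FK parameters of the default synthetic protocol."""
    return FKParameters(D=600.0, k=LN2 / 24.0, u_hat=1.2e-3, b=1200.0)


@pytest.fixture(scope="session")
def study_grid():
    return Grid1D(x_min=0.0, x_max=4000.0, n_nodes=801, dt=0.005, t_end=18.0)


@pytest.fixture(scope="session")
def closing_field(study_params, study_grid):
    """Simulated density field of a closing wound, 73 frames at 15 min."""
    init = make_scratch_initial_condition(study_params, study_grid)
    return simulate_fk_1d(
        init, study_params, study_grid, save_times=np.arange(0.0, 18.01, 0.25)
    )


@pytest.fixture(scope="session")
def closing_stack(closing_field, study_params):
    """Rendered time-lapse of the closing wound plus ground-truth masks."""
    cfg = RenderConfig(pixel_size=5.0, frame_shape=(200, 800), seed=42)
    stack, gt_masks = render_timelapse(closing_field, cfg, u_hat=study_params.u_hat)
    return stack, gt_masks
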