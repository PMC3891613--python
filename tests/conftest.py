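import numpy as np
import pytest

from ehgcv import SimScenario, generate_grid_recording


@pytest.fixture(scope="session")
def noiseless_recording():
    """One noiseless contraction at 10 cm/s straight down the grid
    (theta=0), so inter-row delays are exactly 0.05 s (10 samples)."""
    scenario = SimScenario(
        duration_s=120.0,
        contraction_schedule=((40.0, 40.0),),
        true_cv_cm_s=(10.0,),
        true_angle_rad=(0.0,),
        snr_db=np.inf,
        rng_seed=0,
    )
    return generate_grid_recording(scenario)


@pytest.fixture(scope="session")
def three_contraction_recording():
    """Noisy 2x2-grid recording with three scheduled contractions; small
    grid because only the bipolar channel matters for detection tests."""
    scenario = SimScenario(
        n_rows=2,
        n_cols=2,
        duration_s=380.0,
        contraction_schedule=((50.0, 40.0), (170.0, 40.0), (290.0, 40.0)),
        true_cv_cm_s=(8.0, 8.5, 9.0),
        true_angle_rad=(0.0, 0.5, -0.5),
        snr_db=10.0,
        rng_seed=1,
    )
    return generate_grid_recording(scenario)
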