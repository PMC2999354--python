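import numpy as np
import pytest

from fatseg import FitConfig, generate_stack
from fatseg.calibrate import (
    NoiseSweepConfig,
    corner_background_mask,
    fit_calibration_curve,
    run_noise_sweep,
)
from fatseg.io_formats import AcquisitionDescriptor
from fatseg.synthdata import lard_phantom_config, lard_signal_roi


@pytest.fixture
def descriptor():
    return AcquisitionDescriptor(te_spacing=8.3, n_echoes=10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lard_stack():
    """Noiseless 64x64 homogeneous lard phantom (T2 = 55 ms, S0 = 1000)."""
    stack, labels, _ = generate_stack(lard_phantom_config(64))
    return stack, labels


@pytest.fixture(scope="session")
def calibration_curve(lard_stack):
    """Calibration curve from a 60-trial sweep on the lard phantom."""
    stack, _ = lard_stack
    sweep = NoiseSweepConfig(n_trials=60, rng_seed=11)
    table = run_noise_sweep(
        stack,
        lard_signal_roi(64),
        corner_background_mask((64, 64)),
        FitConfig(method="wls"),
        sweep,
    )
    return fit_calibration_curve(table, sweep)
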