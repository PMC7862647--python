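"""Shared simulated datasets.

All fixtures are session-scoped, seed-fixed simulations kept short enough
for a routine test run; statistical assertions downstream are calibrated to
these problem sizes.
"""

import numpy as np
import pytest

from spadffs import (
    FfsSimConfig,
    calibrate_waists,
    simulate_dark,
    simulate_ffs,
)


@pytest.fixture(scope="session")
def trace_d30():
    """10 s free-diffusion measurement at D = 30.6 um^2/s, 2 us bins,
    no detector artefacts (shot noise only)."""
    cfg = FfsSimConfig(
        D=30.6, duration=10.0, bin_width=2e-6, sim_substep=2e-6,
        dcr=0.0, hot_pixel_dcr=0.0, p_afterpulse=0.0, seed=101,
    )
    return simulate_ffs(cfg)


@pytest.fixture(scope="session")
def trace_d90():
    """10 s fast-diffusion reference (D = 90 um^2/s), 5 us bins."""
    cfg = FfsSimConfig(
        D=90.0, duration=10.0, bin_width=5e-6, sim_substep=1e-6,
        dcr=0.0, hot_pixel_dcr=0.0, p_afterpulse=0.0, seed=202,
    )
    return simulate_ffs(cfg)


@pytest.fixture(scope="session")
def trace_afterpulsing():
    """10 s measurement with dark counts, a hot pixel and after-pulsing."""
    cfg = FfsSimConfig(
        D=30.6, duration=10.0, bin_width=2e-6, sim_substep=2e-6,
        dcr=200.0, hot_pixel_dcr=2.5e4, p_afterpulse=0.05,
        ap_delay_range=(2e-6, 1e-2), seed=303,
    )
    return simulate_ffs(cfg)


@pytest.fixture(scope="session")
def dark_trace():
    """20 s dark trace: 5 kHz uniform background with after-pulsing."""
    cfg = FfsSimConfig(
        D=0.0, n_particles=0, brightness=0.0, duration=20.0, bin_width=1e-6,
        dcr=5e3, hot_pixel_dcr=5e3, p_afterpulse=0.05,
        ap_exponent=1.103, ap_delay_range=(1e-6, 1e-2), seed=404,
    )
    return simulate_dark(cfg)


@pytest.fixture(scope="session")
def calibration_d90(trace_d90):
    """Waist calibration from the fast-diffusion reference measurement."""
    return calibrate_waists(trace_d90, D_reference=90.0, chunk_length=2.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
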