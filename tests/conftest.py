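"""Shared fixtures: synthetic records generated once per session."""

import numpy as np
import pytest

import csfdyn as cd

# Spinal (C2-C3) free-breathing modulations: depth % and phase lag (deg)
# for cardiac period, flow amplitude and net flow.
C2C3_DEPTHS = {"tc": 6.0, "amplitude": 6.8, "qnet": 6.3}
C2C3_LAGS = {"tc": -64.0, "amplitude": -11.0, "qnet": 33.0}


@pytest.fixture(scope="session")
def quiet_record():
    """Zero-modulation, noiseless 45 s record (exactly periodic beats)."""
    cfg = cd.SimulationConfig(seed=0, noise_sd=0.0)
    flow, belt, truth = cd.generate_flow_record(cfg)
    return cfg, flow, belt, truth


@pytest.fixture(scope="session")
def modulated_record():
    """Noiseless record with the spinal-level joint modulations injected."""
    cfg = cd.SimulationConfig(
        seed=0,
        noise_sd=0.0,
        modulation_depth_percent=dict(C2C3_DEPTHS),
        phase_lag_deg=dict(C2C3_LAGS),
    )
    flow, belt, truth = cd.generate_flow_record(cfg)
    return cfg, flow, belt, truth


@pytest.fixture(scope="session")
def rendered_series(quiet_record):
    """Velocity maps of the quiet record with offset and mild noise."""
    _, flow, _, _ = quiet_record
    img = cd.ImageRenderConfig(background_offset=0.3,
                               stationary_tissue_noise_sd=0.05)
    return img, flow, cd.render_velocity_series(flow, img, seed=7)
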