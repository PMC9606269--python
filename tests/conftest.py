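import numpy as np
import pytest
from hypothesis import settings

from smbleach.simulate import SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def noiseless_cfg():
    """Small noiseless configuration for exactness-style tests."""
    return SimulationConfig(
        true_fractions=(0.5, 0.5, 0.0, 0.0, 0.0),
        n_particles=20,
        image_shape=(64, 64),
        shot_noise=False,
        read_noise_sd=0.0,
        n_frames=100,
        mean_bleach_time=30.0,
        min_separation=8.0,
        seed=11,
    )


def trace_cfg(snr: float | None, n_frames: int = 1000, mean_bleach_time: float = 100.0,
              **kwargs) -> SimulationConfig:
    """Trace-level config at a given per-frame signal-to-noise ratio.

    SNR is defined as unit step height over per-frame noise sd; shot noise is
    disabled so the ratio is exact. ``snr=None`` means noiseless.
    """
    unit = 100.0
    read = 0.0 if snr is None else unit / snr
    return SimulationConfig(
        true_fractions=(1.0, 0.0, 0.0, 0.0, 0.0),
        n_particles=1,
        unit_intensity=unit,
        background_level=0.0,
        shot_noise=False,
        read_noise_sd=read,
        n_frames=n_frames,
        mean_bleach_time=mean_bleach_time,
        **kwargs,
    )


def render_spot(shape=(32, 32), row=16.0, col=16.0, amp=500.0, bg=100.0, sigma=1.3):
    """Directly evaluate one Gaussian spot on a flat background (test oracle)."""
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    return bg + amp * np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))
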