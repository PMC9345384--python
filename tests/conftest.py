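import numpy as np
import pytest
from hypothesis import settings

import rgxlf as rx

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg():
    return rx.PhantomConfig()


@pytest.fixture(scope="session")
def default_series(default_cfg):
    """One full default rotational acquisition (1028 frames, 720 deg, 34 s)."""
    return rx.generate_acquisition(
        default_cfg, rx.AcquisitionConfig(seed=11), rx.BreathingParams()
    )


@pytest.fixture(scope="session")
def default_trace(default_cfg, default_series):
    roi = rx.ROI(*rx.interface_roi(default_cfg))
    return rx.compute_breathing_trace(default_series, roi)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale phantom for cheap geometry tests."""
    return rx.PhantomConfig(
        body=rx.Ellipse(0.0, 0.0, 3.6, 3.2),
        lung_regions=(
            rx.Region(rx.Ellipse(-1.6, -0.3, 1.2, 1.6), 0.008),
            rx.Region(rx.Ellipse(1.6, -0.3, 1.2, 1.6), 0.008),
        ),
        cardiac_region=rx.Ellipse(0.25, 0.4, 1.0, 1.2),
        bone_region=rx.Ellipse(0.0, 2.4, 0.35, 0.35),
        grid_size=96,
        pixel_size=0.1,
    )


def synthetic_trace(values, times=None, valid=None):
    """Wrap a plain array as a BreathingTrace (normalized over valid range)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if times is None:
        times = np.arange(n, dtype=float)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    v = values[valid]
    span = v.max() - v.min()
    normalized = np.zeros(n)
    normalized[valid] = (values[valid] - v.min()) / (span if span else 1.0)
    return rx.BreathingTrace(
        raw=values.copy(),
        background=np.zeros(n),
        corrected=values.copy(),
        normalized=normalized,
        valid_mask=np.asarray(valid, dtype=bool),
        sampling_rate=1.0 / float(np.median(np.diff(times))),
        angles=np.zeros(n),
        times=np.asarray(times, dtype=float),
    )
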