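import numpy as np
import pytest

import vesselflow as vf


@pytest.fixture(scope="session")
def calibration():
    """The recording calibration: 0.34 um/pixel at 2000 frames/s."""
    return vf.Calibration(pixel_size=0.34, frame_rate=2000.0)


@pytest.fixture(scope="session")
def parabolic_scene():
    """Default parabolic-flow fixture: 25 um vessel, k=2, jitter 100-140."""
    spec = vf.fixture_specs()["parabolic_default"]
    video, truth = vf.render_scene(spec)
    return spec, video, truth


@pytest.fixture(scope="session")
def static_scene():
    spec = vf.fixture_specs()["static"]
    video, truth = vf.render_scene(spec)
    return spec, video, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def textured_frames(n_frames, shape=(64, 64), seed=0, dtype=np.uint8):
    """A static textured stack (all frames identical)."""
    r = np.random.default_rng(seed)
    frame = r.integers(0, 200, size=shape).astype(dtype)
    return np.repeat(frame[None], n_frames, axis=0)


def band_mask(shape, diameter_px, angle_deg=0.0, center=None):
    """Analytic straight-band mask at the package's angle convention.

    Orientation is CCW from horizontal as displayed (row axis down): the
    band's normal direction is (cos t, sin t) in (row, col).
    """
    h, w = shape
    t = np.deg2rad(angle_deg)
    sin_t, cos_t = np.sin(t), np.cos(t)
    # snap float dust at exact right angles (cos 90 deg = 6e-17 would
    # stagger the wall by one pixel depending on the row)
    sin_t = 0.0 if abs(sin_t) < 1e-12 else sin_t
    cos_t = 0.0 if abs(cos_t) < 1e-12 else cos_t
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = ((h - 1) / 2.0, (w - 1) / 2.0) if center is None else center
    radial = sin_t * (cols - cx) + cos_t * (rows - cy)
    return np.abs(radial) <= diameter_px / 2.0
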