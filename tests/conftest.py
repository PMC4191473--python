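import numpy as np
import pytest

from retinovis import (
    AbsoluteRetinotopicMap,
    ImagingGroundTruth,
    SessionGeometry,
    position_field,
)


@pytest.fixture
def small_geometry():
    """Compact session: 48x48 pixels, 4 stimulus cycles at 40 frames/cycle."""
    return SessionGeometry(shape=(48, 48), n_cycles=4)


def make_noiseless_gt(tilt_deg=25.7, magnification=44.8, **kwargs):
    return ImagingGroundTruth(
        tilt_deg=tilt_deg,
        magnification_deg_per_mm=magnification,
        noise_sd=0.0,
        drift_amplitude=0.0,
        **kwargs,
    )


def make_planar_map(
    shape=(48, 48),
    tilt_deg=25.7,
    magnification=44.8,
    axis="elevation",
    pixel_size_mm=0.005,
    amplitude=None,
):
    """Absolute map built directly from a planar ground-truth position field."""
    geom = SessionGeometry(shape=shape, axis=axis, pixel_size_mm=pixel_size_mm)
    gt = make_noiseless_gt(tilt_deg, magnification)
    v = position_field(gt, geom)
    amp = np.ones(shape) if amplitude is None else amplitude
    return AbsoluteRetinotopicMap(
        visual_angle=v, amplitude=amp, axis=axis, pixel_size_mm=pixel_size_mm
    )
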