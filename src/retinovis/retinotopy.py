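"""Fourier analysis of periodic-stimulation intrinsic-signal imaging.

Each pixel's reflectance time series is high-pass filtered (subtraction of a
centered boxcar moving average spanning two stimulus cycles), the Fourier
component at the stimulus frequency is extracted, a constant bias vector
estimated in a quiet reference region is removed, and the phase maps from
oppositely drifting stimuli are combined: half the wrapped phase difference
cancels the hemodynamic delay common to both directions and leaves the pure
retinotopic position phase, which a constant factor (default 7.2 phase
degrees per visual degree) converts to visual angle.

Phase convention: for a pixel trace ``A*cos(2*pi*f*t + phi)`` the extracted
amplitude is ``A`` and the phase is ``phi``.  Phases are carried in degrees
and wrapped to the principal interval (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .synth import ImagingSession

__all__ = [
    "ComplexResponseMap",
    "AbsoluteRetinotopicMap",
    "wrap_deg",
    "highpass_boxcar",
    "extract_fundamental",
    "remove_bias",
    "combine_opposite",
    "compute_absolute_map",
]

DEFAULT_ANGLE_CONVERSION = 7.2  # phase degrees per visual degree (= 360/50)


def wrap_deg(phase_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase in degrees to the principal interval (-180, 180]."""
    wrapped = -((-np.asarray(phase_deg) + 180.0) % 360.0 - 180.0)
    return wrapped if np.ndim(phase_deg) else float(wrapped)


@dataclass
class ComplexResponseMap:
    """Per-pixel cosine/sine response components at the stimulus frequency."""

    cos_component: np.ndarray
    sin_component: np.ndarray
    direction: str  # "fwd" | "rev"
    axis: str  # "elevation" | "azimuth"
    stim_freq_hz: float
    frame_rate_hz: float
    pixel_size_mm: float

    @property
    def amplitude(self) -> np.ndarray:
        return np.hypot(self.cos_component, self.sin_component)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phase in degrees on (-180, 180]; 0 by convention where amplitude is 0."""
        return wrap_deg(np.degrees(np.arctan2(self.sin_component, self.cos_component)))


@dataclass
class AbsoluteRetinotopicMap:
    """Delay-free per-pixel visual-angle and response-amplitude map."""

    visual_angle: np.ndarray  # degrees of visual field
    amplitude: np.ndarray
    axis: str
    pixel_size_mm: float
    angle_conversion_factor: float = DEFAULT_ANGLE_CONVERSION


def highpass_boxcar(
    stack: np.ndarray,
    stim_freq_hz: float,
    frame_rate_hz: float,
    window_cycles: int = 2,
) -> np.ndarray:
    """Subtract a centered moving average spanning ``window_cycles`` cycles.

    The window length in frames, ``w = window_cycles * frame_rate_hz /
    stim_freq_hz``, must be an integer no longer than the stack.  For even
    ``w`` the average is the symmetric trapezoidal mean over ``w + 1`` frames
    (half weight on the endpoints), which is exact for both integer-cycle
    sinusoids (removed entirely) and linear trends.  Edge frames whose window
    is incomplete are dropped, so the returned stack is shorter by ``w``
    frames (one cycle per side at the default two-cycle window), which keeps
    an integer number of cycles.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    w_exact = window_cycles * frame_rate_hz / stim_freq_hz
    if abs(w_exact - round(w_exact)) > 1e-9:
        raise ValueError(f"boxcar window is not a whole number of frames: {w_exact}")
    w = round(w_exact)
    if w > n:
        raise ValueError(f"boxcar window ({w} frames) longer than stack ({n} frames)")
    if w % 2 == 0:
        kernel = np.ones(w + 1)
        kernel[0] = kernel[-1] = 0.5
        kernel /= w
    else:
        kernel = np.ones(w) / w
    h = kernel.size // 2
    mavg = ndimage.convolve1d(stack, kernel, axis=0, mode="nearest")
    return stack[h : n - h] - mavg[h : n - h]


def extract_fundamental(
    stack: np.ndarray,
    stim_freq_hz: float,
    frame_rate_hz: float,
    direction: str = "fwd",
    axis: str = "elevation",
    pixel_size_mm: float = 1.0,
) -> ComplexResponseMap:
    """Extract each pixel's Fourier component at the stimulation frequency.

    Requires the stack to span an integer number (>= 1) of stimulus cycles;
    under that condition a noiseless ``A*cos(2*pi*f*t + phi)`` trace yields
    amplitude ``A`` and phase ``phi`` exactly.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    k = stim_freq_hz * n / frame_rate_hz
    if abs(k - round(k)) > 1e-6 or round(k) < 1:
        raise ValueError(
            f"stimulus frequency {stim_freq_hz} Hz is not a harmonic of the "
            f"{n}-frame stack at {frame_rate_hz} Hz (k = {k})"
        )
    t = np.arange(n) / frame_rate_hz
    basis = np.exp(-2j * np.pi * stim_freq_hz * t)
    coef = (2.0 / n) * np.tensordot(basis, stack, axes=(0, 0))
    return ComplexResponseMap(
        cos_component=coef.real,
        sin_component=coef.imag,
        direction=direction,
        axis=axis,
        stim_freq_hz=stim_freq_hz,
        frame_rate_hz=frame_rate_hz,
        pixel_size_mm=pixel_size_mm,
    )


def remove_bias(cmap: ComplexResponseMap, reference_roi: np.ndarray) -> ComplexResponseMap:
    """Subtract the reference-region mean (cos, sin) vector from every pixel.

    The reference region should lie away from the evoked activity and be free
    of vascular artifacts; after the operation its mean vector is (0, 0).
    """
    ref = np.asarray(reference_roi, dtype=bool)
    if ref.shape != cmap.cos_component.shape:
        raise ValueError("reference mask shape does not match the map")
    if not ref.any():
        raise ValueError("reference region is empty")
    return replace(
        cmap,
        cos_component=cmap.cos_component - cmap.cos_component[ref].mean(),
        sin_component=cmap.sin_component - cmap.sin_component[ref].mean(),
    )


def combine_opposite(
    map_fwd: ComplexResponseMap,
    map_rev: ComplexResponseMap,
    angle_conversion_factor: float = DEFAULT_ANGLE_CONVERSION,
) -> AbsoluteRetinotopicMap:
    """Combine opposite-direction maps into an absolute retinotopic map.

    Per pixel: the phase difference is wrapped to (-180, 180] and halved —
    the common hemodynamic delay cancels exactly, leaving the position
    phase — then divided by ``angle_conversion_factor`` to give visual
    degrees; amplitudes are averaged.
    """
    if map_fwd.cos_component.shape != map_rev.cos_component.shape:
        raise ValueError("forward and reverse maps have different shapes")
    if map_fwd.axis != map_rev.axis:
        raise ValueError(
            f"axis mismatch: {map_fwd.axis!r} vs {map_rev.axis!r}"
        )
    if angle_conversion_factor <= 0:
        raise ValueError("angle_conversion_factor must be positive")
    half_diff = wrap_deg(map_fwd.phase_deg - map_rev.phase_deg) / 2.0
    return AbsoluteRetinotopicMap(
        visual_angle=half_diff / angle_conversion_factor,
        amplitude=(map_fwd.amplitude + map_rev.amplitude) / 2.0,
        axis=map_fwd.axis,
        pixel_size_mm=map_fwd.pixel_size_mm,
        angle_conversion_factor=angle_conversion_factor,
    )


def compute_absolute_map(
    session: ImagingSession,
    reference_roi: np.ndarray | None = None,
    window_cycles: int = 2,
    angle_conversion_factor: float = DEFAULT_ANGLE_CONVERSION,
) -> AbsoluteRetinotopicMap:
    """Full per-session pipeline: filter, extract, (debias), combine."""
    cmaps = {}
    for direction, stack in (("fwd", session.stack_fwd), ("rev", session.stack_rev)):
        filtered = highpass_boxcar(
            stack, session.stim_freq_hz, session.frame_rate_hz, window_cycles
        )
        cmap = extract_fundamental(
            filtered,
            session.stim_freq_hz,
            session.frame_rate_hz,
            direction=direction,
            axis=session.axis,
            pixel_size_mm=session.pixel_size_mm,
        )
        if reference_roi is not None:
            cmap = remove_bias(cmap, reference_roi)
        cmaps[direction] = cmap
    return combine_opposite(cmaps["fwd"], cmaps["rev"], angle_conversion_factor)
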