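"""Synthetic imaging sessions, VEP epoch sets, and ERG traces with known truth.

Every generator embeds its ground-truth parameters in the object it returns,
so each downstream analysis stage has a parameter-recovery (closed-loop) test
surface without any recorded data.

The imaging generator emulates periodic-stimulation intrinsic-signal optical
imaging: a cortical patch with a planar retinotopic position field whose
zero-level line makes a configurable angle (the map tilt) with the image
axes and whose gradient magnitude sets the cortical magnification.  Pixels
inside the responsive region oscillate at the stimulus drift frequency with a
phase equal to a common hemodynamic delay plus (forward sweep) or minus
(reverse sweep) the position phase; outside the region only noise and slow
drift are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .ephys import EpochSet

__all__ = [
    "SessionGeometry",
    "ImagingGroundTruth",
    "ImagingSession",
    "EphysGroundTruth",
    "ErgGroundTruth",
    "ErgRecording",
    "default_roi_mask",
    "position_field",
    "generate_imaging_session",
    "generate_vep_epochs",
    "generate_erg_trace",
]


@dataclass(frozen=True)
class SessionGeometry:
    """Acquisition geometry and timing of one imaging session.

    Defaults emulate an 8 s stimulus period (0.125 Hz drift) sampled at 5 Hz
    over six full sweeps of an 80 x 80 pixel patch at 5 um/pixel binning.
    Rows index the anteroposterior axis, columns the mediolateral axis,
    origin top-left.
    """

    shape: tuple[int, int] = (80, 80)
    n_cycles: int = 6
    frame_rate_hz: float = 5.0
    stim_freq_hz: float = 0.125
    pixel_size_mm: float = 0.005
    axis: str = "elevation"

    def __post_init__(self) -> None:
        if self.axis not in ("elevation", "azimuth"):
            raise ValueError("axis must be 'elevation' or 'azimuth'")
        if self.frame_rate_hz <= 0 or self.stim_freq_hz <= 0:
            raise ValueError("frame_rate_hz and stim_freq_hz must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.n_cycles < 2:
            raise ValueError("a session must span at least 2 stimulus cycles")
        frames = self.n_cycles * self.frame_rate_hz / self.stim_freq_hz
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError(
                "non-integer frame count: n_cycles * frame_rate_hz / "
                f"stim_freq_hz = {frames}; choose timing with whole cycles"
            )

    @property
    def n_frames(self) -> int:
        return round(self.n_cycles * self.frame_rate_hz / self.stim_freq_hz)

    @property
    def frames_per_cycle(self) -> float:
        return self.frame_rate_hz / self.stim_freq_hz


@dataclass
class ImagingGroundTruth:
    """Generative parameters of a synthetic retinotopic session.

    tilt_deg
        Angle of the zero-phase (monitor-center) line relative to the
        mediolateral axis for elevation maps, anteroposterior for azimuth;
        must lie in [0, 90).
    magnification_deg_per_mm
        Visual degrees represented per millimeter of cortex.
    delay_phase_deg
        Hemodynamic delay, in phase degrees, common to both sweep directions.
    sweep_extent_deg
        Visual-field extent of one stimulus cycle; 50 degrees corresponds to
        the default phase-to-angle conversion factor 360/50 = 7.2.
    noise_sd, drift_amplitude
        Additive i.i.d. Gaussian reflectance noise SD per pixel-frame, and
        amplitude of a per-pixel quadratic slow trend.
    response_amplitude, baseline
        Reflectance modulation depth inside the ROI and the DC reflectance.
    roi_mask
        Boolean mask of pixels carrying visual signal; None selects a
        centered disk covering ~45% of the field.
    vessel_stripes
        Number of high-amplitude static stripes emulating surface vessels;
        stripe pixels are excluded from the ROI.
    """

    tilt_deg: float
    magnification_deg_per_mm: float
    delay_phase_deg: float = 60.0
    sweep_extent_deg: float = 50.0
    noise_sd: float = 0.002
    drift_amplitude: float = 0.001
    response_amplitude: float = 0.01
    baseline: float = 1.0
    roi_mask: np.ndarray | None = None
    vessel_stripes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_deg < 90.0:
            raise ValueError(f"tilt_deg must lie in [0, 90), got {self.tilt_deg}")
        if self.magnification_deg_per_mm <= 0:
            raise ValueError("magnification_deg_per_mm must be positive")
        if self.sweep_extent_deg <= 0:
            raise ValueError("sweep_extent_deg must be positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "tilt_deg": float(self.tilt_deg),
            "magnification_deg_per_mm": float(self.magnification_deg_per_mm),
            "delay_phase_deg": float(self.delay_phase_deg),
            "sweep_extent_deg": float(self.sweep_extent_deg),
            "noise_sd": float(self.noise_sd),
            "drift_amplitude": float(self.drift_amplitude),
            "response_amplitude": float(self.response_amplitude),
            "baseline": float(self.baseline),
            "vessel_stripes": int(self.vessel_stripes),
            "seed": int(self.seed),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping, roi_mask: np.ndarray | None = None):
        return cls(roi_mask=roi_mask, **dict(d))


@dataclass
class ImagingSession:
    """A forward/reverse pair of reflectance frame stacks plus metadata."""

    stack_fwd: np.ndarray  # (frames, rows, cols)
    stack_rev: np.ndarray
    frame_rate_hz: float
    stim_freq_hz: float
    axis: str
    pixel_size_mm: float
    ground_truth: ImagingGroundTruth | None = None

    def __post_init__(self) -> None:
        if self.stack_fwd.shape != self.stack_rev.shape:
            raise ValueError("forward and reverse stacks must share shape")

    @property
    def n_frames(self) -> int:
        return self.stack_fwd.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.stack_fwd.shape[1:]


def default_roi_mask(shape: tuple[int, int]) -> np.ndarray:
    """Centered disk of radius 0.38*min(shape): the responsive patch."""
    nr, nc = shape
    rr, cc = np.ogrid[:nr, :nc]
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    radius = 0.38 * min(nr, nc)
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def _gradient_direction(axis: str, tilt_deg: float) -> tuple[float, float]:
    # Unit gradient direction in (row, col) coordinates such that the
    # zero-level line makes `tilt_deg` with the axis-appropriate reference
    # (mediolateral = columns for elevation, anteroposterior = rows for
    # azimuth).
    th = math.radians(tilt_deg)
    if axis == "elevation":
        return (math.cos(th), math.sin(th))
    return (math.sin(th), math.cos(th))


def position_field(gt: ImagingGroundTruth, geometry: SessionGeometry) -> np.ndarray:
    """Planar visual-angle field (degrees), zero on the map-center line.

    The gradient magnitude equals ``magnification_deg_per_mm`` expressed per
    pixel; the zero-level line passes through the field center at the
    ground-truth tilt.
    """
    nr, nc = geometry.shape
    ur, uc = _gradient_direction(geometry.axis, gt.tilt_deg)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    dist_mm = geometry.pixel_size_mm * ((rr - r0) * ur + (cc - c0) * uc)
    return gt.magnification_deg_per_mm * dist_mm


def _drift(rng: np.random.Generator, n: int, shape: tuple[int, int], amp: float) -> np.ndarray:
    if amp == 0:
        return np.zeros((n,) + shape)
    coef = rng.standard_normal((3,) + shape)
    tau = np.linspace(-1.0, 1.0, n)[:, None, None]
    return amp * (coef[0] + coef[1] * tau + coef[2] * tau**2)


def generate_imaging_session(
    gt: ImagingGroundTruth, geometry: SessionGeometry = SessionGeometry()
) -> ImagingSession:
    """Simulate one forward/reverse periodic-stimulation imaging session.

    Inside the ROI, pixel (r, c) of the forward stack oscillates at the
    stimulus frequency with phase ``delay + position_phase(r, c)`` and the
    reverse stack with ``delay - position_phase(r, c)``; the position phase
    is the planar visual-angle field scaled by 360/sweep_extent_deg.
    Identical seed and parameters give bit-identical stacks.
    """
    rng = np.random.default_rng(gt.seed)
    n = geometry.n_frames
    shape = geometry.shape

    roi = gt.roi_mask if gt.roi_mask is not None else default_roi_mask(shape)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != shape:
        raise ValueError("roi_mask shape does not match geometry shape")

    vessel = np.zeros(shape, dtype=bool)
    if gt.vessel_stripes > 0:
        cols = rng.choice(shape[1] - 2, size=gt.vessel_stripes, replace=False)
        for c in cols:
            vessel[:, c : c + 2] = True
        roi = roi & ~vessel

    pos_phase_deg = position_field(gt, geometry) * (360.0 / gt.sweep_extent_deg)
    t = np.arange(n) / geometry.frame_rate_hz
    omega_t = 2.0 * np.pi * geometry.stim_freq_hz * t[:, None, None]
    delay = math.radians(gt.delay_phase_deg)
    pos = np.deg2rad(pos_phase_deg)[None, :, :]

    stacks = []
    for sign in (+1.0, -1.0):
        signal = gt.response_amplitude * np.cos(omega_t + delay + sign * pos)
        stack = gt.baseline + np.where(roi, signal, 0.0)
        if gt.vessel_stripes > 0:
            stack = stack + np.where(vessel, 10.0 * gt.response_amplitude, 0.0)
        stack = stack + _drift(rng, n, shape, gt.drift_amplitude)
        if gt.noise_sd > 0:
            stack = stack + rng.normal(0.0, gt.noise_sd, size=(n,) + shape)
        stacks.append(stack)

    gt_out = replace(gt, roi_mask=roi)
    return ImagingSession(
        stack_fwd=stacks[0],
        stack_rev=stacks[1],
        frame_rate_hz=geometry.frame_rate_hz,
        stim_freq_hz=geometry.stim_freq_hz,
        axis=geometry.axis,
        pixel_size_mm=geometry.pixel_size_mm,
        ground_truth=gt_out,
    )


# ---------------------------------------------------------------------------
# Electrophysiology generators
# ---------------------------------------------------------------------------


@dataclass
class EphysGroundTruth:
    """True per-condition VEP amplitudes and waveform-template parameters.

    The template is a biphasic negative-then-positive deflection (difference
    of Gaussians) normalized to unit peak-to-trough amplitude, so the true
    amplitude of a condition is exactly its peak-to-trough value.
    """

    amplitudes: dict[str, float]
    noise_sd: float = 0.0
    n_trials: int = 100
    seed: int = 0
    sample_rate_hz: float = 1000.0
    epoch_s: float = 0.3
    trough_s: float = 0.07
    peak_s: float = 0.12
    trough_width_s: float = 0.015
    peak_width_s: float = 0.025

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("true amplitudes must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.trough_s < self.peak_s:
            raise ValueError("template trough must precede the peak")


def _vep_template(gt: EphysGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    time = np.arange(round(gt.epoch_s * gt.sample_rate_hz)) / gt.sample_rate_hz
    w = -np.exp(-0.5 * ((time - gt.trough_s) / gt.trough_width_s) ** 2)
    w = w + 0.8 * np.exp(-0.5 * ((time - gt.peak_s) / gt.peak_width_s) ** 2)
    return time, w / (w.max() - w.min())


def generate_vep_epochs(
    gt: EphysGroundTruth, conditions: Sequence[str] | None = None
) -> EpochSet:
    """Simulate ``n_trials`` noisy VEP epochs per stimulus condition.

    The per-condition trial-averaged trace has peak-to-trough amplitude equal
    to the true amplitude up to noise of order ``noise_sd / sqrt(n_trials)``.
    """
    if conditions is None:
        conditions = list(gt.amplitudes)
    missing = [c for c in conditions if c not in gt.amplitudes]
    if missing:
        raise KeyError(f"no true amplitude for conditions {missing}")

    rng = np.random.default_rng(gt.seed)
    time, template = _vep_template(gt)
    trials, labels = [], []
    for cond in conditions:
        clean = gt.amplitudes[cond] * template
        block = np.tile(clean, (gt.n_trials, 1))
        if gt.noise_sd > 0:
            block = block + rng.normal(0.0, gt.noise_sd, size=block.shape)
        trials.append(block)
        labels.extend([cond] * gt.n_trials)
    return EpochSet(time=time, trials=np.vstack(trials), labels=labels)


@dataclass
class ErgGroundTruth:
    """True a-/b-wave amplitudes and latencies of a synthetic flash ERG.

    The a-wave is modelled as a smooth step to a sustained hyperpolarization
    plateau of depth ``a_amp`` (complete at ``a_latency_s``); the b-wave as a
    Gaussian depolarization of height ``b_amp`` above the plateau peaking at
    ``b_latency_s``.  With ``b_amp = 0`` the trace therefore stays at the
    trough and the measured trough-to-peak b-amplitude is 0.
    """

    a_amp: float
    b_amp: float
    a_latency_s: float = 0.015
    b_latency_s: float = 0.08
    b_width_s: float = 0.012
    pre_s: float = 0.05
    post_s: float = 0.3
    sample_rate_hz: float = 1000.0
    noise_sd: float = 0.0
    n_flashes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_amp < 0 or self.b_amp < 0:
            raise ValueError("a_amp and b_amp must be >= 0")
        if not self.a_latency_s < self.b_latency_s:
            raise ValueError("a-wave latency must precede b-wave latency")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_flashes < 1:
            raise ValueError("n_flashes must be >= 1")


@dataclass
class ErgRecording:
    """One flash-averaged ERG trace with its time base and flash time."""

    time: np.ndarray
    trace: np.ndarray
    flash_time: float = 0.0
    ground_truth: ErgGroundTruth | None = None


def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def generate_erg_trace(gt: ErgGroundTruth) -> ErgRecording:
    """Simulate ``n_flashes`` flash responses and return their average.

    The flash occurs at t = 0; the trace runs from -pre_s to +post_s.
    """
    n = round((gt.pre_s + gt.post_s) * gt.sample_rate_hz)
    time = np.arange(n) / gt.sample_rate_hz - gt.pre_s
    rel = time  # flash at 0
    clean = -gt.a_amp * _smoothstep(rel / gt.a_latency_s)
    clean = clean + gt.b_amp * np.exp(-0.5 * ((rel - gt.b_latency_s) / gt.b_width_s) ** 2) * (
        rel > 0
    )
    rng = np.random.default_rng(gt.seed)
    if gt.noise_sd > 0:
        flashes = clean[None, :] + rng.normal(0.0, gt.noise_sd, size=(gt.n_flashes, n))
        trace = flashes.mean(axis=0)
    else:
        trace = clean.copy()
    return ErgRecording(time=time, trace=trace, flash_time=0.0, ground_truth=gt)
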