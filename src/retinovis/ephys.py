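"""Trial-averaged evoked-potential and electroretinogram feature extraction.

Visually evoked potentials (VEPs) are scored as the peak-to-trough amplitude
of the trial-averaged trace inside an analysis window; per-animal ocular
dominance is summarized by the contralateral bias index (CBI), the ratio of
the contralateral to the ipsilateral eye's amplitude.  Spatial-frequency and
contrast response curves are normalized to a reference condition.

Electroretinograms (ERGs) are scored by the classical two-wave convention:
the a-wave is the initial negative deflection after the flash (measured
baseline-to-trough) and the b-wave is the subsequent positive deflection
(measured trough-to-peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EpochSet",
    "VepFeatures",
    "ErgFeatures",
    "average_epochs",
    "vep_amplitude",
    "compute_cbi",
    "normalize_response_curve",
    "vep_features",
    "erg_wave_amplitudes",
]


@dataclass
class EpochSet:
    """Trial-indexed voltage traces sharing a uniform time base.

    Parameters
    ----------
    time : ndarray, shape (n_samples,)
        Sample times in seconds, uniformly spaced.
    trials : ndarray, shape (n_trials, n_samples)
        One voltage trace per trial (response units).
    labels : sequence of str
        Stimulus-condition label of each trial (eye, spatial frequency,
        contrast, or flash id).
    """

    time: np.ndarray
    trials: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        self.labels = list(self.labels)
        if self.trials.shape != (len(self.labels), self.time.size):
            raise ValueError(
                f"trials shape {self.trials.shape} inconsistent with "
                f"{len(self.labels)} labels x {self.time.size} samples"
            )
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time base must be uniformly sampled")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def conditions(self) -> list[str]:
        """Unique condition labels in order of first appearance."""
        return list(dict.fromkeys(self.labels))

    def select(self, condition: str) -> np.ndarray:
        mask = np.array([lab == condition for lab in self.labels])
        return self.trials[mask]


@dataclass
class VepFeatures:
    """Per-condition VEP amplitudes plus derived summaries."""

    amplitudes: dict[str, float]
    normalized: dict[str, float]
    reference: str
    noise_floor: float | None = None


@dataclass
class ErgFeatures:
    """a-/b-wave scores of one averaged ERG trace.

    ``a_amplitude`` is the baseline-to-trough depth of the initial negative
    deflection; ``b_amplitude`` is the trough-to-peak rise that follows.
    Latencies are in seconds relative to the flash.
    """

    a_amplitude: float
    b_amplitude: float
    trough_latency_s: float
    peak_latency_s: float
    baseline: float = field(default=0.0, repr=False)

    @property
    def ab_ratio(self) -> float:
        if self.b_amplitude <= 0:
            raise ValueError("a/b ratio undefined: b-wave amplitude is zero")
        return self.a_amplitude / self.b_amplitude


def average_epochs(epochs: EpochSet, condition: str) -> np.ndarray:
    """Pointwise mean trace over all trials carrying ``condition``."""
    trials = epochs.select(condition)
    if trials.shape[0] == 0:
        raise ValueError(f"no trials labelled {condition!r}")
    return trials.mean(axis=0)


def vep_amplitude(
    trace: np.ndarray,
    time: np.ndarray | None = None,
    window: tuple[float, float] = (0.0, 0.25),
) -> float:
    """Peak-to-trough amplitude of ``trace`` inside the analysis window.

    ``window`` is in seconds on ``time``; when ``time`` is omitted the whole
    trace is used.
    """
    trace = np.asarray(trace, dtype=float)
    if time is not None:
        time = np.asarray(time, dtype=float)
        sel = (time >= window[0]) & (time <= window[1])
        if not sel.any():
            raise ValueError(f"analysis window {window} contains no samples")
        trace = trace[sel]
    if trace.size == 0:
        raise ValueError("empty trace")
    return float(trace.max() - trace.min())


def compute_cbi(amp_contra: float, amp_ipsi: float) -> float:
    """Contralateral bias index: contralateral / ipsilateral amplitude."""
    if amp_ipsi <= 0:
        raise ValueError("ipsilateral amplitude must be positive")
    return float(amp_contra) / float(amp_ipsi)


def normalize_response_curve(
    amplitudes: Mapping[str, float], reference: str
) -> dict[str, float]:
    """Divide every condition's amplitude by the reference condition's.

    The reference condition maps to exactly 1.
    """
    if reference not in amplitudes:
        raise KeyError(f"reference condition {reference!r} not present")
    ref = float(amplitudes[reference])
    if ref <= 0:
        raise ValueError("reference amplitude must be positive")
    return {cond: float(a) / ref for cond, a in amplitudes.items()}


def vep_features(
    epochs: EpochSet,
    reference: str,
    blank: str | None = None,
    window: tuple[float, float] = (0.0, 0.25),
) -> VepFeatures:
    """Score every condition of an epoch set and normalize to ``reference``.

    ``blank`` names the equal-luminance gray condition whose amplitude is the
    noise floor; it is excluded from the normalized curve.
    """
    amps = {
        cond: vep_amplitude(average_epochs(epochs, cond), epochs.time, window)
        for cond in epochs.conditions
    }
    noise_floor = amps.get(blank) if blank is not None else None
    curve = {c: a for c, a in amps.items() if c != blank}
    return VepFeatures(
        amplitudes=amps,
        normalized=normalize_response_curve(curve, reference),
        reference=reference,
        noise_floor=noise_floor,
    )


def erg_wave_amplitudes(
    time: np.ndarray,
    trace: np.ndarray,
    flash_time: float = 0.0,
    a_window: tuple[float, float] = (0.0, 0.05),
    b_window: tuple[float, float] = (0.05, 0.2),
    baseline_s: float = 0.05,
) -> ErgFeatures:
    """Score a-wave and b-wave amplitudes of one averaged ERG trace.

    Windows are in seconds relative to ``flash_time`` and must lie after it.
    Baseline is the mean of the ``baseline_s`` seconds preceding the flash.
    a_amplitude = baseline - min(trace in a-window);
    b_amplitude = max(trace in b-window) - min(trace in a-window).
    Negative excursions are clipped to zero (no wave present).
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if time.shape != trace.shape:
        raise ValueError("time and trace shapes differ")
    if a_window[0] < 0 or b_window[0] < a_window[0]:
        raise ValueError("search windows must be ordered after the flash")

    rel = time - flash_time
    base_sel = (rel >= -baseline_s) & (rel < 0)
    if not base_sel.any():
        raise ValueError("no baseline samples before the flash")
    baseline = float(trace[base_sel].mean())

    a_sel = (rel >= a_window[0]) & (rel <= a_window[1])
    b_sel = (rel >= b_window[0]) & (rel <= b_window[1])
    if not a_sel.any() or not b_sel.any():
        raise ValueError("a/b search windows contain no samples")

    i_a = np.flatnonzero(a_sel)
    i_b = np.flatnonzero(b_sel)
    i_trough = i_a[np.argmin(trace[i_a])]
    i_peak = i_b[np.argmax(trace[i_b])]
    if rel[i_peak] < rel[i_trough]:
        raise ValueError("b-wave maximum precedes a-wave minimum")

    trough = float(trace[i_trough])
    peak = float(trace[i_peak])
    return ErgFeatures(
        a_amplitude=max(baseline - trough, 0.0),
        b_amplitude=max(peak - trough, 0.0),
        trough_latency_s=float(rel[i_trough]),
        peak_latency_s=float(rel[i_peak]),
        baseline=baseline,
    )
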