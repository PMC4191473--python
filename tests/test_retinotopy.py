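"""Fourier pipeline: boxcar high-pass, fundamental extraction, bias removal,
and opposite-direction combination, each against an independent oracle."""

import numpy as np
import pytest

from retinovis import (
    ComplexResponseMap,
    combine_opposite,
    compute_absolute_map,
    extract_fundamental,
    generate_imaging_session,
    highpass_boxcar,
    position_field,
    remove_bias,
    wrap_deg,
)

from conftest import make_noiseless_gt

F, RATE = 0.125, 5.0  # stimulus drift and frame rate (Hz): 40 frames/cycle


def _stack(trace):
    return np.asarray(trace)[:, None, None]


def boxcar_oracle(trace, w):
    """Naive O(n*w) centered trapezoidal moving average (half-weight ends)."""
    n = len(trace)
    h = (w + 1) // 2 if w % 2 == 0 else w // 2
    out = []
    for t in range(h, n - h):
        if w % 2 == 0:
            window = 0.5 * trace[t - h] + trace[t - h + 1 : t + h].sum() + 0.5 * trace[t + h]
            out.append(trace[t] - window / w)
        else:
            out.append(trace[t] - trace[t - h : t + h + 1].mean())
    return np.array(out)


class TestHighpassBoxcar:
    def test_constant_trace_maps_to_zero(self):
        out = highpass_boxcar(_stack(np.full(240, 3.7)), F, RATE)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_stimulus_frequency_sinusoid_passes_unchanged(self):
        t = np.arange(240) / RATE
        x = np.cos(2 * np.pi * F * t + 0.3)
        out = highpass_boxcar(_stack(x), F, RATE)[:, 0, 0]
        np.testing.assert_allclose(out, x[40:-40], atol=1e-10)

    def test_linear_ramp_removed_and_matches_bruteforce_oracle(self):
        t = np.arange(240, dtype=float)
        x = 0.01 * t + np.sin(2 * np.pi * F * t / RATE)  # ramp + signal
        out = highpass_boxcar(_stack(x), F, RATE)[:, 0, 0]
        np.testing.assert_allclose(out, boxcar_oracle(x, 80), atol=1e-10)
        ramp_only = highpass_boxcar(_stack(0.01 * t), F, RATE)[:, 0, 0]
        np.testing.assert_allclose(ramp_only, 0.0, atol=1e-10)

    def test_window_longer_than_stack_rejected(self):
        with pytest.raises(ValueError, match="longer than stack"):
            highpass_boxcar(_stack(np.zeros(40)), F, RATE, window_cycles=2)

    def test_trimmed_output_keeps_whole_cycles(self):
        out = highpass_boxcar(_stack(np.zeros(240)), F, RATE)
        assert out.shape[0] == 160  # 6 cycles in, window drops 1 per side
        assert (out.shape[0] * F / RATE) == pytest.approx(4.0)


class TestExtractFundamental:
    def test_single_tone_identity(self):
        t = np.arange(160) / RATE
        x = 3.0 * np.cos(2 * np.pi * F * t + 0.5)
        cmap = extract_fundamental(_stack(x), F, RATE)
        assert cmap.amplitude[0, 0] == pytest.approx(3.0, rel=1e-12)
        assert np.deg2rad(cmap.phase_deg[0, 0]) == pytest.approx(0.5, abs=1e-12)

    def test_matches_full_dft_bin_oracle(self):
        rng = np.random.default_rng(42)
        stack = rng.standard_normal((160, 6, 5))
        cmap = extract_fundamental(stack, F, RATE)
        k = round(F * 160 / RATE)
        bin_coef = (2.0 / 160) * np.fft.fft(stack, axis=0)[k]
        np.testing.assert_allclose(cmap.cos_component, bin_coef.real, atol=1e-12)
        np.testing.assert_allclose(cmap.sin_component, bin_coef.imag, atol=1e-12)
        np.testing.assert_allclose(cmap.amplitude, np.abs(bin_coef), atol=1e-12)

    def test_zero_trace_reports_zero_amplitude_and_phase(self):
        cmap = extract_fundamental(_stack(np.zeros(160)), F, RATE)
        assert cmap.amplitude[0, 0] == 0.0
        assert cmap.phase_deg[0, 0] == 0.0

    def test_off_grid_frequency_rejected(self):
        with pytest.raises(ValueError, match="harmonic"):
            extract_fundamental(_stack(np.zeros(160)), 0.1234, RATE)

    def test_amplitude_equals_component_modulus(self):
        rng = np.random.default_rng(0)
        stack = rng.standard_normal((80, 4, 4))
        cmap = extract_fundamental(stack, F, RATE)
        np.testing.assert_allclose(
            cmap.amplitude,
            np.sqrt(cmap.cos_component**2 + cmap.sin_component**2),
            atol=1e-14,
        )


def _cmap(cos, sin, direction="fwd", axis="elevation"):
    return ComplexResponseMap(
        cos_component=np.asarray(cos, dtype=float),
        sin_component=np.asarray(sin, dtype=float),
        direction=direction,
        axis=axis,
        stim_freq_hz=F,
        frame_rate_hz=RATE,
        pixel_size_mm=0.005,
    )


class TestRemoveBias:
    def test_constant_offset_cancels_exactly(self):
        rng = np.random.default_rng(1)
        cos, sin = rng.standard_normal((2, 8, 8))
        biased = _cmap(cos + 0.7, sin - 1.2)
        ref = np.zeros((8, 8), dtype=bool)
        ref[:2, :2] = True
        clean = remove_bias(biased, ref)
        expected_cos = cos + 0.7 - (cos[:2, :2] + 0.7).mean()
        np.testing.assert_allclose(clean.cos_component, expected_cos, atol=1e-12)
        assert clean.cos_component[ref].mean() == pytest.approx(0.0, abs=1e-12)
        assert clean.sin_component[ref].mean() == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            remove_bias(_cmap(np.ones((4, 4)), np.ones((4, 4))), np.zeros((4, 4), bool))

    def test_estimated_bias_within_standard_error(self, small_geometry):
        """On a noisy synthetic session the reference-region residual bias is
        below 3x its standard error (sigma*sqrt(2/N) per component)."""
        gt = make_noiseless_gt()
        gt.noise_sd = 0.005
        gt.seed = 9
        ses = generate_imaging_session(gt, small_geometry)
        filt = highpass_boxcar(ses.stack_fwd, F, RATE)
        cmap = extract_fundamental(filt, F, RATE)
        ref = ~ses.ground_truth.roi_mask
        n_frames = filt.shape[0]
        se = gt.noise_sd * np.sqrt(2.0 / n_frames) / np.sqrt(ref.sum())
        assert abs(cmap.cos_component[ref].mean()) < 3 * se
        assert abs(cmap.sin_component[ref].mean()) < 3 * se


class TestCombineOpposite:
    def test_delay_cancels_algebraically(self):
        delay, pos = 77.0, 31.0
        fwd = _cmap([[np.cos(np.deg2rad(delay + pos))]], [[np.sin(np.deg2rad(delay + pos))]])
        rev = _cmap([[np.cos(np.deg2rad(delay - pos))]], [[np.sin(np.deg2rad(delay - pos))]], "rev")
        amap = combine_opposite(fwd, rev)
        assert amap.visual_angle[0, 0] * 7.2 == pytest.approx(pos, abs=1e-9)

    def test_amplitudes_average(self):
        fwd = _cmap([[10.0]], [[0.0]])
        rev = _cmap([[6.0]], [[0.0]], "rev")
        assert combine_opposite(fwd, rev).amplitude[0, 0] == pytest.approx(8.0)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            combine_opposite(
                _cmap([[1.0]], [[0.0]], axis="elevation"),
                _cmap([[1.0]], [[0.0]], "rev", axis="azimuth"),
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            combine_opposite(
                _cmap(np.ones((2, 2)), np.zeros((2, 2))),
                _cmap(np.ones((3, 3)), np.zeros((3, 3)), "rev"),
            )

    def test_noiseless_session_recovers_position_field(self, small_geometry):
        """Closed loop: the combined visual-angle field equals the generator's
        planar position field everywhere inside the ROI."""
        gt = make_noiseless_gt(tilt_deg=30.0)
        ses = generate_imaging_session(gt, small_geometry)
        amap = compute_absolute_map(ses)
        truth = position_field(ses.ground_truth, small_geometry)
        roi = ses.ground_truth.roi_mask
        np.testing.assert_allclose(amap.visual_angle[roi], truth[roi], atol=1e-9)


def test_wrap_deg_principal_interval():
    vals = np.array([-540.0, -180.0, -179.9, 0.0, 179.9, 180.0, 360.0, 541.0])
    wrapped = wrap_deg(vals)
    assert np.all(wrapped > -180.0) and np.all(wrapped <= 180.0)
    np.testing.assert_allclose(np.cos(np.deg2rad(wrapped)), np.cos(np.deg2rad(vals)), atol=1e-12)
    np.testing.assert_allclose(np.sin(np.deg2rad(wrapped)), np.sin(np.deg2rad(vals)), atol=1e-12)
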