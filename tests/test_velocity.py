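"""Velocity estimation, combined PSD, A1 peak features, and the A1r rules."""

import numpy as np
import pytest

from tremorkit import (
    A1Features,
    DataError,
    classify_a1r,
    combined_velocity_psd,
    estimate_velocity,
    extract_a1_features,
    extract_a1_for_recording,
)

FS = 120.0


class TestEstimateVelocity:
    def test_constant_trajectory_gives_zero(self):
        v = estimate_velocity(np.full((600, 3), 123.4), FS)
        np.testing.assert_allclose(v, 0.0, atol=1e-9)

    def test_linear_ramp_matches_analytic_slope(self):
        t = np.arange(600) / FS
        v = estimate_velocity(10.0 * t, FS)
        np.testing.assert_allclose(v[100:-100], 10.0, rtol=0.02)

    @pytest.mark.parametrize("f0", [2.0, 5.0, 8.0, 10.0])
    def test_sinusoid_amplitude_matches_derivative(self, f0):
        t = np.arange(int(20 * FS)) / FS
        v = estimate_velocity(2.5 * np.sin(2 * np.pi * f0 * t), FS)
        assert np.max(np.abs(v[200:-200])) == pytest.approx(2 * np.pi * f0 * 2.5, rel=0.02)

    def test_too_short_signal_raises(self):
        with pytest.raises(DataError):
            estimate_velocity(np.zeros(10), FS)

    def test_nonfinite_raises(self):
        x = np.zeros(600)
        x[5] = np.nan
        with pytest.raises(DataError):
            estimate_velocity(x, FS)


class TestCombinedPsd:
    def _vel(self, x):
        v = np.zeros((len(x), 3))
        v[:, 0] = x
        return v

    def test_energy_on_one_axis_equals_that_axis_psd(self):
        from scipy.signal import welch

        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 6 * t)
        freqs, _, raw = combined_velocity_psd(self._vel(x), FS)
        f2, px = welch(x, fs=FS, window="hamming", nperseg=480, noverlap=240)
        # identical up to summation roundoff at the numerical noise floor
        np.testing.assert_allclose(raw, px, rtol=1e-7, atol=px.max() * 1e-12)

    def test_identical_axes_scale_by_sqrt3(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 6 * t)
        v3 = np.column_stack([x, x, x])
        _, _, raw3 = combined_velocity_psd(v3, FS)
        _, _, raw1 = combined_velocity_psd(self._vel(x), FS)
        np.testing.assert_allclose(raw3, np.sqrt(3) * raw1, rtol=1e-10)

    def test_argmax_localizes_6hz(self):
        t = np.arange(int(20 * FS)) / FS
        freqs, smoothed, _ = combined_velocity_psd(self._vel(np.sin(2 * np.pi * 6 * t)), FS)
        df = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(smoothed)] - 6.0) <= df

    def test_wrong_shape_raises(self):
        with pytest.raises(DataError):
            combined_velocity_psd(np.zeros((100, 2)), FS)


class TestExtractA1Features:
    def test_flat_psd_has_no_valid_peak(self):
        freqs = np.linspace(0, 20, 81)
        feats = extract_a1_features(freqs, np.ones_like(freqs))
        assert not feats.valid_peak

    def test_all_zero_psd_invalid(self):
        freqs = np.linspace(0, 20, 81)
        assert not extract_a1_features(freqs, np.zeros_like(freqs)).valid_peak

    def test_symmetric_gaussian_bump_is_symmetric(self):
        freqs = np.linspace(0, 20, 401)
        psd = 1e-6 + np.exp(-0.5 * ((freqs - 6.0) / 0.4) ** 2)
        feats = extract_a1_features(freqs, psd)
        assert feats.valid_peak
        assert abs(feats.HI_POWER - feats.LO_POWER) < 0.1
        assert feats.LO_F <= feats.F_CENTER <= feats.HI_F
        assert feats.BW == pytest.approx(feats.HI_F - feats.LO_F)
        assert 0.0 <= feats.RELATIVE_POWER <= 1.0

    def test_scale_equivariance(self, tremor_factory):
        # scaling the trajectory by c scales amplitude by c and power by
        # 20*log10(c) dB; the band-relative shape features are unchanged
        rec = tremor_factory(tremor_freq_hz=6.0, tremor_amp_mm=1.0, jitter_sd_mm=0.02)
        c = 3.7
        base = extract_a1_for_recording(rec)[0]
        scaled_rec = tremor_factory(tremor_freq_hz=6.0, tremor_amp_mm=1.0, jitter_sd_mm=0.02)
        scaled_rec.data = scaled_rec.data * c
        scaled = extract_a1_for_recording(scaled_rec)[0]
        assert scaled.AMPLITUDE_MM_P_S == pytest.approx(c * base.AMPLITUDE_MM_P_S, rel=1e-6)
        assert scaled.MAX_POWER - base.MAX_POWER == pytest.approx(20 * np.log10(c), abs=1e-6)
        assert scaled.F_CENTER == base.F_CENTER
        assert scaled.BW == pytest.approx(base.BW, rel=1e-6)

    def test_time_reversal_leaves_psd_unchanged(self, tremor_factory):
        rec = tremor_factory(tremor_freq_hz=5.0, jitter_sd_mm=0.03)
        vel = estimate_velocity(rec.marker(rec.marker_names[0]), FS)
        vel_rev = estimate_velocity(rec.marker(rec.marker_names[0])[::-1], FS)
        _, _, raw = combined_velocity_psd(vel, FS)
        _, _, raw_rev = combined_velocity_psd(vel_rev, FS)
        # filter edge transients differ slightly between directions
        np.testing.assert_allclose(raw, raw_rev, rtol=0.1, atol=raw.max() * 1e-10)

    def test_velocity_amplitude_matches_sinusoid_relation(self, tremor_factory):
        # pure tremor of displacement amplitude A at f0 on each axis has a
        # per-axis velocity amplitude 2*pi*f0*A; the Euclidean-norm-combined
        # PSD of three equal axes is sqrt(3) larger, so the ENBW-based
        # amplitude estimate reads 3**(1/4) * 2*pi*f0*A
        rec = tremor_factory(tremor_freq_hz=5.0, tremor_amp_mm=1.0, duration_s=20.0)
        feats = extract_a1_for_recording(rec)[0]
        expected = 3**0.25 * 2 * np.pi * 5.0 * 1.0
        assert feats.AMPLITUDE_MM_P_S == pytest.approx(expected, rel=0.1)


class TestClassifyA1r:
    def _feat(self, **kw):
        base = dict(
            F_CENTER=5.0, AMPLITUDE_MM_P_S=10.0, BW=1.0, HI_F=5.5, LO_F=4.5,
            MAX_POWER=20.0, HI_POWER=-5.0, LO_POWER=-5.0, RELATIVE_POWER=0.5,
            valid_peak=True,
        )
        base.update(kw)
        return A1Features(**base)

    def test_narrow_symmetric_midband_peak_is_present(self):
        label, rep = classify_a1r([self._feat()])
        assert label == "present"
        assert rep.F_CENTER == 5.0

    @pytest.mark.parametrize(
        "kw",
        [
            {"F_CENTER": 12.0},
            {"BW": 3.0},
            {"HI_POWER": 0.0, "LO_POWER": -10.0},
            {"valid_peak": False},
        ],
    )
    def test_each_rule_violation_gives_absent(self, kw):
        label, _ = classify_a1r([self._feat(**kw)])
        assert label == "absent"

    def test_boundaries_are_inclusive(self):
        assert classify_a1r([self._feat(F_CENTER=10.0)])[0] == "present"
        assert classify_a1r([self._feat(BW=2.0)])[0] == "present"

    def test_winner_take_all_picks_largest_amplitude(self):
        small = self._feat(AMPLITUDE_MM_P_S=1.0, F_CENTER=4.0)
        big = self._feat(AMPLITUDE_MM_P_S=10.0, F_CENTER=7.0)
        label, rep = classify_a1r([small, big])
        assert label == "present"
        assert rep.F_CENTER == 7.0

    def test_amplitude_tie_breaks_to_first_marker(self):
        a = self._feat(F_CENTER=4.0)
        b = self._feat(F_CENTER=7.0)
        _, rep = classify_a1r([a, b])
        assert rep is a

    def test_empty_feature_list_raises(self):
        with pytest.raises(DataError):
            classify_a1r([])


class TestEndToEndProperties:
    @pytest.mark.parametrize("f0", [4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    def test_frequency_recovery_grid(self, tremor_factory, f0):
        # injected tremor in the 4..10 Hz clinical band, amp >= 0.5 mm,
        # small jitter: classified present with the center within one bin
        rec = tremor_factory(
            tremor_freq_hz=f0, tremor_amp_mm=0.6, jitter_sd_mm=0.05, duration_s=20.0
        )
        feats = extract_a1_for_recording(rec)
        label, rep = classify_a1r(feats)
        assert label == "present"
        assert abs(rep.F_CENTER - f0) <= 0.25  # one Welch bin at 480 samples / 120 Hz

    @pytest.mark.parametrize("vol", [[(0.5, 50.0)], [(1.9, 80.0)], [(1.0, 30.0), (2.0, 40.0)]])
    def test_pure_voluntary_motion_is_absent(self, tremor_factory, vol):
        rec = tremor_factory(
            tremor_present=False, voluntary=vol, jitter_sd_mm=0.03, duration_s=20.0
        )
        label, _ = classify_a1r(extract_a1_for_recording(rec))
        assert label == "absent"
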