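"""Preprocessing, Welch spectra, frequency landmarks and band schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lewyeeg import spectral
from lewyeeg.recording import Recording
from lewyeeg.spectral import (BAND_NAMES, BandScheme, FrequencyLandmarks,
                              RejectionCriteria)

CH8 = tuple(f"ch{i}" for i in range(8))


def make_rec(data, fs=256.0, labels=None):
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording("s1", labels, fs, data)


# ---------------------------------------------------------------------------
# standardize_recording

class TestStandardize:
    def test_common_average_property(self):
        rng = np.random.default_rng(0)
        rec = make_rec(rng.normal(size=(8, 2560)))
        out = spectral.standardize_recording(rec)
        col = np.abs(out.data.sum(axis=0))
        assert col.max() < 1e-9 * 8 * out.data.std()

    def test_resampling_preserves_10hz_sine(self):
        t = np.arange(int(512 * 4)) / 512.0
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = make_rec(np.vstack([x, -x]), fs=512.0)
        out = spectral.standardize_recording(rec)
        assert out.fs == 256.0
        assert out.data.shape[1] == 1024
        # amplitude of the 10 Hz component on channel 0, away from filter edges
        seg = out.data[0, 128:-128]
        tt = np.arange(128, 1024 - 128) / 256.0
        amp = 2 * np.abs(np.exp(-2j * np.pi * 10.0 * tt) @ seg) / len(seg)
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_60hz_attenuated_40db(self):
        t = np.arange(2560) / 256.0
        x = np.sin(2 * np.pi * 60.0 * t)
        rec = make_rec(np.vstack([x, -x]))
        out = spectral.standardize_recording(rec)
        ratio = out.data[0].std() / x.std()
        assert 20 * np.log10(ratio) < -40.0

    def test_low_sampling_rate_rejected(self):
        rec = make_rec(np.zeros((4, 1000)) + np.eye(4, 1000), fs=128.0)
        with pytest.raises(ValueError, match="256"):
            spectral.standardize_recording(rec)


# ---------------------------------------------------------------------------
# epoch_recording

class TestEpoching:
    @pytest.mark.parametrize("duration_s, expected", [
        (300.0, 150),   # 5 min of 2-s epochs
        (3.9, 1),       # trailing partial epoch discarded
        (2.0, 1),
    ])
    def test_epoch_counts(self, duration_s, expected):
        n = int(round(duration_s * 256))
        rec = make_rec(np.random.default_rng(1).normal(size=(3, n)))
        eps = spectral.epoch_recording(rec)
        assert eps.n_epochs == expected
        assert eps.data.shape[2] == 512

    def test_too_short_errors(self):
        rec = make_rec(np.zeros((3, 100)))
        with pytest.raises(ValueError, match="shorter"):
            spectral.epoch_recording(rec)


# ---------------------------------------------------------------------------
# reject_epochs

class TestRejection:
    def test_disabled_criteria_identity(self):
        rng = np.random.default_rng(2)
        rec = make_rec(rng.normal(size=(4, 512 * 20)))
        eps = spectral.epoch_recording(rec)
        out = spectral.reject_epochs(eps, RejectionCriteria(
            amp_max_uv=np.inf, var_z_max=np.inf, emg_ratio_max=np.inf))
        assert out.n_epochs == eps.n_epochs
        np.testing.assert_array_equal(out.data, eps.data)

    def test_amplitude_criterion_and_error_naming(self):
        rng = np.random.default_rng(3)
        data = rng.normal(scale=500.0, size=(4, 512 * 5))
        eps = spectral.epoch_recording(make_rec(data))
        with pytest.raises(ValueError, match="amplitude"):
            spectral.reject_epochs(eps, RejectionCriteria(
                var_z_max=np.inf, emg_ratio_max=np.inf))

    def test_clean_cohort_kept_fraction(self, lf22, space22):
        from lewyeeg import synth
        from tests.conftest import small_cohort_config

        cfg = small_cohort_config(n=1, n_epochs=20)
        profs = synth.generate_profiles(cfg, 5)
        for i, p in enumerate(profs):
            rec = synth.simulate_subject(p, lf22, space22, cfg, 100 + i)
            eps = spectral.epoch_recording(spectral.standardize_recording(rec))
            out = spectral.reject_epochs(eps)
            assert out.kept_fraction > 0.75

    def test_blink_detection_sensitivity(self, lf22, space22, healthy_profile):
        from lewyeeg import synth
        from tests.conftest import small_cohort_config

        cfg = small_cohort_config(n=1, n_epochs=40)
        rec = synth.simulate_subject(healthy_profile, lf22, space22, cfg, 9)
        art = synth.ArtifactConfig(blink_rate=0.3, blink_amp_uv=250.0)
        cont = synth.inject_artifacts(rec, art, 17)
        mask = np.asarray(cont.meta["artifact_mask"])
        eps = spectral.epoch_recording(spectral.standardize_recording(cont))
        out = spectral.reject_epochs(eps)
        rejected = ~out.kept_mask
        sens = rejected[mask].mean()
        assert sens >= 0.8


# ---------------------------------------------------------------------------
# welch_psd

class TestWelch:
    def test_on_grid_sine_peak(self):
        t = np.arange(512 * 10) / 256.0
        x = np.sin(2 * np.pi * 10.0 * t)
        eps = spectral.epoch_recording(make_rec(np.vstack([x, 2 * x, -x])))
        psd = spectral.welch_psd(eps)
        for ch in range(3):
            assert psd.freqs[np.argmax(psd.psd[ch])] == 10.0

    def test_white_noise_flat(self):
        rng = np.random.default_rng(4)
        eps = spectral.Epochs("s", rng.normal(size=(1000, 2, 512)), 256.0, 2.0)
        psd = spectral.welch_psd(eps)
        m = (psd.freqs >= 1.0) & (psd.freqs <= 40.0)
        g = psd.global_psd[m]
        assert g.max() / g.min() < 1.5

    def test_parseval(self):
        rng = np.random.default_rng(5)
        rec = make_rec(rng.normal(size=(3, 512 * 50)))
        std = spectral.standardize_recording(rec)
        eps = spectral.epoch_recording(std)
        psd = spectral.welch_psd(eps)
        for ch in range(3):
            band_power = psd.psd[ch].sum() * 0.5
            var = std.data[ch].var()
            assert band_power == pytest.approx(var, rel=0.05)

    def test_scaling_and_epoch_order_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(10, 3, 512))
        eps = spectral.Epochs("s", data, 256.0, 2.0)
        base = spectral.welch_psd(eps).psd
        scaled = spectral.welch_psd(
            spectral.Epochs("s", 3.0 * data, 256.0, 2.0)).psd
        np.testing.assert_allclose(scaled, 9.0 * base, rtol=1e-12)
        perm = spectral.welch_psd(
            spectral.Epochs("s", data[::-1], 256.0, 2.0)).psd
        np.testing.assert_allclose(perm, base, rtol=1e-12)

    def test_incompatible_resolution_errors(self):
        eps = spectral.Epochs("s", np.zeros((2, 2, 256)), 256.0, 1.0)
        with pytest.raises(ValueError, match="resolution"):
            spectral.welch_psd(eps)


# ---------------------------------------------------------------------------
# detect_landmarks

def constructed_spectrum(trough, peak):
    freqs = np.arange(1, 91) * 0.5
    g = 1.0 / freqs
    g += 2.0 * np.exp(-((freqs - peak) / 0.8) ** 2)
    g -= 0.5 * np.exp(-((freqs - trough) / 0.6) ** 2) / trough
    g = np.clip(g, 1e-6, None)
    return spectral.PowerSpectrum("s", freqs, g[None, :])


class TestLandmarks:
    def test_constructed_extrema(self):
        lm = spectral.detect_landmarks(constructed_spectrum(5.5, 9.0))
        assert (lm.tf, lm.iaf) == (5.5, 9.0)
        assert lm.valid

    def test_monotone_spectrum_flags(self):
        freqs = np.arange(1, 91) * 0.5
        ps = spectral.PowerSpectrum("s", freqs, (1.0 / freqs)[None, :])
        lm = spectral.detect_landmarks(ps)
        assert lm.iaf == 6.0
        assert "no-peak" in lm.flags and "iaf-boundary-hit" in lm.flags

    def test_scale_invariance(self):
        ps = constructed_spectrum(5.0, 10.0)
        lm1 = spectral.detect_landmarks(ps)
        ps2 = spectral.PowerSpectrum("s", ps.freqs, 37.5 * ps.psd)
        lm2 = spectral.detect_landmarks(ps2)
        assert (lm1.tf, lm1.iaf) == (lm2.tf, lm2.iaf)

    def test_non_finite_errors(self):
        freqs = np.arange(1, 91) * 0.5
        bad = np.ones_like(freqs)
        bad[10] = np.nan
        # bypass the PowerSpectrum non-negativity check with a finite array,
        # then corrupt in place
        ps = spectral.PowerSpectrum("s", freqs, np.ones((1, 90)))
        ps.psd[0, 10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            spectral.detect_landmarks(ps)


# ---------------------------------------------------------------------------
# individual_band_scheme

class TestBandScheme:
    def test_midpoint_arithmetic(self):
        lm = FrequencyLandmarks("s", 6.0, 10.0)
        b = spectral.individual_band_scheme(lm)
        assert b["alpha1"] == (6.0, 8.0)
        assert b["alpha2"] == (8.0, 10.0)
        assert b["alpha3"] == (10.0, 12.0)

    def test_healthy_low_mean_landmarks(self):
        # TF/IAF at the Healthy-Edu- subgroup means
        b = spectral.individual_band_scheme(FrequencyLandmarks("s", 5.6, 8.9))
        assert b["delta"] == pytest.approx((1.6, 3.6))
        assert b["theta"] == pytest.approx((3.6, 5.6))
        assert b["alpha1"] == pytest.approx((5.6, 7.25))
        assert b["alpha2"] == pytest.approx((7.25, 8.9))
        assert b["alpha3"] == pytest.approx((8.9, 10.9))

    def test_fixed_high_bands(self):
        b = spectral.individual_band_scheme(FrequencyLandmarks("s", 4.5, 9.5))
        assert b["beta1"] == (14.0, 20.0)
        assert b["beta2"] == (20.0, 30.0)
        assert b["gamma"] == (30.0, 40.0)

    def test_invalid_ordering_errors(self):
        with pytest.raises(ValueError, match="partition"):
            spectral.individual_band_scheme(FrequencyLandmarks("s", 8.0, 7.0))

    def test_delta_clipped_at_grid_start(self):
        b = spectral.individual_band_scheme(FrequencyLandmarks("s", 4.0, 9.0))
        assert b["delta"][0] == 0.5
        assert "delta-low-clipped" in b.flags

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(tf=st.floats(4.2, 7.9), gap=st.floats(0.2, 6.0))
    def test_partition_properties(self, tf, gap):
        iaf = min(tf + gap, 14.0)
        b = spectral.individual_band_scheme(FrequencyLandmarks("s", tf, iaf))
        order = ["delta", "theta", "alpha1", "alpha2", "alpha3"]
        for a, c in zip(order, order[1:]):
            assert b[a][1] == pytest.approx(b[c][0])   # contiguous
        for name in BAND_NAMES:
            lo, hi = b[name]
            assert hi > lo
        w1 = b["alpha1"][1] - b["alpha1"][0]
        w2 = b["alpha2"][1] - b["alpha2"][0]
        assert w1 == pytest.approx(w2)
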