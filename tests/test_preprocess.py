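"""Optical-density conversion, channel quality, motion detection, modified
Beer-Lambert, band-pass filtering, short-separation regression."""

import numpy as np
import pytest

from nirslayout import beerlambert, preprocess
from nirslayout.hrf import double_gamma_hrf, task_regressor

FS = 7.8125


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self):
        od = preprocess.intensity_to_od(np.full((2, 100), 3.0))
        np.testing.assert_allclose(od, 0.0)

    def test_single_sample_matches_definition(self):
        x = np.ones(100)
        x[10] = np.exp(-0.2)
        # referencing uses the series mean, so compute the expected OD directly
        od = preprocess.intensity_to_od(x)
        expected = -np.log(x / x.mean())
        np.testing.assert_allclose(od, expected)
        assert od[10] > od[0]

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(size=200)) + 0.5
        od = preprocess.intensity_to_od(x)
        back = x.mean() * np.exp(-od)
        np.testing.assert_allclose(back, x, rtol=1e-12)

    def test_nonpositive_samples_rejected(self):
        x = np.ones((2, 50))
        x[1, 3] = 0.0
        with pytest.raises(ValueError, match="channel"):
            preprocess.intensity_to_od(x)


class TestChannelQuality:
    def test_constant_channel_retained_with_zero_cv(self):
        q = preprocess.compute_cv_and_filter(np.full((1, 2, 50), 2.0))
        assert q.cv_percent[0, 0] == 0.0 and q.retained[0]

    def test_hand_computed_cv(self):
        x = np.array([90.0, 100.0, 110.0, 100.0])
        q = preprocess.compute_cv_and_filter(x[None, None, :])
        expected = 100.0 * np.std(x, ddof=1) / np.mean(x)
        assert q.cv_percent[0, 0] == pytest.approx(expected)

    def test_cv_exactly_at_threshold_is_discarded(self):
        # build a two-sample series with CV exactly 7.5%
        m, cv = 100.0, 7.5
        sd = cv * m / 100.0
        x = np.array([m - sd / np.sqrt(2) * np.sqrt(2),
                      m + sd / np.sqrt(2) * np.sqrt(2)])
        # two samples: sd(ddof=1) = |x1-x0|/sqrt(2)
        x = np.array([m - sd * np.sqrt(2) / 2, m + sd * np.sqrt(2) / 2])
        q = preprocess.compute_cv_and_filter(x[None, None, :])
        assert q.cv_percent[0, 0] == pytest.approx(7.5)
        assert not q.retained[0]

    def test_either_wavelength_failing_discards_channel(self):
        good = 100.0 + np.sin(np.arange(100))
        bad = 100.0 + 40.0 * np.sin(np.arange(100))
        inten = np.stack([np.stack([good, bad])])
        q = preprocess.compute_cv_and_filter(inten)
        assert not q.retained[0]


class TestMotionDetection:
    def test_clean_sinusoid_has_empty_mask(self):
        t = np.arange(500) / FS
        x = 0.01 * np.sin(2 * np.pi * 0.1 * t)
        mask = preprocess.detect_motion_artifacts(x[None], FS, std_thresh=50,
                                                  amp_thresh=5)
        assert not mask.any()

    def test_injected_step_is_flagged_near_step(self):
        rng = np.random.default_rng(1)
        x = 0.001 * rng.normal(size=600)
        x[300:] += 10 * np.std(x)
        mask = preprocess.detect_motion_artifacts(x[None], FS, std_thresh=5,
                                                  amp_thresh=5)[0]
        assert mask[295:305].any()
        pad = int(round(1.0 * FS)) + int(round(0.5 * FS)) + 1
        assert not mask[:300 - pad - 1].any()
        assert not mask[300 + pad + 1:].any()

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        x = 0.01 * rng.normal(size=400)
        x[100:] += 0.3
        a = preprocess.detect_motion_artifacts(x[None], FS, std_thresh=8,
                                               amp_thresh=0.2)
        b = preprocess.detect_motion_artifacts(x[None] + 5.0, FS, std_thresh=8,
                                               amp_thresh=0.2)
        np.testing.assert_array_equal(a, b)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self):
        hbo, hbr = preprocess.od_to_concentration(np.zeros((1, 2, 10)), 30.0, 30.0)
        np.testing.assert_allclose(hbo, 0.0)
        np.testing.assert_allclose(hbr, 0.0)

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(3)
        hbo = rng.normal(size=50)
        hbr = rng.normal(size=50)
        od = beerlambert.concentration_to_od(hbo, hbr, 32.0, 28.0)
        hbo2, hbr2 = beerlambert.od_to_concentration_pair(od, 32.0, 28.0)
        np.testing.assert_allclose(hbo2, hbo, atol=1e-9)
        np.testing.assert_allclose(hbr2, hbr, atol=1e-9)

    def test_dpf_decreases_with_wavelength(self):
        assert beerlambert.dpf(760.0, 30.0) > beerlambert.dpf(850.0, 30.0)

    def test_dpf_plausible_adult_range(self):
        for wl in (760.0, 850.0):
            assert 4.0 < beerlambert.dpf(wl, 29.81) < 8.0

    def test_age_bounds_enforced(self):
        with pytest.raises(ValueError):
            beerlambert.dpf(760.0, 130.0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            beerlambert.od_to_concentration_pair(np.zeros((2, 5)), 0.0, 30.0)


class TestBandpass:
    def test_in_band_tone_preserved_with_zero_lag(self):
        n = 4000
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        y = preprocess.bandpass_filter(x, FS)
        core = slice(500, -500)
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.05)
        lag = np.argmax(np.correlate(y[core], x[core], mode="full")) - \
            (len(x[core]) - 1)
        assert lag == 0

    def test_dc_strongly_attenuated(self):
        # the 0.008 Hz low edge at order 1000 leaves a small DC leak
        # (transition width ~ fs/order); require > 19 dB suppression
        y = preprocess.bandpass_filter(np.full(4000, 5.0), FS)
        assert np.abs(y[500:-500]).max() < 5.0 * 10 ** (-19 / 20)

    def test_out_of_band_tone_attenuated(self):
        n = 4000
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = preprocess.bandpass_filter(x, FS)
        atten_db = 20 * np.log10(np.abs(y[500:-500]).max())
        assert atten_db < -20

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            preprocess.bandpass_filter(np.zeros(100), FS, order=1000)


class TestShortChannelRegression:
    def test_perfect_scaling_removed(self):
        rng = np.random.default_rng(4)
        sdc = rng.normal(size=500)
        ndc = 0.8 * sdc
        resid = preprocess.short_channel_regress(ndc, sdc)
        assert np.linalg.norm(resid - resid.mean()) / np.linalg.norm(ndc) < 1e-10

    def test_residual_orthogonal_to_regressor(self):
        rng = np.random.default_rng(5)
        sdc = rng.normal(size=300)
        ndc = rng.normal(size=300)
        resid = preprocess.short_channel_regress(ndc, sdc)
        s = sdc - sdc.mean()
        assert abs((resid - resid.mean()) @ s) < 1e-8 * np.linalg.norm(s)

    def test_recovers_hrf_orthogonal_to_superficial(self):
        fs = FS
        n = 1000
        hrf_course = task_regressor([20.0, 60.0], [10.0, 10.0], fs, n,
                                    hrf=double_gamma_hrf(fs))
        rng = np.random.default_rng(6)
        sdc = rng.normal(size=n)
        s = sdc - sdc.mean()
        h = hrf_course - hrf_course.mean()
        h_perp = h - (h @ s) / (s @ s) * s  # exactly orthogonal component
        ndc = h_perp + 0.8 * s
        resid = preprocess.short_channel_regress(ndc, sdc)
        rmse = np.sqrt(np.mean((resid - resid.mean() - h_perp) ** 2))
        assert rmse < 0.01 * np.std(h_perp)

    def test_zero_variance_sdc_returns_ndc_unchanged(self):
        ndc = np.sin(np.arange(100) * 0.1)
        out = preprocess.short_channel_regress(ndc, np.full(100, 2.0))
        np.testing.assert_array_equal(out, ndc)


class TestPipelineOrder:
    def test_stage_order_is_logged(self):
        rng = np.random.default_rng(7)
        n = 900
        inten = 1.0 + 0.001 * rng.normal(size=(3, 2, n))
        pipe = preprocess.PreprocessingPipeline(filter_order=250)
        out = pipe.run(inten, FS, [30.0, 30.0, 8.0], 30.0, sdc_for_ndc={0: 2, 1: 2})
        joined = " | ".join(out.log_lines)
        order = ["OD", "CV", "motion", "Beer-Lambert", "short-separation",
                 "band-pass"]
        idx = [joined.find(token) for token in order]
        assert all(i >= 0 for i in idx)
        assert idx == sorted(idx)

    def test_cv_filter_does_not_alter_data(self):
        rng = np.random.default_rng(8)
        inten = 1.0 + 0.001 * rng.normal(size=(2, 2, 900))
        pipe = preprocess.PreprocessingPipeline(filter_order=250, apply_ssr=False)
        out = pipe.run(inten, FS, [30.0, 30.0], 30.0)
        od = preprocess.intensity_to_od(inten)
        hbo, hbr = preprocess.od_to_concentration(od, [30.0, 30.0], 30.0)
        np.testing.assert_allclose(out.hbo_um, hbo)
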