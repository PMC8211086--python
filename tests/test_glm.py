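"""Design matrices, AR-prewhitened GLM, ROI statistics, block averages, CNR."""

import numpy as np
import pytest

from conftest import mini_setup
from nirslayout import glm, preprocess
from nirslayout.simulate import TruthConfig, generate_schedule, simulate_recording

FS = 7.8125
TASKS = ("mental_calculation", "mental_rotation")


@pytest.fixture(scope="module")
def schedule():
    return generate_schedule(n_runs=2, n_trials_per_task_per_run=4,
                             tasks=TASKS, seed=0)


class TestDesignMatrix:
    def test_dct_column_count_matches_enumeration(self):
        for n, fs, cutoff in [(3000, FS, 0.009), (1500, 10.0, 0.01),
                              (800, 4.0, 0.02)]:
            dct = glm.dct_basis(n, fs, cutoff)
            dt = 1.0 / fs
            expected = sum(1 for k in range(1, n)
                           if k / (2 * n * dt) < cutoff)
            assert dct.shape[1] == expected

    def test_task_peak_lags_onset_by_hrf_peak(self, schedule):
        n = schedule.run_samples(0)
        dm = glm.build_design_matrix(schedule, 0, FS, n)
        col = dm.X[:, dm.task_columns[TASKS[0]]]
        first = schedule.trials_for(0, TASKS[0])[0]
        i0 = int(round(first.onset_s * FS))
        # peak of the first isolated response: scan a window after onset
        window = col[i0:i0 + int(25 * FS)]
        lag_s = np.argmax(window) / FS
        # 10-s boxcar * double-gamma peaks near onset + ~6 s HRF delay + half
        # the boxcar rise; just require the peak inside a physiological band
        assert 6.0 <= lag_s <= 14.0

    def test_zero_trial_task_column_dropped(self):
        sched = generate_schedule(n_runs=1, n_trials_per_task_per_run=3,
                                  tasks=("mental_calculation",), seed=1)
        n = sched.run_samples(0)
        dm = glm.build_design_matrix(sched, 0, FS, n)
        assert "mental_calculation" in dm.task_columns
        assert all(not lbl.startswith("task:mental_rotation")
                   for lbl in dm.labels)

    def test_hbr_scaling_flips_and_scales_task_columns(self, schedule):
        n = schedule.run_samples(0)
        dm = glm.build_design_matrix(schedule, 0, FS, n)
        dm_hbr = dm.scaled_for_hbr(-1.0 / 3.0)
        for task, col in dm.task_columns.items():
            np.testing.assert_allclose(dm_hbr.X[:, col], -dm.X[:, col] / 3.0)


class TestFitArGlm:
    def test_noise_free_recovery_is_exact(self, schedule):
        n = schedule.run_samples(0)
        dm = glm.build_design_matrix(schedule, 0, FS, n)
        beta0 = np.arange(1.0, dm.X.shape[1] + 1)
        y = dm.X @ beta0
        res = glm.fit_ar_glm(y, dm.X, fs=FS)
        np.testing.assert_allclose(res.beta, beta0, rtol=1e-8)

    def test_whitened_residuals_are_white(self, schedule):
        rng = np.random.default_rng(2)
        n = schedule.run_samples(0)
        dm = glm.build_design_matrix(schedule, 0, FS, n)
        # AR(1) noise
        e = rng.normal(size=n)
        noise = np.zeros(n)
        for t in range(1, n):
            noise[t] = 0.8 * noise[t - 1] + e[t]
        y = 0.5 * dm.X[:, 0] + noise
        res = glm.fit_ar_glm(y, dm.X, fs=FS)
        r = res.whitened_resid
        r1 = np.corrcoef(r[:-1], r[1:])[0, 1]
        assert abs(r1) < 2 / np.sqrt(r.size)

    def test_ar_estimator_matches_statsmodels_burg(self):
        from statsmodels.regression.linear_model import burg as sm_burg

        rng = np.random.default_rng(3)
        e = rng.normal(size=4000)
        x = np.zeros_like(e)
        for t in range(2, x.size):
            x[t] = 0.5 * x[t - 1] + 0.2 * x[t - 2] + e[t]
        coeffs, order = glm.estimate_ar(x, max_order=6)
        assert order >= 2
        rho, _ = sm_burg(x - x.mean(), order=order)
        np.testing.assert_allclose(coeffs, rho, atol=1e-6)

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            glm.fit_ar_glm(np.zeros(50), np.ones((50, 2)), max_order=60)


class TestROIContrast:
    def test_hand_built_covariance_example(self):
        st = glm.roi_contrast(np.array([3.0, 1.0]),
                              np.array([[4.0, 2.0], [2.0, 4.0]]),
                              np.array([0.5, 0.5]), dof=100)
        assert st.beta_roi == pytest.approx(2.0)
        assert st.cov_roi == pytest.approx(3.0)
        assert st.t == pytest.approx(2.0 / np.sqrt(3.0))

    def test_single_unit_contrast_equals_channel_statistic(self):
        st = glm.roi_contrast(np.array([1.7]), np.array([[0.25]]),
                              np.array([1.0]), dof=50)
        assert st.beta_roi == pytest.approx(1.7)
        assert st.t == pytest.approx(1.7 / 0.5)

    def test_equal_beta_uncorrelated_variance(self):
        st = glm.roi_contrast(np.array([2.0, 2.0]),
                              np.diag([0.5, 0.5]), np.array([0.5, 0.5]),
                              dof=40)
        assert st.beta_roi == pytest.approx(2.0)
        assert st.cov_roi == pytest.approx(0.25)


class TestMultirun:
    def _simulate_and_preprocess(self, noise_sd=1e-3, n_runs=2, seed=0,
                                 amp_sens=15.0, superficial=0.0):
        setup = mini_setup()
        sched = generate_schedule(n_runs=n_runs, n_trials_per_task_per_run=4,
                                  tasks=TASKS, seed=seed)
        cfg = TruthConfig(noise_sd_od=noise_sd, superficial_hbo_um=superficial,
                          superficial_hbr_um=-superficial / 3,
                          superficial_channel_um=0.0, spike_rate_per_min=0.0,
                          shift_rate_per_min=0.0)
        sens = {(0, TASKS[0]): amp_sens, (1, TASKS[0]): amp_sens}
        rec, truth = simulate_recording(setup, sched, cfg, seed=seed,
                                        channel_task_sensitivity=sens)
        pipe = preprocess.PreprocessingPipeline(filter_order=250)
        runs = [pipe.run(rec.intensity[r], FS,
                         [c["distance_mm"] for c in setup.channels],
                         rec.age_years, setup.sdc_for_ndc())
                for r in range(n_runs)]
        designs = [glm.build_design_matrix(sched, r, FS, sched.run_samples(r))
                   for r in range(n_runs)]
        return setup, sched, truth, runs, designs

    def test_single_run_reduces_to_single_run_statistic(self):
        _, _, _, runs, designs = self._simulate_and_preprocess(n_runs=1)
        fit = glm.fit_multirun_channel([runs[0].hbo_um[0]], [designs[0]], FS,
                                       max_order=8)
        single = glm.fit_ar_glm(runs[0].hbo_um[0], designs[0].X, max_order=8,
                                fs=FS)
        col = designs[0].task_columns[TASKS[0]]
        assert fit.beta_task[TASKS[0]] == pytest.approx(single.beta[col],
                                                        rel=1e-6)
        assert fit.var_task[TASKS[0]] == pytest.approx(
            single.cov_beta[col, col], rel=1e-6)

    def test_multirun_roi_statistic(self):
        _, _, truth, runs, designs = self._simulate_and_preprocess()
        fits = [glm.fit_multirun_channel([r.hbo_um[k] for r in runs], designs,
                                         FS, max_order=8) for k in (0, 1)]
        st = glm.multirun_roi_stats(fits, TASKS[0])
        amp = truth.amplitudes_um[(0, TASKS[0])]
        assert st.beta_roi == pytest.approx(amp, rel=0.05)
        assert st.t > 10

    def test_cv_rejected_channel_falls_back_to_survivor(self):
        _, _, _, runs, designs = self._simulate_and_preprocess()
        fits = [glm.fit_multirun_channel([r.hbo_um[k] for r in runs], designs,
                                         FS, max_order=8) for k in (0, 1)]
        st = glm.multirun_roi_stats(fits, TASKS[0], retained=[True, False])
        np.testing.assert_array_equal(st.contrast, [1.0])
        assert st.beta_roi == pytest.approx(fits[0].beta_task[TASKS[0]])

    def test_t_monotone_in_injected_amplitude(self):
        ts = []
        for sens in (5.0, 15.0, 30.0):
            _, _, _, runs, designs = self._simulate_and_preprocess(
                noise_sd=2e-3, seed=11, amp_sens=sens)
            fit = glm.fit_multirun_channel([r.hbo_um[0] for r in runs],
                                           designs, FS, max_order=8)
            ts.append(fit.beta_task[TASKS[0]] /
                      np.sqrt(fit.var_task[TASKS[0]]))
        assert ts[0] <= ts[1] <= ts[2]

    def test_ssr_reduces_amplitude_bias(self):
        """Superficial contamination biases the GLM beta; short-separation
        regression must reduce the median relative error."""
        errs = {True: [], False: []}
        n_runs = 3
        for seed in range(6):
            setup = mini_setup()
            sched = generate_schedule(n_runs=n_runs,
                                      n_trials_per_task_per_run=4,
                                      tasks=TASKS, seed=seed)
            cfg = TruthConfig(noise_sd_od=1e-3, superficial_hbo_um=1.0,
                              superficial_hbr_um=-0.33,
                              superficial_channel_um=0.0,
                              spike_rate_per_min=0.0, shift_rate_per_min=0.0)
            sens = {(0, TASKS[0]): 25.0}
            rec, truth = simulate_recording(setup, sched, cfg, seed=seed,
                                            channel_task_sensitivity=sens)
            amp = truth.amplitudes_um[(0, TASKS[0])]
            designs = [glm.build_design_matrix(sched, r, FS,
                                               sched.run_samples(r))
                       for r in range(n_runs)]
            for use_ssr in (True, False):
                pipe = preprocess.PreprocessingPipeline(filter_order=250,
                                                        apply_ssr=use_ssr)
                runs = [pipe.run(rec.intensity[r], FS,
                                 [c["distance_mm"] for c in setup.channels],
                                 rec.age_years, setup.sdc_for_ndc())
                        for r in range(n_runs)]
                fit = glm.fit_multirun_channel([r.hbo_um[0] for r in runs],
                                               designs, FS, max_order=8)
                b = fit.beta_task[TASKS[0]]
                errs[use_ssr].append(abs(b - amp) / amp)
        assert np.median(errs[True]) < 0.10
        assert np.median(errs[True]) < np.median(errs[False])


class TestBlockAverageAndCNR:
    def test_constant_signal_averages_to_zero(self, schedule):
        n = schedule.run_samples(0)
        conc = [np.full(n, 3.7), np.full(schedule.run_samples(1), 3.7)]
        ba = glm.block_average(conc, schedule, TASKS[0], FS)
        np.testing.assert_allclose(ba.mean, 0.0, atol=1e-12)

    def test_window_sample_count(self, schedule):
        conc = [np.zeros(schedule.run_samples(r)) for r in range(2)]
        ba = glm.block_average(conc, schedule, TASKS[0], FS)
        assert ba.mean.size == int(round(29 * FS))
        assert ba.time_s[int(round(4 * FS))] == pytest.approx(0.0)

    def test_averaging_reduces_noise_variance(self, schedule):
        rng = np.random.default_rng(9)
        ratios = []
        n_trials = sum(len(schedule.trials_for(r, TASKS[0])) for r in range(2))
        for _ in range(60):
            conc = [rng.normal(size=schedule.run_samples(r)) for r in range(2)]
            ba = glm.block_average(conc, schedule, TASKS[0], FS)
            ratios.append(np.var(ba.mean))
        assert np.mean(ratios) == pytest.approx(1.0 / n_trials, rel=0.3)

    def test_cnr_of_identical_windows_is_zero(self):
        t = np.linspace(-4, 25, 227)
        block = glm.BlockAverage(time_s=t, mean=np.ones_like(t), n_trials=5,
                                 task="x", fs=FS)
        assert glm.compute_cnr(block) == 0.0

    def test_cnr_hand_arithmetic(self):
        time = np.array([-4.0, -3.0, -2.0, -1.0, 6.0, 8.0, 10.0, 12.0])
        mean = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 3.0, 3.0])
        block = glm.BlockAverage(time_s=time, mean=mean, n_trials=4, task="x",
                                 fs=1.0)
        assert glm.compute_cnr(block) == pytest.approx(2.0 / np.sqrt(4.0 / 3.0))

    def test_cnr_scale_invariance(self):
        rng = np.random.default_rng(10)
        t = np.linspace(-4, 25, 227)
        block = glm.BlockAverage(time_s=t, mean=rng.normal(size=t.size),
                                 n_trials=5, task="x", fs=FS)
        a = glm.compute_cnr(block)
        block.mean = 7.3 * block.mean
        assert glm.compute_cnr(block) == pytest.approx(a)
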