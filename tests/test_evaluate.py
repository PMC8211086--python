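"""Group statistics, cortical projection, fMRI agreement, subject models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import fast_study_config
from nirslayout import evaluate, phantom
from nirslayout.design import APPROACHES


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        vals = np.tile(np.arange(5.0)[:, None], (1, 4))
        stat, dof, p = evaluate.friedman_test(vals)
        assert stat == 0.0 and p == 1.0 and dof == 3

    def test_toy_table_matches_permutation_oracle(self):
        vals = np.array([[1.0, 2.0, 3.0],
                         [2.0, 3.0, 1.0],
                         [1.0, 3.0, 2.0],
                         [1.0, 2.0, 3.0]])
        stat, dof, p = evaluate.friedman_test(vals)
        # oracle: enumerate all within-row rank permutations for the exact
        # null distribution of the Friedman statistic
        n, k = vals.shape

        def fr_stat(rank_rows):
            R = np.sum(rank_rows, axis=0)
            return 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3 * n * (k + 1)

        observed_ranks = np.array([np.argsort(np.argsort(r)) + 1 for r in vals])
        assert stat == pytest.approx(fr_stat(observed_ranks))
        null = []
        for perms in itertools.product(itertools.permutations([1, 2, 3]),
                                       repeat=n):
            null.append(fr_stat(np.array(perms)))
        exact_p = np.mean(np.array(null) >= stat - 1e-12)
        # the implementation reports the asymptotic chi-square p; at n=4 the
        # exact permutation p is coarser but both must sit on the same side
        # of conventional significance
        assert 0 < p < 1 and 0 < exact_p < 1
        assert (p < 0.05) == (exact_p < 0.05)

    def test_row_shift_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 4))
        stat1, _, _ = evaluate.friedman_test(vals)
        shifted = vals.copy()
        shifted[2] += 100.0
        stat2, _, _ = evaluate.friedman_test(shifted)
        assert stat1 == pytest.approx(stat2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            evaluate.friedman_test(np.ones((2, 4)))


class TestWilcoxonBH:
    def test_bh_step_up_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])

    def test_all_positive_differences_exact_p(self):
        # 8 paired differences, all favoring the informed approach: the
        # exact one-sided signed-rank p is 1/256
        vals = np.zeros((8, 4))
        vals[:, 1:] = 1.0  # PROB/iFMRI/fVASC beat LIT in every subject
        vals += np.arange(8)[:, None]  # subject offsets (rank-invariant)
        df = evaluate.pairwise_wilcoxon_bh(vals, APPROACHES)
        row = df[(df.better == "PROB") & (df.worse == "LIT")].iloc[0]
        assert row.p == pytest.approx(1.0 / 256.0)

    def test_all_zero_differences_give_p_one(self):
        vals = np.tile(np.arange(5.0)[:, None], (1, 4))
        df = evaluate.pairwise_wilcoxon_bh(vals, APPROACHES)
        assert (df.p == 1.0).all() and (df.q == 1.0).all()

    def test_q_never_below_p_and_order_preserved(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 4))
        df = evaluate.pairwise_wilcoxon_bh(vals, APPROACHES)
        assert (df.q >= df.p - 1e-12).all()
        order_p = df.sort_values("p").index
        assert (df.loc[order_p, "q"].diff().dropna() >= -1e-12).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                    max_size=12))
    def test_bh_matches_independent_step_up(self, ps):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(ps, method="fdr_bh")
        # independent step-up implementation
        p = np.asarray(ps)
        m = p.size
        order = np.argsort(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestPercentSignificant:
    def _frame(self, ps):
        return pd.DataFrame([
            {"subject": f"S{i}", "approach": "iFMRI", "task": "mc",
             "chromophore": "HbO", "p_one": p} for i, p in enumerate(ps)])

    def test_all_significant(self):
        out = evaluate.percent_significant(self._frame([0.01] * 6))
        assert out.percent.iloc[0] == 100.0

    def test_none_significant(self):
        out = evaluate.percent_significant(self._frame([0.5] * 6))
        assert out.percent.iloc[0] == 0.0

    def test_half_significant(self):
        out = evaluate.percent_significant(self._frame([0.01] * 7 + [0.9] * 7))
        assert out.percent.iloc[0] == 50.0


class TestProjection:
    def test_weights_sum_to_one_and_constant_map_preserved(self, onion):
        mid = np.array([*onion.center_xy, 25.0])
        w = evaluate.project_channel_to_cortex(mid, onion, radius_mm=20.0)
        assert w.weights.sum() == pytest.approx(1.0)
        tmap = np.zeros(onion.shape)
        tmap[onion.tissue_mask("gray_matter")] = 3.0
        avg, peak, _ = evaluate.fnirs_fmri_agreement(w, tmap)
        assert avg == pytest.approx(3.0)
        assert peak == pytest.approx(3.0)

    def test_voxels_beyond_radius_excluded(self, onion):
        mid = np.array([*onion.center_xy, 25.0])
        w = evaluate.project_channel_to_cortex(mid, onion, radius_mm=15.0)
        coords = onion.voxel_centers_mm(w.voxels)
        assert np.linalg.norm(coords - mid, axis=1).max() <= 15.0

    def test_equidistant_voxels_get_equal_weight(self, onion):
        mid = np.array([*onion.center_xy, 25.0])
        w = evaluate.project_channel_to_cortex(mid, onion, radius_mm=20.0)
        coords = onion.voxel_centers_mm(w.voxels)
        d = np.linalg.norm(coords - mid, axis=1)
        i, j = 0, int(np.argmin(np.abs(d - d[0])[1:]) + 1)
        if abs(d[i] - d[j]) < 1e-9:
            assert w.weights[i] == pytest.approx(w.weights[j])

    def test_correlation_of_identical_and_negated_series(self, onion):
        mid = np.array([*onion.center_xy, 25.0])
        w = evaluate.project_channel_to_cortex(mid, onion, radius_mm=20.0)
        tmap = np.zeros(onion.shape)
        t = np.linspace(-4, 25, 100)
        y = np.sin(t / 4)
        _, _, r = evaluate.fnirs_fmri_agreement(w, tmap, (t, y), (t, y))
        assert r == pytest.approx(1.0)
        _, _, r = evaluate.fnirs_fmri_agreement(w, tmap, (t, y), (t, -y))
        assert r == pytest.approx(-1.0)


@pytest.fixture(scope="module")
def cohort3():
    cfg = fast_study_config(n_subjects=3, vasculature_density=0.0)
    subjects = evaluate.build_cohort(cfg, seed=5)
    return cfg, subjects


class TestApproachStructure:
    def test_fvasc_without_vessels_equals_ifmri(self, cohort3):
        cfg, subjects = cohort3
        layouts = evaluate.design_subject_layouts(subjects[0], cfg)
        for task in cfg.tasks:
            a = layouts[("fVASC", task)]
            b = layouts[("iFMRI", task)]
            assert [c.pair for c in a.channels] == [c.pair for c in b.channels]

    def test_lit_layout_is_subject_independent(self, cohort3):
        cfg, subjects = cohort3
        lay = [evaluate.design_subject_layouts(s, cfg,
                                               tasks=(cfg.tasks[0],))
               for s in subjects[:2]]
        a = lay[0][("LIT", cfg.tasks[0])]
        b = lay[1][("LIT", cfg.tasks[0])]
        assert [c.pair for c in a.channels] == [c.pair for c in b.channels]

    def test_three_optodes_per_approach_layout(self, cohort3):
        cfg, subjects = cohort3
        layouts = evaluate.design_subject_layouts(subjects[0], cfg)
        for layout in layouts.values():
            assert len(layout.optode_indices) == 3
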