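"""Cohort-level comparison of the four layout-design approaches, cortical
projection, synthetic-fMRI agreement, and the full-study orchestrator.

Group differences in CNR and ROI t-values are assessed with a Friedman test
over the four approaches followed by one-sided Wilcoxon signed-rank tests
per approach pair (direction: the more-informed approach of the pair is
expected to score higher), Benjamini-Hochberg corrected within each family
of pairs.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import design, glm, phantom, preprocess, simulate, transport
from .design import APPROACHES
from .io import StudyConfig, derive_seed

__all__ = [
    "friedman_test",
    "pairwise_wilcoxon_bh",
    "percent_significant",
    "ProjectionWeights",
    "project_channel_to_cortex",
    "synthetic_fmri_tmap",
    "fnirs_fmri_agreement",
    "SubjectModel",
    "ComparisonReport",
    "run_full_study",
]

log = logging.getLogger(__name__)

#: informedness ordering used for the one-sided test direction
_INFORMEDNESS = {a: i for i, a in enumerate(APPROACHES)}


def friedman_test(values: np.ndarray):
    """Friedman rank test across approach columns; rows with missing cells
    are dropped (logged).  Returns (statistic, dof, p)."""
    values = np.asarray(values, dtype=float)
    ok = np.all(np.isfinite(values), axis=1)
    if not ok.all():
        log.info("Friedman: dropping %d incomplete rows", int((~ok).sum()))
    values = values[ok]
    if values.shape[0] < 3:
        raise ValueError("Friedman test needs at least 3 complete rows")
    if values.shape[1] < 3:
        raise ValueError("Friedman test needs at least 3 groups")
    if np.allclose(values, values[:, [0]]):
        return 0.0, values.shape[1] - 1, 1.0
    stat, p = stats.friedmanchisquare(*values.T)
    return float(stat), values.shape[1] - 1, float(p)


def pairwise_wilcoxon_bh(values: np.ndarray, approaches=APPROACHES,
                         alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank test per approach pair with BH step-up
    correction across the family of pairs.

    ``values`` is subjects x approaches; for each pair the alternative is
    that the more-informed approach exceeds the less-informed one.  An
    all-zero difference yields p = 1.
    """
    from statsmodels.stats.multitest import multipletests

    values = np.asarray(values, dtype=float)
    rows = []
    for i, j in itertools.combinations(range(len(approaches)), 2):
        lo, hi = (i, j) if _INFORMEDNESS[approaches[i]] < \
            _INFORMEDNESS[approaches[j]] else (j, i)
        diff = values[:, hi] - values[:, lo]
        diff = diff[np.isfinite(diff)]
        if diff.size == 0 or np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff, alternative="greater",
                                     method="auto").pvalue)
        rows.append({"better": approaches[hi], "worse": approaches[lo],
                     "p": p, "n": int(diff.size)})
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    df["q"] = q
    return df


def percent_significant(roi_stats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Percent of subjects with a one-sided p below alpha (expected
    direction: positive activation), per approach x task x chromophore."""
    def frac(g):
        return 100.0 * float((g["p_one"] < alpha).sum()) / len(g)

    out = (roi_stats.groupby(["approach", "task", "chromophore"])
           .apply(frac, include_groups=False).rename("percent").reset_index())
    return out


# ---------------------------------------------------------------------------
# Cortical projection and fMRI agreement
# ---------------------------------------------------------------------------

@dataclass
class ProjectionWeights:
    voxels: np.ndarray  # (n, 3) indices
    weights: np.ndarray  # sum to 1
    radius_mm: float
    center_mm: np.ndarray


def project_channel_to_cortex(midpoint_mm, head: phantom.HeadPhantom,
                              radius_mm: float = 20.0) -> ProjectionWeights:
    """Inverse-distance weights over gray-matter voxels within a sphere
    centred at the channel's scalp midpoint."""
    center = np.asarray(midpoint_mm, dtype=float)
    gm = np.argwhere(head.tissue_mask("gray_matter"))
    coords = head.voxel_centers_mm(gm)
    d = np.linalg.norm(coords - center[None, :], axis=1)
    inside = d <= radius_mm
    if not inside.any():
        log.warning("no gray-matter voxel within %.0f mm of %s", radius_mm, center)
        return ProjectionWeights(voxels=np.empty((0, 3), int),
                                 weights=np.empty(0), radius_mm=radius_mm,
                                 center_mm=center)
    w = 1.0 / np.maximum(d[inside], 1e-6)
    w = w / w.sum()
    return ProjectionWeights(voxels=gm[inside], weights=w,
                             radius_mm=radius_mm, center_mm=center)


def synthetic_fmri_tmap(head: phantom.HeadPhantom, roi_center_mm,
                        peak_t: float = 8.0, sigma_mm: float = 10.0,
                        noise_sd: float = 0.5, seed: int = 0) -> np.ndarray:
    """Spatial t-field peaking at the true ROI center and decaying with a
    Gaussian profile over gray matter, plus voxel noise.  Stands in for a
    first-level activation map without simulating BOLD time series."""
    rng = np.random.default_rng(seed)
    tmap = np.zeros(head.shape)
    gm = np.argwhere(head.tissue_mask("gray_matter"))
    coords = head.voxel_centers_mm(gm)
    d = np.linalg.norm(coords - np.asarray(roi_center_mm)[None, :], axis=1)
    vals = peak_t * np.exp(-(d**2) / (2 * sigma_mm**2)) + \
        rng.normal(scale=noise_sd, size=d.size)
    tmap[gm[:, 0], gm[:, 1], gm[:, 2]] = vals
    return tmap


def fnirs_fmri_agreement(weights: ProjectionWeights, tmap: np.ndarray,
                         fnirs_block=None, fmri_block=None):
    """(weighted average t, peak t, Pearson r of the block time courses).

    The fMRI block is linearly resampled onto the fNIRS time grid; with a
    zero-variance series the correlation is undefined and returned as NaN.
    """
    if weights.weights.size == 0:
        raise ValueError("empty projection weights")
    vals = tmap[weights.voxels[:, 0], weights.voxels[:, 1], weights.voxels[:, 2]]
    avg_t = float(weights.weights @ vals)
    peak_t = float(vals.max())
    r = np.nan
    if fnirs_block is not None and fmri_block is not None:
        t_f, y_f = fnirs_block
        t_m, y_m = fmri_block
        y_mi = np.interp(t_f, t_m, y_m)
        if np.std(y_f) == 0 or np.std(y_mi) == 0:
            log.warning("zero-variance series; correlation undefined")
        else:
            r = float(stats.pearsonr(y_f, y_mi).statistic)
    return avg_t, peak_t, r


# ---------------------------------------------------------------------------
# Subject models
# ---------------------------------------------------------------------------

@dataclass
class SubjectModel:
    """Everything layout design needs for one subject."""

    subject_id: str
    head: phantom.HeadPhantom
    vasc_head: phantom.HeadPhantom
    atlas_head: phantom.HeadPhantom
    positions: phantom.ScalpPositionSet
    rois: dict  # task -> {"individual","probabilistic"} maps (subject grid)
    atlas_rois: dict  # task -> anatomical ROIMap (atlas grid)
    engines: dict = field(default_factory=dict)
    roi_centers_mm: dict = field(default_factory=dict)

    def engine_for(self, approach: str) -> transport.SensitivityEngine:
        key = {"LIT": "atlas", "PROB": "standard", "iFMRI": "standard",
               "fVASC": "vasc"}[approach]
        return self.engines[key]

    def roi_for(self, approach: str, task: str) -> phantom.ROIMap:
        kind = design.APPROACH_ROI_KIND[approach]
        if kind == "anatomical":
            return self.atlas_rois[task]
        return self.rois[task][kind]


def build_cohort(config: StudyConfig, seed: int) -> list:
    """Build phantoms, the shared position template, ROI cohorts, and
    sensitivity engines for every subject."""
    rng = np.random.default_rng(derive_seed(seed, "cohort"))
    base = dict(radius_mm=config.head_radius_mm, scalp_mm=config.scalp_mm,
                skull_mm=config.skull_mm, csf_mm=config.csf_mm,
                gm_mm=config.gm_mm)
    atlas = phantom.build_phantom(phantom.PhantomConfig(
        resolution_mm=config.atlas_resolution_mm, **base))
    heads, vasc_heads = [], []
    for s in range(config.n_subjects):
        jit = {k: max(0.5, base[k] + rng.normal(scale=config.thickness_jitter_mm))
               for k in ("scalp_mm", "skull_mm", "csf_mm", "gm_mm")}
        geo = dict(base)
        geo.update(jit)
        cfg_plain = phantom.PhantomConfig(
            resolution_mm=config.subject_resolution_mm, **geo)
        cfg_vasc = phantom.PhantomConfig(
            resolution_mm=config.subject_resolution_mm,
            vasculature_density=config.vasculature_density, **geo)
        sub_seed = derive_seed(seed, "phantom", s)
        heads.append(phantom.build_phantom(cfg_plain, seed=sub_seed))
        vasc_heads.append(phantom.build_phantom(cfg_vasc, seed=sub_seed))
    positions = phantom.sample_scalp_positions(
        heads[0], n=config.n_positions, seed=derive_seed(seed, "positions"),
        min_spacing_mm=config.min_position_spacing_mm)

    design_tasks = tuple(dict.fromkeys(tuple(config.design_tasks) +
                                       tuple(config.tasks)))
    cohorts = {}
    for task in design_tasks:
        cohorts[task] = phantom.generate_roi_cohort(
            heads, atlas, task, config.n_subjects,
            seed=derive_seed(seed, "roi", task),
            roi_radius_mm=config.roi_radius_mm,
            center_jitter_mm=config.roi_center_jitter_mm,
            anatomical_offset_mm=config.anatomical_offset_mm)

    optics = phantom.TABLE_OPTICAL_PROPERTIES
    n_atlas = config.n_photons_atlas or 4 * config.n_photons
    atlas_engine = transport.SensitivityEngine(
        atlas, optics, positions.positions, n_photons=n_atlas,
        seed=derive_seed(seed, "photons", "atlas"),
        domain=config.sensitivity_domain)
    subjects = []
    for s in range(config.n_subjects):
        sid = f"S{s:02d}"
        standard = transport.SensitivityEngine(
            heads[s], optics, positions.positions,
            n_photons=config.n_photons,
            seed=derive_seed(seed, "photons", sid),
            domain=config.sensitivity_domain)
        engines = {
            "atlas": atlas_engine,
            "standard": standard,
            # without vessels the vascular phantom is label-identical and the
            # seed matches, so the engine would be bitwise identical: alias it
            "vasc": standard if config.vasculature_density == 0 else
            transport.SensitivityEngine(
                vasc_heads[s], optics, positions.positions,
                n_photons=config.n_photons,
                seed=derive_seed(seed, "photons", sid),
                domain=config.sensitivity_domain),
            # independent transport run on the subject's vascularized head:
            # ground-truth response amplitudes must not share Monte Carlo
            # noise with the sensitivities the approaches optimized over,
            # or the informed approaches would inherit a winner's-curse
            # inflation of their true responses
            "truth": transport.SensitivityEngine(
                vasc_heads[s], optics, positions.positions,
                n_photons=config.n_photons,
                seed=derive_seed(seed, "photons-truth", sid),
                domain=config.sensitivity_domain),
        }
        rois = {t: {"individual": cohorts[t].individual[s],
                    "probabilistic": cohorts[t].probabilistic[s]}
                for t in design_tasks}
        atlas_rois = {t: cohorts[t].anatomical for t in design_tasks}
        centers = {t: cohorts[t].centers_mm[s] for t in config.tasks}
        subjects.append(SubjectModel(
            subject_id=sid, head=heads[s], vasc_head=vasc_heads[s],
            atlas_head=atlas, positions=positions, rois=rois,
            atlas_rois=atlas_rois, engines=engines, roi_centers_mm=centers))
    return subjects


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    roi_stats: pd.DataFrame
    cnr: pd.DataFrame
    group_tests: pd.DataFrame
    pairwise: pd.DataFrame
    percent_significant: pd.DataFrame
    similarity: pd.DataFrame
    fmri_agreement: pd.DataFrame
    config: dict
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "roi_stats": self.roi_stats.to_dict(orient="records"),
            "cnr": self.cnr.to_dict(orient="records"),
            "group_tests": self.group_tests.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "percent_significant":
                self.percent_significant.to_dict(orient="records"),
            "similarity": self.similarity.to_dict(orient="records"),
            "fmri_agreement": self.fmri_agreement.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, default=_json_default)

    def save(self, directory) -> None:
        import os

        from .io import atomic_write

        os.makedirs(directory, exist_ok=True)
        atomic_write(os.path.join(directory, "report.json"), self.to_json())
        for name in ("roi_stats", "cnr", "group_tests", "pairwise",
                     "percent_significant", "similarity", "fmri_agreement"):
            getattr(self, name).to_csv(os.path.join(directory, f"{name}.csv"),
                                       index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def design_subject_layouts(subject: SubjectModel, config: StudyConfig,
                           tasks=None) -> dict:
    """All (approach, task) layouts for one subject.

    By default layouts are designed for every task in
    ``config.design_tasks`` (12 per subject with three tasks and four
    approaches); only the two measured tasks' layouts enter the merged
    setup downstream.
    """
    if tasks is None:
        tasks = config.design_tasks
    layouts = {}
    for task in tasks:
        for approach in config.approaches:
            layouts[(approach, task)] = design.design_approach_layout(
                approach, subject, task, d_enum=config.enum_distance_mm,
                d_opt=config.channel_distance_mm,
                shared_role=config.shared_role)
    return layouts


def _true_sensitivities(subject: SubjectModel, layouts: dict,
                        setup: design.CombinedSetup, config: StudyConfig) -> dict:
    """%-sensitivity of every merged NDC channel to each task's *true*
    (individual) ROI, from the independent ground-truth transport run."""
    engine = subject.engines["truth"]
    per_task = {t: engine.sensitivity_matrix(subject.rois[t]["individual"])
                for t in config.tasks}
    out = {}
    for key, layout in layouts.items():
        members = setup.memberships[key]
        for ch, setup_idx in zip(layout.channels, members):
            i, j = ch.pair
            for task in config.tasks:
                out[(setup_idx, task)] = float(per_task[task][i, j])
    return out


def analyze_subject(subject: SubjectModel, layouts: dict, config: StudyConfig,
                    seed: int):
    """Simulate, preprocess and fit one subject; returns (roi rows, cnr rows,
    agreement rows)."""
    setup = design.merge_setups(
        list(layouts.values()), subject.positions.positions,
        merge_radius_mm=config.merge_radius_mm,
        sdc_distance_mm=config.sdc_distance_mm,
        shared_role=config.shared_role, phantom=subject.head)
    schedule = simulate.generate_schedule(
        n_runs=config.n_runs,
        n_trials_per_task_per_run=config.n_trials_per_task_per_run,
        tasks=config.tasks, seed=derive_seed(seed, "schedule",
                                             subject.subject_id),
        trial_duration_s=config.trial_duration_s,
        rest_choices_s=config.rest_choices_s, fs=config.fs)
    sens_true = _true_sensitivities(subject, layouts, setup, config)
    rec, truth = simulate.simulate_recording(
        setup, schedule, config.truth,
        seed=derive_seed(seed, "recording", subject.subject_id),
        channel_task_sensitivity=sens_true)

    pipeline = preprocess.PreprocessingPipeline(
        cv_threshold=config.cv_threshold_percent,
        low_hz=config.filter_band_hz[0], high_hz=config.filter_band_hz[1],
        filter_order=config.filter_order)
    sdc_map = setup.sdc_for_ndc()
    runs = [pipeline.run(rec.intensity[r], config.fs,
                         [c["distance_mm"] for c in setup.channels],
                         config.truth.age_years, sdc_map)
            for r in range(schedule.n_runs)]

    hrf = glm.double_gamma_hrf(config.fs)
    max_order = int(round(config.ar_max_order_factor * config.fs))
    designs = [glm.build_design_matrix(schedule, r, config.fs,
                                       schedule.run_samples(r), hrf=hrf,
                                       dct_cutoff_hz=config.dct_cutoff_hz)
               for r in range(schedule.n_runs)]
    designs_hbr = [d.scaled_for_hbr(config.truth.hbr_ratio) for d in designs]

    ndcs = setup.ndc_indices()
    fits = {}
    retained_all = {}
    for k in ndcs:
        runs_ok = [r for r in range(schedule.n_runs)
                   if runs[r].quality.retained[k]]
        retained_all[k] = bool(runs_ok)
        if not runs_ok:
            continue
        for chrom, dsets, attr in (("HbO", designs, "hbo_um"),
                                   ("HbR", designs_hbr, "hbr_um")):
            ys = [getattr(runs[r], attr)[k] for r in runs_ok]
            ds = [dsets[r] for r in runs_ok]
            fits[(k, chrom)] = glm.fit_multirun_channel(ys, ds, config.fs,
                                                        max_order=max_order)

    roi_rows, cnr_rows = [], []
    filt = {"HbO": [r.hbo_filtered for r in runs],
            "HbR": [r.hbr_filtered for r in runs]}
    masks = [r.motion_masks for r in runs]
    for (approach, task), layout in layouts.items():
        members = setup.memberships[(approach, task)]
        for chrom in ("HbO", "HbR"):
            ch_fits = [fits[(k, chrom)] for k in members if (k, chrom) in fits]
            flags = [retained_all[k] for k in members if (k, chrom) in fits]
            if not ch_fits:
                continue
            st = glm.multirun_roi_stats(ch_fits, task, retained=flags,
                                        subject=subject.subject_id,
                                        approach=approach, chromophore=chrom)
            roi_rows.append({"subject": subject.subject_id, "task": task,
                             "approach": approach, "chromophore": chrom,
                             "beta": st.beta_roi, "cov": st.cov_roi,
                             "t": st.t, "dof": st.dof, "p_two": st.p_two,
                             "p_one": st.p_one})
            # ROI block average: mean of the member channels' block averages
            blocks = []
            for k in members:
                if not retained_all[k]:
                    continue
                ba = glm.block_average(filt[chrom], schedule, task, config.fs,
                                       pre_s=config.block_pre_s,
                                       post_s=config.block_post_s,
                                       motion_masks=masks, channel=k)
                blocks.append(ba)
            if blocks:
                mean_course = np.mean([b.mean for b in blocks], axis=0)
                roi_block = glm.BlockAverage(time_s=blocks[0].time_s,
                                             mean=mean_course,
                                             n_trials=blocks[0].n_trials,
                                             task=task, fs=config.fs)
                cnr = glm.compute_cnr(roi_block, config.cnr_pre_window_s,
                                      config.cnr_dur_window_s)
                cnr_rows.append({"subject": subject.subject_id, "task": task,
                                 "approach": approach, "chromophore": chrom,
                                 "cnr": cnr})

    agree_rows = []
    for task in config.tasks:
        tmap = synthetic_fmri_tmap(
            subject.head, subject.roi_centers_mm[task],
            seed=derive_seed(seed, "fmri", subject.subject_id, task))
        for approach in config.approaches:
            layout = layouts[(approach, task)]
            avg_ts, peak_ts = [], []
            for ch in layout.channels:
                mid = subject.positions.positions[list(ch.pair)].mean(axis=0)
                w = project_channel_to_cortex(mid, subject.head,
                                              config.projection_radius_mm)
                if w.weights.size == 0:
                    continue
                a, p, _ = fnirs_fmri_agreement(w, tmap)
                avg_ts.append(a)
                peak_ts.append(p)
            if avg_ts:
                agree_rows.append({"subject": subject.subject_id, "task": task,
                                   "approach": approach,
                                   "weighted_avg_t": float(np.mean(avg_ts)),
                                   "peak_t": float(np.max(peak_ts))})
    return roi_rows, cnr_rows, agree_rows


def _similarity_table(all_layouts: dict, positions: np.ndarray,
                      config: StudyConfig) -> pd.DataFrame:
    rows = []
    for task in config.tasks:
        for a, b in itertools.combinations(config.approaches, 2):
            overlaps, dists = [], []
            for sid, layouts in all_layouts.items():
                ov, d = design.layout_similarity(layouts[(a, task)],
                                                 layouts[(b, task)], positions)
                overlaps.append(ov)
                dists.append(d)
            rows.append({"task": task, "approach_a": a, "approach_b": b,
                         "mean_overlap": float(np.mean(overlaps)),
                         "mean_cog_distance_mm": float(np.mean(dists))})
    return pd.DataFrame(rows)


def _group_tables(roi_stats: pd.DataFrame, cnr: pd.DataFrame,
                  config: StudyConfig):
    group_rows, pair_frames = [], []
    metrics = {"roi_t": (roi_stats, "t"), "cnr": (cnr, "cnr")}
    groupings = [("all", None)] + [(t, t) for t in config.tasks]
    for metric, (df, col) in metrics.items():
        for chrom in ("HbO", "HbR"):
            for gname, gtask in groupings:
                sub = df[df["chromophore"] == chrom]
                if gtask is not None:
                    sub = sub[sub["task"] == gtask]
                    n_sub = sub["subject"].nunique()
                    if n_sub < config.min_subjects_per_task:
                        continue
                pivot = sub.pivot_table(index=["subject", "task"],
                                        columns="approach", values=col)
                pivot = pivot.reindex(columns=list(config.approaches))
                vals = pivot.to_numpy()
                try:
                    stat, dof, p = friedman_test(vals)
                except ValueError:
                    continue
                group_rows.append({"metric": metric, "chromophore": chrom,
                                   "grouping": gname, "friedman": stat,
                                   "dof": dof, "p": p,
                                   "n_rows": int(np.isfinite(vals).all(1).sum())})
                pw = pairwise_wilcoxon_bh(vals, config.approaches, config.alpha)
                pw.insert(0, "grouping", gname)
                pw.insert(0, "chromophore", chrom)
                pw.insert(0, "metric", metric)
                pair_frames.append(pw)
    pairwise = pd.concat(pair_frames, ignore_index=True) if pair_frames \
        else pd.DataFrame()
    return pd.DataFrame(group_rows), pairwise


def run_full_study(config: StudyConfig | None = None, seed: int = 0) -> ComparisonReport:
    """Run the complete synthetic study and assemble the comparison report.

    Fully reproducible from (config, seed): cohort generation -> per-subject
    layout design (4 approaches x 2 tasks) -> setup merging -> 6-run
    recording simulation -> preprocessing -> AR GLMs -> ROI statistics,
    block-average CNR, layout similarity, group statistics.
    """
    if config is None:
        config = StudyConfig()
    subjects = build_cohort(config, seed)
    all_layouts = {}
    roi_rows, cnr_rows, agree_rows = [], [], []
    for subject in subjects:
        designed = design_subject_layouts(subject, config)
        # task selection: only the measured tasks' layouts enter the setup
        layouts = {(a, t): designed[(a, t)] for a in config.approaches
                   for t in config.tasks}
        all_layouts[subject.subject_id] = layouts
        rr, cr, ar = analyze_subject(subject, layouts, config, seed)
        roi_rows.extend(rr)
        cnr_rows.extend(cr)
        agree_rows.extend(ar)
    roi_stats = pd.DataFrame(roi_rows)
    cnr = pd.DataFrame(cnr_rows)
    group_tests, pairwise = _group_tables(roi_stats, cnr, config)
    psig = percent_significant(roi_stats, config.alpha)
    similarity = _similarity_table(all_layouts,
                                   subjects[0].positions.positions, config)
    return ComparisonReport(
        roi_stats=roi_stats, cnr=cnr, group_tests=group_tests,
        pairwise=pairwise, percent_significant=psig, similarity=similarity,
        fmri_agreement=pd.DataFrame(agree_rows), config=config.to_dict(),
        seed=seed)


def plot_group_comparison(report: ComparisonReport, path,
                          metric: str = "cnr", chromophore: str = "HbO") -> None:
    """Box plots of the per-subject metric per approach (one panel per task
    grouping), mirroring the study's headline figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.cnr if metric == "cnr" else report.roi_stats
    col = "cnr" if metric == "cnr" else "t"
    df = df[df["chromophore"] == chromophore]
    approaches = sorted(df["approach"].unique(),
                        key=lambda a: _INFORMEDNESS.get(a, 99))
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [df[df["approach"] == a][col].to_numpy() for a in approaches]
    ax.boxplot(data, tick_labels=approaches)
    ax.set_ylabel(f"{metric} ({chromophore})")
    ax.set_title("Approach comparison, all tasks pooled")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
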