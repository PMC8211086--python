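"""Design matrices, AR-prewhitened GLM, multirun ROI statistics, block
averages, and the contrast-to-noise ratio.

The GLM follows the AR-whitened ordinary-least-squares scheme: an initial
OLS fit, an AR(p) model of the residuals with the order chosen by AIC up to
four times the sampling rate, prewhitening of both the data and the design
with the fitted AR filter, OLS on the whitened system, and one re-estimation
pass.  The ROI statistic combines the two layout channels with contrast
weights 0.5 each: beta_ROI = c . beta_channel, Cov_ROI = c Cov c^T, and
t = beta_ROI / sqrt(Cov_ROI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .hrf import double_gamma_hrf, task_regressor

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "ROIStat",
    "BlockAverage",
    "build_design_matrix",
    "dct_basis",
    "fit_ar_glm",
    "roi_contrast",
    "multirun_roi_stats",
    "block_average",
    "compute_cnr",
]

log = logging.getLogger(__name__)


def dct_basis(n_samples: int, fs: float, cutoff_hz: float = 0.009) -> np.ndarray:
    """Discrete-cosine confound columns with frequencies k/(2 N dt) below the
    cutoff, k >= 1 (the intercept is a separate column)."""
    dt = 1.0 / fs
    k_max = int(np.floor(2 * n_samples * dt * cutoff_hz))
    if 2 * n_samples * dt * cutoff_hz == k_max:  # strict inequality
        k_max -= 1
    t = np.arange(n_samples)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_samples))
            for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_samples, 0))


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_samples, n_predictors)
    labels: list
    fs: float
    task_columns: dict  # task -> column index
    hbr_scaled: bool = False

    def scaled_for_hbr(self, ratio: float = -1.0 / 3.0) -> "DesignMatrix":
        """Scale the task columns so the fitted beta stays on the HbO scale
        while the predictor matches the constrained HbR response."""
        X = self.X.copy()
        for col in self.task_columns.values():
            X[:, col] *= ratio
        return DesignMatrix(X=X, labels=list(self.labels), fs=self.fs,
                            task_columns=dict(self.task_columns), hbr_scaled=True)


def build_design_matrix(schedule, run: int, fs: float, n_samples: int,
                        hrf: np.ndarray | None = None,
                        dct_cutoff_hz: float = 0.009,
                        motion_mask: np.ndarray | None = None,
                        max_motion_regressors: int = 12) -> DesignMatrix:
    """Task HRF regressors + DCT confounds + intercept (+ optional one
    indicator column per contiguous motion-flagged segment)."""
    if hrf is None:
        hrf = double_gamma_hrf(fs)
    cols, labels = [], []
    task_columns = {}
    for task in schedule.tasks():
        trials = schedule.trials_for(run, task)
        reg = task_regressor([t.onset_s for t in trials],
                             [t.duration_s for t in trials], fs, n_samples,
                             hrf=hrf)
        if not trials or np.allclose(reg, 0):
            log.info("task %s has no trials in run %d; column dropped", task, run)
            continue
        task_columns[task] = len(cols)
        cols.append(reg)
        labels.append(f"task:{task}")
    dct = dct_basis(n_samples, fs, dct_cutoff_hz)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        labels.append(f"dct:{k + 1}")
    cols.append(np.ones(n_samples))
    labels.append("intercept")
    if motion_mask is not None and motion_mask.any():
        segments = _contiguous_segments(motion_mask)
        for i0, i1 in segments[:max_motion_regressors]:
            col = np.zeros(n_samples)
            col[i0:i1] = 1.0
            cols.append(col)
            labels.append(f"motion:{i0}-{i1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient ({rank} < {X.shape[1]}); "
                         f"columns: {labels}")
    return DesignMatrix(X=X, labels=labels, fs=fs, task_columns=task_columns)


def _contiguous_segments(mask: np.ndarray) -> list:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# AR estimation (Burg recursion, all orders in one pass) + whitening
# ---------------------------------------------------------------------------

def _burg(x: np.ndarray, max_order: int):
    """Burg AR fits for every order up to max_order.

    Returns (coeffs_per_order, prediction_error_per_order); order 0 is
    included.  Burg's forward-backward recursion is markedly less biased
    than Yule-Walker for strongly autocorrelated series at moderate n,
    which matters for the whitened-GLM standard errors.
    """
    n = x.size
    coeffs = [np.array([])]
    err = float(x @ x) / n
    pev = [err]
    a = np.array([])
    f = x[1:].astype(float)
    b = x[:-1].astype(float)
    for _ in range(1, max_order + 1):
        den = float(f @ f + b @ b)
        k = 2.0 * float(f @ b) / den if den > 0 else 0.0
        p = a.size + 1
        new_a = np.empty(p)
        new_a[:p - 1] = a - k * a[::-1]
        new_a[p - 1] = k
        a = new_a
        err *= max(1.0 - k * k, 1e-12)
        coeffs.append(a.copy())
        pev.append(max(err, 1e-300))
        f, b = f[1:] - k * b[1:], b[:-1] - k * f[:-1]
    return coeffs, pev


def estimate_ar(resid: np.ndarray, max_order: int):
    """Burg AR coefficients with AIC order selection."""
    n = resid.size
    x = resid - resid.mean()
    var = float(x @ x) / n
    if var < 1e-24:
        return np.array([]), 0
    max_order = min(max_order, n // 4)
    coeffs, pev = _burg(x, max_order)
    aic = [n * np.log(pev[p]) + 2 * (p + 1) for p in range(max_order + 1)]
    p_best = int(np.argmin(aic))
    return coeffs[p_best], p_best


def _whiten(x: np.ndarray, ar: np.ndarray) -> np.ndarray:
    """Apply the AR whitening filter 1 - sum(phi_k B^k) and drop the initial
    p samples (no valid history)."""
    p = ar.size
    if p == 0:
        return np.asarray(x, dtype=float)
    b = np.concatenate([[1.0], -ar])
    y = signal.lfilter(b, [1.0], x, axis=0)
    return y[p:]


@dataclass
class GLMResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    dof: int
    sigma2: float
    ar_coeffs: np.ndarray
    ar_order: int
    labels: list
    whitened_X: np.ndarray = field(repr=False, default=None)
    whitened_resid: np.ndarray = field(repr=False, default=None)

    def t_value(self, col: int) -> float:
        return float(self.beta[col] / np.sqrt(self.cov_beta[col, col]))


def fit_ar_glm(y: np.ndarray, X: np.ndarray, max_order: int | None = None,
               fs: float = 7.8125, n_iterations: int = 1,
               labels: list | None = None) -> GLMResult:
    """AR-prewhitened OLS.

    OLS fit -> AR(p) of the residuals (AIC up to ``max_order``, default
    4 x fs) -> whiten y and X -> OLS on the whitened system; the AR model is
    re-estimated and the fit repeated ``n_iterations`` more times.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if max_order is None:
        max_order = int(round(4 * fs))
    n, k = X.shape
    if n <= k + max_order:
        raise ValueError("series too short for the requested AR order")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ar = np.array([])
    Xw, yw = X, y
    for _ in range(max(1, n_iterations) + 1):
        resid = y - X @ beta
        ar, order = estimate_ar(resid, max_order)
        yw = _whiten(y, ar)
        Xw = _whiten(X, ar)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    dof = Xw.shape[0] - k
    sigma2 = float(resid_w @ resid_w) / dof if dof > 0 else 0.0
    XtX = Xw.T @ Xw
    try:
        cov = sigma2 * np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("whitened design is singular") from exc
    return GLMResult(beta=beta, cov_beta=cov, dof=dof, sigma2=sigma2,
                     ar_coeffs=ar, ar_order=ar.size,
                     labels=labels or [f"b{i}" for i in range(k)],
                     whitened_X=Xw, whitened_resid=resid_w)


# ---------------------------------------------------------------------------
# Multirun ROI statistics (contrast over the two layout channels)
# ---------------------------------------------------------------------------

@dataclass
class ROIStat:
    beta_roi: float
    cov_roi: float
    t: float
    dof: int
    p_two: float
    p_one: float
    contrast: np.ndarray
    subject: str = ""
    task: str = ""
    approach: str = ""
    chromophore: str = ""


def roi_contrast(beta_channel: np.ndarray, cov_channel: np.ndarray,
                 c: np.ndarray, dof: int, **labels) -> ROIStat:
    """beta_ROI = c . beta, Cov_ROI = c Cov c^T, t = beta_ROI/sqrt(Cov_ROI)."""
    c = np.asarray(c, dtype=float)
    beta_roi = float(c @ np.asarray(beta_channel, dtype=float))
    cov_roi = float(c @ np.asarray(cov_channel, dtype=float) @ c)
    if cov_roi <= 0:
        raise ValueError("ROI covariance is not positive")
    t = beta_roi / np.sqrt(cov_roi)
    p_two = 2 * stats.t.sf(abs(t), dof)
    p_one = stats.t.sf(t, dof)
    return ROIStat(beta_roi=beta_roi, cov_roi=cov_roi, t=float(t), dof=int(dof),
                   p_two=float(p_two), p_one=float(p_one), contrast=c, **labels)


@dataclass
class MultirunChannelFit:
    """Multirun beta for one channel: per-run whitened systems stacked with
    shared task columns and per-run confound blocks."""

    beta_task: dict  # task -> beta
    var_task: dict  # task -> variance of beta
    dof: int
    resid_per_run: list  # whitened residuals, per run


def fit_multirun_channel(ys: list, designs: list, fs: float,
                         max_order: int | None = None) -> MultirunChannelFit:
    """Fit one channel across runs.

    Each run is whitened with its own AR model (estimated from that run's
    OLS residuals, one re-estimation pass); the whitened systems are stacked
    with the task columns shared and each run's confounds block-diagonal.
    """
    if max_order is None:
        max_order = int(round(4 * fs))
    tasks = sorted({t for d in designs for t in d.task_columns})
    n_task = len(tasks)
    conf_sizes = [d.X.shape[1] - len(d.task_columns) for d in designs]
    n_cols = n_task + sum(conf_sizes)
    rows_w, X_blocks, resid_runs = [], [], []
    # per-run whitening
    whitened = []
    for y, d in zip(ys, designs):
        res = fit_ar_glm(y, d.X, max_order=max_order, fs=fs)
        yw = _whiten(y, res.ar_coeffs)
        Xw = _whiten(d.X, res.ar_coeffs)
        whitened.append((yw, Xw, d))
    total_rows = sum(yw.size for yw, _, _ in whitened)
    Xbig = np.zeros((total_rows, n_cols))
    ybig = np.zeros(total_rows)
    r0 = 0
    c0 = n_task
    for (yw, Xw, d), csize in zip(whitened, conf_sizes):
        nr = yw.size
        task_cols = list(d.task_columns.values())
        conf_cols = [j for j in range(d.X.shape[1]) if j not in task_cols]
        for t_i, task in enumerate(tasks):
            if task in d.task_columns:
                Xbig[r0:r0 + nr, t_i] = Xw[:, d.task_columns[task]]
        Xbig[r0:r0 + nr, c0:c0 + csize] = Xw[:, conf_cols]
        ybig[r0:r0 + nr] = yw
        r0 += nr
        c0 += csize
    beta, *_ = np.linalg.lstsq(Xbig, ybig, rcond=None)
    resid = ybig - Xbig @ beta
    dof = total_rows - n_cols
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(Xbig.T @ Xbig)
    beta_task = {task: float(beta[i]) for i, task in enumerate(tasks)}
    var_task = {task: float(sigma2 * XtX_inv[i, i]) for i, task in enumerate(tasks)}
    # split residuals back per run for cross-channel correlation
    r0 = 0
    for yw, _, _ in whitened:
        resid_runs.append(resid[r0:r0 + yw.size])
        r0 += yw.size
    return MultirunChannelFit(beta_task=beta_task, var_task=var_task, dof=dof,
                              resid_per_run=resid_runs)


def _residual_correlation(fit_a: MultirunChannelFit,
                          fit_b: MultirunChannelFit) -> float:
    """Whitened-residual correlation, runs aligned and trimmed to the common
    length from the end (AR orders may differ between the channels)."""
    xs, ys = [], []
    for ra, rb in zip(fit_a.resid_per_run, fit_b.resid_per_run):
        m = min(ra.size, rb.size)
        xs.append(ra[-m:])
        ys.append(rb[-m:])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    denom = np.sqrt(float(x @ x) * float(y @ y))
    return float(x @ y) / denom if denom > 0 else 0.0


def multirun_roi_stats(channel_fits: list, task: str, retained=None,
                       **labels) -> ROIStat:
    """ROI statistic for a two-channel layout.

    ``channel_fits`` holds the MultirunChannelFit of each ROI channel; if one
    was rejected by the CV filter (``retained`` flags), the contrast falls
    back to 1.0 on the survivor (logged).
    """
    if not channel_fits:
        raise ValueError("need at least one channel fit")
    if retained is None:
        retained = [True] * len(channel_fits)
    keep = [f for f, r in zip(channel_fits, retained) if r]
    if not keep:
        raise ValueError("all ROI channels were rejected")
    if len(keep) == 1:
        log.info("one ROI channel rejected; falling back to c = 1.0")
        c = np.array([1.0])
    else:
        c = np.full(len(keep), 0.5)
    betas = np.array([f.beta_task[task] for f in keep])
    n = len(keep)
    cov = np.zeros((n, n))
    for i in range(n):
        cov[i, i] = keep[i].var_task[task]
    for i in range(n):
        for j in range(i + 1, n):
            rho = _residual_correlation(keep[i], keep[j])
            cov[i, j] = cov[j, i] = rho * np.sqrt(cov[i, i] * cov[j, j])
    dof = min(f.dof for f in keep)
    return roi_contrast(betas, cov, c, dof, task=task, **labels)


# ---------------------------------------------------------------------------
# Block averages and CNR
# ---------------------------------------------------------------------------

@dataclass
class BlockAverage:
    time_s: np.ndarray
    mean: np.ndarray
    n_trials: int
    task: str
    fs: float


def block_average(conc: list, schedule, task: str, fs: float,
                  pre_s: float = 4.0, post_s: float = 15.0,
                  motion_masks: list | None = None,
                  channel: int | np.ndarray = 0) -> BlockAverage:
    """Trial average of the per-trial baseline-shifted segments.

    ``conc`` is per run (n_channels, n_samples) or (n_samples,); the window
    spans [-pre, duration + post] s; baseline is the mean over [-pre, 0) s;
    motion-masked samples are excluded (NaN-mean across trials).
    """
    n_pre = int(round(pre_s * fs))
    segments = []
    duration = None
    for r, run_conc in enumerate(conc):
        x = run_conc if run_conc.ndim == 1 else run_conc[channel]
        mask = None
        if motion_masks is not None:
            m = motion_masks[r]
            mask = m if m.ndim == 1 else m[channel]
        for trial in schedule.trials_for(r, task):
            duration = trial.duration_s
            n_win = int(round((pre_s + trial.duration_s + post_s) * fs))
            i0 = int(round(trial.onset_s * fs)) - n_pre
            if i0 < 0 or i0 + n_win > x.size:
                continue
            seg = x[i0:i0 + n_win].astype(float).copy()
            if mask is not None:
                seg[mask[i0:i0 + n_win]] = np.nan
            base = np.nanmean(seg[:n_pre]) if np.any(np.isfinite(seg[:n_pre])) else 0.0
            segments.append(seg - base)
    if not segments:
        raise ValueError(f"no usable trials for task {task!r}")
    arr = np.array(segments)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=0)
    time = (np.arange(mean.size) - n_pre) / fs
    return BlockAverage(time_s=time, mean=mean, n_trials=len(segments),
                        task=task, fs=fs)


def compute_cnr(block: BlockAverage, pre_window=(-4.0, 0.0),
                dur_window=(5.0, 15.0)) -> float:
    """CNR = |mean(dur) - mean(pre)| / sqrt(var(dur) + var(pre)) with sample
    variances (ddof 1); scale-invariant and non-negative."""
    t = block.time_s
    pre = block.mean[(t >= pre_window[0]) & (t < pre_window[1])]
    dur = block.mean[(t >= dur_window[0]) & (t < dur_window[1])]
    if pre.size < 2 or dur.size < 2:
        raise ValueError("block average does not span both CNR windows")
    pre = pre[np.isfinite(pre)]
    dur = dur[np.isfinite(dur)]
    num = abs(dur.mean() - pre.mean())
    denom = np.sqrt(np.var(dur, ddof=1) + np.var(pre, ddof=1))
    if num == 0:
        return 0.0
    if denom == 0:
        log.warning("zero CNR denominator; returning +inf")
        return float("inf")
    return float(num / denom)
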