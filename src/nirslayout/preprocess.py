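"""Channel-level preprocessing chain.

Order (enforced by :class:`PreprocessingPipeline` and logged): intensity ->
optical density -> coefficient-of-variation channel rejection -> motion
detection on OD -> modified Beer-Lambert conversion to concentrations ->
short-separation regression on the *unfiltered* concentrations (input to
the GLM) and zero-phase band-pass filtering (input to block averages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .beerlambert import WAVELENGTHS_NM, od_to_concentration_pair

__all__ = [
    "ChannelQuality",
    "intensity_to_od",
    "compute_cv_and_filter",
    "detect_motion_artifacts",
    "od_to_concentration",
    "bandpass_filter",
    "short_channel_regress",
    "PreprocessingPipeline",
    "PreprocessedRun",
]

log = logging.getLogger(__name__)


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """OD(t) = -ln(I(t) / mean(I)) along the last axis."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        bad = np.argwhere(np.any(intensity <= 0, axis=-1))
        raise ValueError(f"non-positive intensity samples in channels {bad[:5].tolist()}")
    mean = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / mean)


@dataclass
class ChannelQuality:
    """Per-channel CV (%) per wavelength and the retained flags."""

    cv_percent: np.ndarray  # (n_channels, n_wavelengths)
    retained: np.ndarray  # (n_channels,) bool
    threshold: float
    motion_masks: np.ndarray | None = None  # (n_channels, n_samples) bool


def compute_cv_and_filter(intensity: np.ndarray, threshold: float = 7.5) -> ChannelQuality:
    """Whole-run coefficient of variation; a channel is discarded when
    CV >= threshold at either wavelength (inclusive bound)."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    mean = intensity.mean(axis=-1)
    sd = intensity.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    zero_mean = mean == 0
    if np.any(zero_mean):
        log.warning("channels with zero mean intensity discarded")
        cv[zero_mean] = np.inf
    retained = np.all(cv < threshold, axis=-1)
    return ChannelQuality(cv_percent=cv, retained=retained, threshold=threshold)


def detect_motion_artifacts(od: np.ndarray, fs: float, t_motion_s: float = 0.5,
                            t_mask_s: float = 1.0, std_thresh: float = 50.0,
                            amp_thresh: float = 5.0) -> np.ndarray:
    """Per-channel boolean motion masks on OD series.

    A sample is flagged when the signal change across any window of length
    ``t_motion_s`` containing it exceeds ``std_thresh`` times the standard
    deviation of the one-sample differences, or ``amp_thresh`` in absolute
    OD; flags are dilated by ``t_mask_s`` on both sides.  Offsets cancel
    (the detector only sees differences).
    """
    if min(t_motion_s, t_mask_s, std_thresh, amp_thresh) <= 0:
        raise ValueError("motion-detection parameters must be positive")
    od = np.atleast_2d(np.asarray(od, dtype=float))
    # collapse a wavelength axis if present: flag on the worst wavelength
    if od.ndim == 3:
        masks = np.zeros((od.shape[0], od.shape[-1]), dtype=bool)
        for w in range(od.shape[1]):
            masks |= detect_motion_artifacts(od[:, w], fs, t_motion_s, t_mask_s,
                                             std_thresh, amp_thresh)
        return masks
    n_ch, n = od.shape
    w = max(1, int(round(t_motion_s * fs)))
    dilate = int(round(t_mask_s * fs))
    masks = np.zeros((n_ch, n), dtype=bool)
    for c in range(n_ch):
        x = od[c]
        sigma = np.std(np.diff(x))
        change = np.abs(x[w:] - x[:-w])
        hit = (change > std_thresh * sigma) | (change > amp_thresh)
        flag = np.zeros(n, dtype=bool)
        idx = np.flatnonzero(hit)
        for i in idx:
            flag[i:i + w + 1] = True
        if flag.any() and dilate > 0:
            kernel = np.ones(2 * dilate + 1, dtype=int)
            flag = np.convolve(flag.astype(int), kernel, mode="same") > 0
        masks[c] = flag
    return masks


def od_to_concentration(od: np.ndarray, distance_mm, age_years: float,
                        wavelengths_nm=WAVELENGTHS_NM):
    """Modified Beer-Lambert inversion.

    ``od`` has shape (n_channels, 2, n_samples); ``distance_mm`` scalar or
    per channel.  Returns (hbo_um, hbr_um), each (n_channels, n_samples).
    """
    od = np.asarray(od, dtype=float)
    if od.ndim == 2:
        od = od[None]
    distances = np.broadcast_to(np.asarray(distance_mm, dtype=float), (od.shape[0],))
    hbo = np.empty((od.shape[0], od.shape[-1]))
    hbr = np.empty_like(hbo)
    for c in range(od.shape[0]):
        hbo[c], hbr[c] = od_to_concentration_pair(od[c], distances[c], age_years,
                                                  wavelengths_nm)
    return hbo, hbr


def bandpass_filter(x: np.ndarray, fs: float = 7.8125, low_hz: float = 0.008,
                    high_hz: float = 0.25, order: int = 1000) -> np.ndarray:
    """Zero-phase band-pass FIR (linear-phase design applied forward and
    backward with reflection padding)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= 3 * order:
        raise ValueError(
            f"series of {n} samples is too short for order {order}; need more "
            f"than {3 * order} samples (reduce the filter order)")
    taps = signal.firwin(order + 1, [low_hz, high_hz], pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], x, axis=-1, padtype="even",
                           padlen=min(3 * order, n - 1))


def short_channel_regress(ndc: np.ndarray, sdc: np.ndarray) -> np.ndarray:
    """Remove the least-squares projection of the (demeaned) short-channel
    regressor from a normal channel; slope-only fit, residual returned with
    the NDC mean restored."""
    ndc = np.asarray(ndc, dtype=float)
    sdc = np.asarray(sdc, dtype=float)
    s = sdc - sdc.mean()
    denom = float(s @ s)
    if denom < 1e-20:
        log.warning("zero-variance short channel; NDC returned unchanged")
        return ndc.copy()
    y = ndc - ndc.mean()
    beta = float(y @ s) / denom
    return ndc - beta * s


@dataclass
class PreprocessedRun:
    """Outputs of the chain for one run."""

    quality: ChannelQuality
    hbo_um: np.ndarray  # (n_channels, n_samples), SDC-corrected, unfiltered
    hbr_um: np.ndarray
    hbo_filtered: np.ndarray  # band-passed (block-average input)
    hbr_filtered: np.ndarray
    motion_masks: np.ndarray
    log_lines: list = field(default_factory=list)


class PreprocessingPipeline:
    """Runs the chain in the fixed order and records what it did.

    Short-separation regression is applied to the unfiltered concentrations
    (GLM input); band-pass filtering produces the block-average input.
    """

    def __init__(self, cv_threshold: float = 7.5, t_motion_s: float = 0.5,
                 t_mask_s: float = 1.0, std_thresh: float = 50.0,
                 amp_thresh: float = 5.0, low_hz: float = 0.008,
                 high_hz: float = 0.25, filter_order: int = 1000,
                 apply_ssr: bool = True):
        self.cv_threshold = cv_threshold
        self.t_motion_s = t_motion_s
        self.t_mask_s = t_mask_s
        self.std_thresh = std_thresh
        self.amp_thresh = amp_thresh
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.filter_order = filter_order
        self.apply_ssr = apply_ssr

    def run(self, intensity: np.ndarray, fs: float, distances_mm,
            age_years: float, sdc_for_ndc: dict | None = None) -> PreprocessedRun:
        lines = []
        od = intensity_to_od(intensity)
        lines.append("intensity->OD (natural log, run-mean reference)")
        quality = compute_cv_and_filter(intensity, self.cv_threshold)
        lines.append(f"CV filter at {self.cv_threshold}%: retained "
                     f"{int(quality.retained.sum())}/{len(quality.retained)}")
        masks = detect_motion_artifacts(od, fs, self.t_motion_s, self.t_mask_s,
                                        self.std_thresh, self.amp_thresh)
        quality.motion_masks = masks
        lines.append(f"motion detection flagged {int(masks.sum())} samples")
        hbo, hbr = od_to_concentration(od, distances_mm, age_years)
        lines.append("modified Beer-Lambert with age-specific DPF")
        if self.apply_ssr and sdc_for_ndc:
            hbo_c, hbr_c = hbo.copy(), hbr.copy()
            for ndc_idx, sdc_idx in sdc_for_ndc.items():
                hbo_c[ndc_idx] = short_channel_regress(hbo[ndc_idx], hbo[sdc_idx])
                hbr_c[ndc_idx] = short_channel_regress(hbr[ndc_idx], hbr[sdc_idx])
            hbo, hbr = hbo_c, hbr_c
            lines.append("short-separation regression on unfiltered data")
        hbo_f = bandpass_filter(hbo, fs, self.low_hz, self.high_hz,
                                self.filter_order)
        hbr_f = bandpass_filter(hbr, fs, self.low_hz, self.high_hz,
                                self.filter_order)
        lines.append(f"zero-phase FIR band-pass [{self.low_hz}, {self.high_hz}] Hz, "
                     f"order {self.filter_order}")
        for line in lines:
            log.debug("preprocess: %s", line)
        return PreprocessedRun(quality=quality, hbo_um=hbo, hbr_um=hbr,
                               hbo_filtered=hbo_f, hbr_filtered=hbr_f,
                               motion_masks=masks, log_lines=lines)
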