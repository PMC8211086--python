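"""Canonical double-gamma hemodynamic response function.

One HRF implementation is shared by the forward simulator and the GLM
design matrix so that noise-free amplitude recovery is exact by
construction.  Parameters follow the canonical SPM-style double gamma:
response peak ~6 s, undershoot peak ~16 s, undershoot ratio 1/6.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["double_gamma_hrf", "task_regressor"]


def double_gamma_hrf(fs: float, duration_s: float = 32.0,
                     peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
                     peak_disp_s: float = 1.0, undershoot_disp_s: float = 1.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Sampled double-gamma HRF, normalized to unit peak."""
    t = np.arange(0, duration_s, 1.0 / fs)
    peak = gamma_dist.pdf(t, peak_delay_s / peak_disp_s, scale=peak_disp_s)
    under = gamma_dist.pdf(t, undershoot_delay_s / undershoot_disp_s,
                           scale=undershoot_disp_s)
    h = peak - under / ratio
    return h / h.max()


def task_regressor(onsets_s, durations_s, fs: float, n_samples: int,
                   hrf: np.ndarray | None = None,
                   normalize_peak: bool = True) -> np.ndarray:
    """Boxcar of the trials convolved with the HRF.

    With ``normalize_peak`` the regressor is scaled so an isolated trial
    peaks at 1, making the GLM beta the peak concentration change of one
    trial (the scale the simulator injects amplitudes on).
    """
    if hrf is None:
        hrf = double_gamma_hrf(fs)
    box = np.zeros(n_samples)
    for onset, dur in zip(np.atleast_1d(onsets_s), np.atleast_1d(durations_s)):
        i0 = int(round(onset * fs))
        i1 = int(round((onset + dur) * fs))
        box[max(i0, 0):min(i1, n_samples)] = 1.0
    reg = np.convolve(box, hrf)[:n_samples]
    if normalize_peak:
        if len(np.atleast_1d(onsets_s)) == 0:
            return reg
        dur = float(np.atleast_1d(durations_s)[0])
        single = np.convolve(np.ones(int(round(dur * fs))), hrf)
        peak = single.max()
        if peak > 0:
            reg = reg / peak
    return reg
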