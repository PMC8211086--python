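"""Event schedules and raw two-wavelength fNIRS recordings with known truth.

The forward model inverts the analysis chain: per normal-distance channel,
the oxyhemoglobin concentration course is the sum of task regressors
(10-s boxcars convolved with the canonical double-gamma HRF) scaled by the
channel's true response amplitude, deoxyhemoglobin is locked to -1/3 of it;
a superficial course (Mayer wave + slow drift) is added to every channel at
unit coupling and is the *only* physiological content of short-distance
channels; concentrations convert to optical density through the same
modified Beer-Lambert model the preprocessing inverts; AR noise and optional
spike/shift motion artifacts are added in OD; intensity is
``baseline * exp(-OD)`` per wavelength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beerlambert import WAVELENGTHS_NM, concentration_to_od
from .hrf import double_gamma_hrf, task_regressor

__all__ = [
    "Trial",
    "EventSchedule",
    "TruthConfig",
    "GroundTruth",
    "FnirsRecording",
    "generate_schedule",
    "simulate_recording",
]

SAMPLING_RATE_HZ = 7.8125


@dataclass(frozen=True)
class Trial:
    task: str
    onset_s: float
    duration_s: float


@dataclass
class EventSchedule:
    """Per-run ordered trials with jittered rest gaps."""

    # lead-in/out rests chosen so the shortest possible default run
    # (all rest draws at 20 s) still exceeds the 3x order-1000 samples the
    # zero-phase band-pass filter requires
    runs: list  # list of list[Trial]
    fs: float = SAMPLING_RATE_HZ
    lead_in_s: float = 20.0
    lead_out_s: float = 20.0

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def run_duration_s(self, r: int) -> float:
        last = self.runs[r][-1]
        return last.onset_s + last.duration_s + self.lead_out_s

    def run_samples(self, r: int) -> int:
        return int(round(self.run_duration_s(r) * self.fs))

    def trials_for(self, r: int, task: str) -> list:
        return [t for t in self.runs[r] if t.task == task]

    def tasks(self) -> list:
        seen = []
        for run in self.runs:
            for t in run:
                if t.task not in seen:
                    seen.append(t.task)
        return sorted(seen)


def _pseudorandom_order(tasks, n_per_task, rng, max_consecutive=2):
    """Shuffle trial labels, rejecting runs of more than ``max_consecutive``."""
    labels = [t for t in tasks for _ in range(n_per_task)]
    for _ in range(1000):
        rng.shuffle(labels)
        run = 1
        ok = True
        for a, b in zip(labels, labels[1:]):
            run = run + 1 if a == b else 1
            if run > max_consecutive:
                ok = False
                break
        if ok:
            return list(labels)
    return list(labels)  # single-task schedules cannot satisfy the cap


def generate_schedule(n_runs: int = 6, n_trials_per_task_per_run: int = 6,
                      tasks=("mental_calculation", "mental_rotation"),
                      seed: int = 0, trial_duration_s: float = 10.0,
                      rest_choices_s=(20, 21, 22, 23, 24),
                      fs: float = SAMPLING_RATE_HZ) -> EventSchedule:
    """Pseudorandomized trial schedule: 10-s trials, rest gaps drawn uniformly
    from {20..24} s (mean 22 s), no task repeated more than twice in a row."""
    if n_runs < 1 or not tasks:
        raise ValueError("need at least one run and one task")
    rng = np.random.default_rng(seed)
    runs = []
    sched = EventSchedule(runs=[], fs=fs)
    for _ in range(n_runs):
        order = _pseudorandom_order(list(tasks), n_trials_per_task_per_run, rng)
        t = sched.lead_in_s
        trials = []
        for task in order:
            trials.append(Trial(task=task, onset_s=t, duration_s=trial_duration_s))
            t += trial_duration_s + float(rng.choice(rest_choices_s))
        runs.append(trials)
    sched.runs = runs
    return sched


@dataclass
class TruthConfig:
    """Forward-model parameters (study conditions).

    ``amplitude_per_percent_um`` converts a channel's %-sensitivity to the
    task's true ROI into the peak single-trial oxyhemoglobin change (uM), so
    well-targeted channels peak around 0.5-1 uM.  The superficial course
    (Mayer wave near 0.1 Hz plus a slow drift) is shared between a normal
    channel and its short-distance neighbour at unit coupling.  AR(1) noise
    is expressed in optical-density units.
    """

    amplitude_per_percent_um: float = 0.02
    hbr_ratio: float = -1.0 / 3.0
    superficial_hbo_um: float = 0.6
    superficial_hbr_um: float = -0.2
    superficial_channel_um: float = 0.2
    mayer_freq_hz: float = 0.095
    drift_freq_hz: float = 0.01
    sdc_coupling: float = 1.0
    noise_sd_od: float = 1.5e-3
    ar_coeffs: tuple = (0.6,)
    spike_rate_per_min: float = 0.2
    spike_duration_s: float = 0.5
    spike_sd_multiple: float = 5.0
    shift_rate_per_min: float = 0.05
    shift_sd_multiple: float = 8.0
    baseline_intensity: float = 1.0
    age_years: float = 29.81
    bad_channel_rate: float = 0.0
    bad_channel_cv_pct: float = 15.0


@dataclass
class GroundTruth:
    """Everything the recovery tests need to score the pipeline."""

    amplitudes_um: dict  # (channel_index, task) -> peak HbO uM
    superficial_hbo_um: list  # per run, array
    artifact_times_s: dict  # (run, channel) -> list of onsets
    noise_params: dict
    conc_hbo_um: list = field(default_factory=list)  # per run: (n_ch, n_t)
    conc_hbr_um: list = field(default_factory=list)


@dataclass
class FnirsRecording:
    """Raw two-wavelength intensity for one combined setup.

    ``intensity``: list per run of arrays (n_channels, 2, n_samples); the
    channel table and SDC->NDC mapping come from the CombinedSetup.
    """

    intensity: list
    fs: float
    wavelengths_nm: tuple
    setup: object  # CombinedSetup
    schedule: EventSchedule
    age_years: float = 29.81

    @property
    def n_channels(self) -> int:
        return self.intensity[0].shape[0]


def _ar_noise(rng, n, coeffs, sd):
    if sd == 0:
        return np.zeros(n)
    p = len(coeffs)
    innov_sd = sd * math.sqrt(max(1e-12, _ar_innovation_scale(coeffs)))
    e = rng.normal(scale=innov_sd, size=n + 10 * p)
    x = np.zeros_like(e)
    for t in range(len(e)):
        acc = e[t]
        for k, c in enumerate(coeffs, start=1):
            if t - k >= 0:
                acc += c * x[t - k]
        x[t] = acc
    return x[10 * p:]


def _ar_innovation_scale(coeffs):
    """Innovation variance ratio so the process variance equals sd^2 (AR(1)
    exact; higher orders approximate)."""
    if len(coeffs) == 1:
        return 1.0 - coeffs[0] ** 2
    return max(0.05, (1.0 - sum(coeffs)) ** 2)


def simulate_recording(setup, schedule: EventSchedule, truth_config: TruthConfig,
                       seed: int = 0, channel_task_sensitivity: dict | None = None):
    """Simulate a multi-run recording for a merged setup.

    ``channel_task_sensitivity`` maps (channel_index, task) to the channel's
    %-sensitivity to that task's true ROI; missing entries default to 0
    (no cortical response).  Returns (FnirsRecording, GroundTruth).
    """
    if truth_config.baseline_intensity <= 0:
        raise ValueError("baseline intensity must be positive")
    ndcs = setup.ndc_indices()
    sdcs = setup.sdc_indices()
    if not ndcs or not sdcs:
        raise ValueError("setup needs at least one NDC and one SDC")
    rng = np.random.default_rng(seed)
    fs = schedule.fs
    tasks = schedule.tasks()
    hrf = double_gamma_hrf(fs)

    amplitudes = {}
    for k in ndcs:
        for task in tasks:
            sens = 0.0
            if channel_task_sensitivity is not None:
                sens = channel_task_sensitivity.get((k, task), 0.0)
            amplitudes[(k, task)] = truth_config.amplitude_per_percent_um * sens

    n_ch = len(setup.channels)
    bad = rng.random(n_ch) < truth_config.bad_channel_rate

    sdc_of = setup.sdc_for_ndc()
    intensity_runs = []
    sup_runs = []
    conc_hbo_runs, conc_hbr_runs = [], []
    artifact_times: dict = {}
    for r in range(schedule.n_runs):
        n = schedule.run_samples(r)
        t = np.arange(n) / fs
        # one superficial course per run shared by all channels, plus a
        # smaller channel-specific component (local scalp physiology) that
        # short-separation regression cannot remove
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        sup = (np.sin(2 * np.pi * truth_config.mayer_freq_hz * t + phase1) +
               np.sin(2 * np.pi * truth_config.drift_freq_hz * t + phase2))
        sup_hbo = truth_config.superficial_hbo_um * sup / 2.0
        sup_hbr = truth_config.superficial_hbr_um * sup / 2.0
        sup_runs.append(sup_hbo)

        def _local_course():
            if truth_config.superficial_channel_um == 0:
                return 0.0
            p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
            f1 = truth_config.mayer_freq_hz * rng.uniform(0.85, 1.15)
            f2 = truth_config.drift_freq_hz * rng.uniform(0.6, 1.6)
            course = np.sin(2 * np.pi * f1 * t + p1) + \
                np.sin(2 * np.pi * f2 * t + p2)
            return truth_config.superficial_channel_um * course / 2.0

        regs = {}
        for task in tasks:
            trials = schedule.trials_for(r, task)
            regs[task] = task_regressor([x.onset_s for x in trials],
                                        [x.duration_s for x in trials], fs, n,
                                        hrf=hrf)
        hbo = np.zeros((n_ch, n))
        hbr = np.zeros((n_ch, n))
        hbr_scale = (truth_config.superficial_hbr_um /
                     truth_config.superficial_hbo_um
                     if truth_config.superficial_hbo_um else 0.0)
        for k in ndcs:
            resp = np.zeros(n)
            for task in tasks:
                resp += amplitudes[(k, task)] * regs[task]
            local = _local_course()
            hbo[k] = resp + sup_hbo + local
            hbr[k] = truth_config.hbr_ratio * resp + sup_hbr + hbr_scale * local
        for k in sdcs:
            local = _local_course()
            hbo[k] = truth_config.sdc_coupling * sup_hbo + local
            hbr[k] = truth_config.sdc_coupling * sup_hbr + hbr_scale * local
        conc_hbo_runs.append(hbo.copy())
        conc_hbr_runs.append(hbr.copy())

        inten = np.empty((n_ch, 2, n))
        for k, ch in enumerate(setup.channels):
            od = concentration_to_od(hbo[k], hbr[k], ch["distance_mm"],
                                     truth_config.age_years)
            sd = truth_config.noise_sd_od
            if bad[k]:
                # a poorly coupled optode: noise large enough to trip the
                # coefficient-of-variation rejection
                sd = truth_config.bad_channel_cv_pct / 100.0
            for w in range(2):
                noise = _ar_noise(rng, n, truth_config.ar_coeffs, sd)
                art, times = _motion_artifacts(rng, n, fs, truth_config, sd)
                if times:
                    artifact_times.setdefault((r, k), []).extend(times)
                od_w = od[w] + noise + art
                inten[k, w] = truth_config.baseline_intensity * np.exp(-od_w)
        intensity_runs.append(inten)

    rec = FnirsRecording(intensity=intensity_runs, fs=fs,
                         wavelengths_nm=WAVELENGTHS_NM, setup=setup,
                         schedule=schedule, age_years=truth_config.age_years)
    truth = GroundTruth(amplitudes_um=amplitudes, superficial_hbo_um=sup_runs,
                        artifact_times_s=artifact_times,
                        noise_params={"ar_coeffs": truth_config.ar_coeffs,
                                      "sd_od": truth_config.noise_sd_od},
                        conc_hbo_um=conc_hbo_runs, conc_hbr_um=conc_hbr_runs)
    # record the SDC mapping used
    truth.noise_params["sdc_for_ndc"] = sdc_of
    return rec, truth


def _motion_artifacts(rng, n, fs, cfg: TruthConfig, sd):
    """Additive spikes and baseline shifts in OD; returns (series, onset list)."""
    art = np.zeros(n)
    times = []
    if sd <= 0:
        return art, times
    minutes = n / fs / 60.0
    for _ in range(rng.poisson(cfg.spike_rate_per_min * minutes)):
        i0 = int(rng.integers(0, n))
        w = max(1, int(round(cfg.spike_duration_s * fs)))
        amp = cfg.spike_sd_multiple * sd * rng.choice([-1, 1])
        shape = np.hanning(2 * w + 1)[w:]
        seg = min(w + 1, n - i0)
        art[i0:i0 + seg] += amp * shape[:seg]
        times.append(i0 / fs)
    for _ in range(rng.poisson(cfg.shift_rate_per_min * minutes)):
        i0 = int(rng.integers(0, n))
        amp = cfg.shift_sd_multiple * sd * rng.choice([-1, 1])
        art[i0:] += amp
        times.append(i0 / fs)
    return art, times
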