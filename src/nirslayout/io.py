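"""Configuration, seed derivation, and file I/O shared by all stages.

SNIRF (HDF5) is the canonical recording format; NIfTI carries volumes with a
JSON sidecar for the tissue-code dictionary; events mirror to BIDS-style
TSV; configuration is YAML.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .design import APPROACHES
from .simulate import SAMPLING_RATE_HZ, TruthConfig

__all__ = [
    "StudyConfig",
    "validate_config",
    "derive_seed",
    "atomic_write",
    "write_snirf",
    "read_snirf",
    "write_events_tsv",
    "read_events_tsv",
]


def derive_seed(master: int, *labels) -> int:
    """Stable per-stage seed below 2**31, derived by hashing the labels."""
    h = int(master) & 0x7FFFFFFF
    for label in labels:
        h = zlib.crc32(str(label).encode(), h) & 0x7FFFFFFF
    return h


def atomic_write(path, data: bytes | str) -> None:
    mode = "wb" if isinstance(data, bytes) else "w"
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d)
    try:
        with os.fdopen(fd, mode) as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """All stage parameters with the study's default conditions.

    Acquisition and analysis constants default to the protocol values
    (10-s trials, 22 +/- 2 s rest, 6 runs, 7.8125 Hz, 760/850 nm, 8-mm
    short channels, 25-40 mm normal channels, CV threshold 7.5%, band-pass
    [0.008, 0.25] Hz at order 1000, DCT cutoff 0.009 Hz, AR order up to
    4 x fs, ROI contrast 0.5/0.5, CNR windows [-4,0] and [5,15] s, 20-mm
    projection sphere).  Geometry and photon counts are the desk-scale
    synthetic-study sizes described in the methods note.
    """

    n_subjects: int = 16
    #: tasks measured in the fNIRS session (two of the three)
    tasks: tuple = ("mental_calculation", "mental_rotation")
    #: tasks for which layouts are designed (all three mental-imagery tasks)
    design_tasks: tuple = ("inner_speech", "mental_calculation",
                           "mental_rotation")
    approaches: tuple = APPROACHES
    # phantom geometry
    head_radius_mm: float = 40.0
    subject_resolution_mm: float = 1.0
    atlas_resolution_mm: float = 2.0
    scalp_mm: float = 3.0
    skull_mm: float = 4.0
    csf_mm: float = 2.0
    gm_mm: float = 4.0
    thickness_jitter_mm: float = 0.4
    vasculature_density: float = 0.015
    # functional ROIs
    roi_radius_mm: float = 9.0
    roi_center_jitter_mm: float = 5.0
    anatomical_offset_mm: float = 15.0
    # scalp positions
    n_positions: int = 130
    min_position_spacing_mm: float = 4.0
    # photon transport; the shared atlas engine stands in for a precomputed
    # high-photon database, and its one-time cost is amortized over the
    # cohort, so it defaults to 4x the per-subject count (None -> 4x)
    n_photons: int = 8000
    n_photons_atlas: int | None = None
    sensitivity_domain: str = "gm+wm"
    # channel constraints
    enum_distance_mm: tuple = (20.0, 45.0)
    channel_distance_mm: tuple = (25.0, 40.0)
    merge_radius_mm: float = 5.0
    sdc_distance_mm: float = 8.0
    shared_role: str = "source"
    # schedule
    n_runs: int = 6
    n_trials_per_task_per_run: int = 6
    trial_duration_s: float = 10.0
    rest_choices_s: tuple = (20, 21, 22, 23, 24)
    fs: float = SAMPLING_RATE_HZ
    # forward model
    truth: TruthConfig = field(default_factory=TruthConfig)
    # preprocessing / analysis
    cv_threshold_percent: float = 7.5
    filter_band_hz: tuple = (0.008, 0.25)
    filter_order: int = 1000
    dct_cutoff_hz: float = 0.009
    ar_max_order_factor: float = 4.0
    alpha: float = 0.05
    cnr_pre_window_s: tuple = (-4.0, 0.0)
    cnr_dur_window_s: tuple = (5.0, 15.0)
    block_pre_s: float = 4.0
    block_post_s: float = 15.0
    min_subjects_per_task: int = 5
    projection_radius_mm: float = 20.0
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save_yaml(self, path) -> None:
        atomic_write(path, yaml.safe_dump(_yaml_safe(self.to_dict()),
                                          sort_keys=False))


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


_ALL_TASKS = ("inner_speech", "mental_calculation", "mental_rotation")


def validate_config(raw: dict | str | None) -> StudyConfig:
    """Build a StudyConfig from a (possibly partial) mapping or YAML path,
    checking units and cross-constraints; each violation names the config
    path and the default."""
    if raw is None:
        raw = {}
    if isinstance(raw, (str, os.PathLike)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "truth" in kwargs and isinstance(kwargs["truth"], dict):
        kwargs["truth"] = TruthConfig(**kwargs["truth"])
    for key in ("tasks", "design_tasks", "approaches", "enum_distance_mm",
                "channel_distance_mm",
                "rest_choices_s", "filter_band_hz", "cnr_pre_window_s",
                "cnr_dur_window_s"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    cfg = StudyConfig(**kwargs)

    def bad(path, msg, default):
        raise ValueError(f"config {path}: {msg} (default {default})")

    if not all(t in _ALL_TASKS for t in cfg.tasks):
        bad("tasks", f"must be chosen from {_ALL_TASKS}", StudyConfig.tasks)
    if len(cfg.tasks) != 2:
        bad("tasks", "exactly two of the three mental-imagery tasks are "
            "selected per subject", StudyConfig.tasks)
    if not all(t in _ALL_TASKS for t in cfg.design_tasks):
        bad("design_tasks", f"must be chosen from {_ALL_TASKS}", _ALL_TASKS)
    if not set(cfg.tasks) <= set(cfg.design_tasks):
        bad("design_tasks", "must include every measured task", _ALL_TASKS)
    if not all(a in APPROACHES for a in cfg.approaches):
        bad("approaches", f"must be chosen from {APPROACHES}", APPROACHES)
    lo, hi = cfg.enum_distance_mm
    if lo > hi:
        bad("enum_distance_mm", "lower bound exceeds upper bound", (20.0, 45.0))
    lo, hi = cfg.channel_distance_mm
    if lo > hi:
        bad("channel_distance_mm", "lower bound exceeds upper bound", (25.0, 40.0))
    f_lo, f_hi = cfg.filter_band_hz
    if not 0 < f_lo < f_hi:
        bad("filter_band_hz", "band must satisfy 0 < low < high", (0.008, 0.25))
    if f_hi >= cfg.fs / 2:
        bad("filter_band_hz", f"high cutoff {f_hi} Hz is not below the Nyquist "
            f"frequency {cfg.fs / 2} Hz", (0.008, 0.25))
    if cfg.n_photons <= 0:
        bad("n_photons", "photon count must be positive", 8000)
    if cfg.n_subjects < 3:
        bad("n_subjects", "leave-one-out maps need at least 3 subjects", 16)
    if not 0 <= cfg.truth.age_years <= 120:
        bad("truth.age_years", "age must be in [0, 120]", 29.81)
    return cfg


# ---------------------------------------------------------------------------
# SNIRF (minimal v1 subset on HDF5)
# ---------------------------------------------------------------------------

def _h5str(value: str):
    return np.bytes_(value.encode())


def write_snirf(path, recording, run: int = 0) -> None:
    """Write one run of a simulated recording as a SNIRF v1 file.

    Measurements are ordered channel-major, wavelength-minor, wavelengths
    stored in ascending order (760, 850).
    """
    import h5py

    setup = recording.setup
    sources = [i for i, r in enumerate(setup.roles) if r == "source"]
    detectors = [i for i, r in enumerate(setup.roles) if r == "detector"]
    src_of = {opt: k + 1 for k, opt in enumerate(sources)}
    det_of = {opt: k + 1 for k, opt in enumerate(detectors)}
    inten = recording.intensity[run]
    n_ch, n_wl, n_t = inten.shape
    data = np.empty((n_t, n_ch * n_wl))
    for c in range(n_ch):
        for w in range(n_wl):
            data[:, c * n_wl + w] = inten[c, w]

    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".snirf")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("formatVersion", data=_h5str("1.0"))
            nirs = f.create_group("nirs")
            meta = nirs.create_group("metaDataTags")
            meta.create_dataset("SubjectID", data=_h5str("synthetic"))
            meta.create_dataset("MeasurementDate", data=_h5str("2000-01-01"))
            meta.create_dataset("MeasurementTime", data=_h5str("00:00:00"))
            meta.create_dataset("LengthUnit", data=_h5str("mm"))
            meta.create_dataset("TimeUnit", data=_h5str("s"))
            meta.create_dataset("FrequencyUnit", data=_h5str("Hz"))
            d1 = nirs.create_group("data1")
            d1.create_dataset("dataTimeSeries", data=data)
            d1.create_dataset("time", data=np.arange(n_t) / recording.fs)
            for m in range(n_ch * n_wl):
                c, w = divmod(m, n_wl)
                ch = setup.channels[c]
                ml = d1.create_group(f"measurementList{m + 1}")
                ml.create_dataset("sourceIndex", data=src_of[ch["source"]])
                ml.create_dataset("detectorIndex", data=det_of[ch["detector"]])
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
            probe = nirs.create_group("probe")
            probe.create_dataset("wavelengths",
                                 data=np.asarray(recording.wavelengths_nm, float))
            probe.create_dataset("sourcePos3D",
                                 data=setup.optode_positions[sources])
            probe.create_dataset("detectorPos3D",
                                 data=setup.optode_positions[detectors])
            for s_i, task in enumerate(recording.schedule.tasks()):
                trials = recording.schedule.trials_for(run, task)
                stim = nirs.create_group(f"stim{s_i + 1}")
                stim.create_dataset("name", data=_h5str(task))
                arr = np.array([[t.onset_s, t.duration_s, 1.0] for t in trials])
                stim.create_dataset("data", data=arr if len(trials) else
                                    np.empty((0, 3)))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass
class SnirfRun:
    """Lightweight in-memory view of one SNIRF run."""

    intensity: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    time_s: np.ndarray
    fs: float
    wavelengths_nm: tuple
    channels: list  # dicts: source, detector (0-based optode-list indices)
    source_pos: np.ndarray
    detector_pos: np.ndarray
    events: list  # (task, onset_s, duration_s)
    meta: dict


def read_snirf(path) -> SnirfRun:
    """Read the SNIRF subset written by :func:`write_snirf`.

    Wavelength order is normalized to ascending (760 before 850) regardless
    of the file order; a missing stim block yields an empty event list with
    a warning.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise ValueError("malformed SNIRF: missing /nirs")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise ValueError("malformed SNIRF: missing /nirs/data1")
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        wl = tuple(np.asarray(nirs["probe"]["wavelengths"]).tolist())
        order = np.argsort(wl)
        wl_sorted = tuple(np.asarray(wl)[order].tolist())
        mls = sorted((k for k in d1 if k.startswith("measurementList")),
                     key=lambda k: int(k[len("measurementList"):]))
        if not mls:
            raise ValueError("malformed SNIRF: /nirs/data1 has no measurementList")
        meas = []
        for k in mls:
            g = d1[k]
            meas.append((int(g["sourceIndex"][()]), int(g["detectorIndex"][()]),
                         int(g["wavelengthIndex"][()])))
        pairs = []
        for s, d_, _ in meas:
            if (s, d_) not in pairs:
                pairs.append((s, d_))
        n_wl = len(wl)
        inten = np.empty((len(pairs), n_wl, data.shape[0]))
        for m, (s, d_, w) in enumerate(meas):
            c = pairs.index((s, d_))
            w_sorted = int(np.flatnonzero(order == (w - 1))[0])
            inten[c, w_sorted] = data[:, m]
        events = []
        for k in sorted(k for k in nirs if k.startswith("stim")):
            g = nirs[k]
            name = bytes(g["name"][()]).decode()
            arr = np.asarray(g["data"])
            for row in arr.reshape(-1, 3):
                events.append((name, float(row[0]), float(row[1])))
        if not events and not any(k.startswith("stim") for k in nirs):
            warnings.warn("SNIRF file carries no stimulus events")
        fs = 1.0 / float(np.median(np.diff(time))) if time.size > 1 else 0.0
        meta = {}
        if "metaDataTags" in nirs:
            for k, v in nirs["metaDataTags"].items():
                try:
                    meta[k] = bytes(v[()]).decode()
                except Exception:
                    meta[k] = v[()]
        return SnirfRun(
            intensity=inten, time_s=time, fs=fs, wavelengths_nm=wl_sorted,
            channels=[{"source": s - 1, "detector": d_ - 1} for s, d_ in pairs],
            source_pos=np.asarray(nirs["probe"]["sourcePos3D"]),
            detector_pos=np.asarray(nirs["probe"]["detectorPos3D"]),
            events=sorted(events, key=lambda e: e[1]), meta=meta)


def write_events_tsv(path, schedule, run: int) -> None:
    import pandas as pd

    rows = [{"onset": t.onset_s, "duration": t.duration_s, "trial_type": t.task}
            for t in schedule.runs[run]]
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    atomic_write(path, df.to_csv(sep="\t", index=False))


def read_events_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
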