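"""Candidate-channel enumeration, the seeded two-channel layout optimizer,
setup merging, and layout-similarity measures.

A layout is two channels sharing one common optode (three optodes total),
with both interoptode distances inside the 25-40 mm signal-to-noise window.
The optimizer sweeps every candidate channel as a seed, pairs it with the
best remaining channel that shares one of its optodes, and keeps the pair
with the largest summed %-sensitivity; the sweep is exhaustive over
optode-sharing pairs by construction.  Channel selection is role-free (any
scalp position may act as source or detector); optode roles are assigned at
hardware assembly, where the shared optode becomes the source by default so
a merged eight-layout setup carries eight sources and eight short-distance
channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Channel",
    "Layout",
    "CombinedSetup",
    "enumerate_channels",
    "optimize_layout",
    "design_approach_layout",
    "merge_setups",
    "layout_similarity",
    "APPROACHES",
]

log = logging.getLogger(__name__)

APPROACHES = ("LIT", "PROB", "iFMRI", "fVASC")

#: ROI kind each design approach scores channels against.
APPROACH_ROI_KIND = {
    "LIT": "anatomical",
    "PROB": "probabilistic",
    "iFMRI": "individual",
    "fVASC": "individual",
}


@dataclass(frozen=True)
class Channel:
    """An unordered optode pair; indices refer to a ScalpPositionSet."""

    source_index: int
    detector_index: int
    distance_mm: float
    sensitivity_percent: float = 0.0

    @property
    def pair(self):
        return tuple(sorted((self.source_index, self.detector_index)))


@dataclass
class Layout:
    """Two channels sharing one optode (or one channel in the degenerate
    no-partner case), with the summed %-sensitivity."""

    channels: list
    total_sensitivity: float
    approach: str = ""
    task: str = ""
    shared_optode: int | None = None
    degenerate: bool = False

    @property
    def optode_indices(self) -> list:
        seen = []
        for ch in self.channels:
            for idx in (ch.source_index, ch.detector_index):
                if idx not in seen:
                    seen.append(idx)
        return seen

    def cog(self, positions: np.ndarray) -> np.ndarray:
        return positions[self.optode_indices].mean(axis=0)


def enumerate_channels(positions: np.ndarray, d_min: float = 20.0,
                       d_max: float = 45.0) -> list:
    """All unordered position pairs with distance in [d_min, d_max]."""
    if d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least two positions")
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    out = []
    n = positions.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if d_min <= dist[i, j] <= d_max:
                out.append(Channel(source_index=i, detector_index=j,
                                   distance_mm=float(dist[i, j])))
    return out


def _with_sensitivity(channels, sensitivities) -> list:
    out = []
    for k, ch in enumerate(channels):
        if isinstance(sensitivities, dict):
            s = sensitivities[ch.pair]
        elif np.ndim(sensitivities) == 2:
            s = sensitivities[ch.source_index, ch.detector_index]
        else:
            s = sensitivities[k]
        out.append(Channel(ch.source_index, ch.detector_index, ch.distance_mm,
                           float(s)))
    return out


def optimize_layout(channels: list, sensitivities=None, d_min: float = 25.0,
                    d_max: float = 40.0, approach: str = "", task: str = "",
                    shared_role: str = "source") -> Layout:
    """Seeded sweep maximizing the summed sensitivity of two optode-sharing
    channels.

    Every candidate serves once as the seed; for each seed and each of its
    two optodes as the shared one, the best remaining channel containing
    that optode is the partner.  Ties break toward the lexicographically
    smallest (sorted) index pair.  With no feasible partner anywhere, the
    best single channel is returned as a degenerate one-channel layout.
    ``shared_role`` names the hardware role given to the shared optode and
    does not affect selection (positions are role-free).
    """
    if not channels:
        raise ValueError("empty channel list")
    if sensitivities is not None:
        channels = _with_sensitivity(channels, sensitivities)
    pruned = [c for c in channels if d_min <= c.distance_mm <= d_max]
    if not pruned:
        raise ValueError(
            f"no candidate channel inside [{d_min}, {d_max}] mm")
    order = sorted(pruned, key=lambda c: (-c.sensitivity_percent, c.pair))

    # channels indexed by optode for partner lookup
    by_optode: dict = {}
    for c in order:
        for o in c.pair:
            by_optode.setdefault(o, []).append(c)

    best = None  # (neg total, pair_a, pair_b, seed, partner, shared)
    for seed_ch in order:
        for shared in seed_ch.pair:
            for partner in by_optode.get(shared, ()):
                if partner.pair == seed_ch.pair:
                    continue
                total = seed_ch.sensitivity_percent + partner.sensitivity_percent
                a, b = sorted((seed_ch.pair, partner.pair))
                key = (-total, a, b)
                if best is None or key < best[0]:
                    best = (key, seed_ch, partner, shared)
                break  # list is sorted: first valid partner is the best
    if best is None:
        top = order[0]
        log.warning("no two channels share an optode; returning a degenerate "
                    "one-channel layout")
        return Layout(channels=[top], total_sensitivity=top.sensitivity_percent,
                      approach=approach, task=task, shared_optode=None,
                      degenerate=True)
    _, seed_ch, partner, shared = best
    pair = sorted((seed_ch, partner), key=lambda c: c.pair)
    total = seed_ch.sensitivity_percent + partner.sensitivity_percent
    return Layout(channels=pair, total_sensitivity=float(total),
                  approach=approach, task=task, shared_optode=int(shared))


def design_approach_layout(approach: str, subject_data, task: str,
                           d_enum=(20.0, 45.0), d_opt=(25.0, 40.0),
                           shared_role: str = "source") -> Layout:
    """Score candidate channels for one approach and task, then optimize.

    ``subject_data`` must provide, per approach, a SensitivityEngine on the
    approach's phantom/optics and an ROIMap of the approach's kind (see
    ``nirslayout.evaluate.SubjectModel``); LIT runs on the shared atlas
    phantom with the anatomical ROI, PROB/iFMRI on the subject phantom with
    the probabilistic/individual ROI, and fVASC on the subject phantom with
    vasculature tissue and the individual ROI.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    try:
        engine = subject_data.engine_for(approach)
        roi = subject_data.roi_for(approach, task)
    except KeyError as exc:
        raise ValueError(
            f"approach {approach} is missing required input: {exc}") from exc
    channels = enumerate_channels(engine.positions, *d_enum)
    sens = engine.sensitivity_matrix(roi)
    layout = optimize_layout(channels, sens, d_min=d_opt[0], d_max=d_opt[1],
                             approach=approach, task=task,
                             shared_role=shared_role)
    return layout


@dataclass
class CombinedSetup:
    """Merged per-subject montage.

    ``optode_positions`` are physical positions (mm) after merging optodes
    closer than the merge radius; ``roles`` is "source" or "detector" per
    physical optode; ``channels`` are (source, detector) indices into the
    physical optode list with distances and SDC flags; ``memberships`` maps
    (approach, task) to the channel indices of that layout.
    """

    optode_positions: np.ndarray
    roles: list
    channels: list  # dicts: source, detector, distance_mm, is_sdc
    memberships: dict
    n_premerge_optodes: int = 0

    @property
    def n_sources(self) -> int:
        return sum(1 for r in self.roles if r == "source")

    def ndc_indices(self) -> list:
        return [k for k, c in enumerate(self.channels) if not c["is_sdc"]]

    def sdc_indices(self) -> list:
        return [k for k, c in enumerate(self.channels) if c["is_sdc"]]

    def sdc_for_ndc(self) -> dict:
        """Nearest SDC (by source-optode distance) for every NDC."""
        sdcs = self.sdc_indices()
        out = {}
        for k in self.ndc_indices():
            mid_k = self._channel_mid(k)
            best = min(sdcs, key=lambda s: np.linalg.norm(self._channel_mid(s) - mid_k))
            out[k] = best
        return out

    def _channel_mid(self, k: int) -> np.ndarray:
        c = self.channels[k]
        return 0.5 * (self.optode_positions[c["source"]] +
                      self.optode_positions[c["detector"]])


def merge_setups(layouts: list, positions: np.ndarray, merge_radius_mm: float = 5.0,
                 sdc_distance_mm: float = 8.0, shared_role: str = "source",
                 phantom=None) -> CombinedSetup:
    """Combine per-approach/task layouts into one physical montage.

    Optode positions closer than ``merge_radius_mm`` collapse into one
    physical optode (greedy, deterministic order).  The shared optode of
    each layout takes ``shared_role``; its partner optodes the complementary
    role.  A role conflict at a merged optode is resolved by splitting the
    physical optode in two at a minimal tangential offset (logged).  One
    short-distance detector is placed ``sdc_distance_mm`` from every source.
    """
    positions = np.asarray(positions, dtype=float)
    wanted = []  # (pos, role, layout_key, which)
    for layout in layouts:
        key = (layout.approach, layout.task)
        outer_role = "detector" if shared_role == "source" else "source"
        for ch in layout.channels:
            for idx in ch.pair:
                role = shared_role if idx == layout.shared_optode else outer_role
                wanted.append((positions[idx], role, key, ch.pair))
    n_premerge = len({(tuple(np.round(p, 6)), k) for p, _, k, _ in wanted})
    # count unique optodes per layout then total
    per_layout: dict = {}
    for p, _, k, _ in wanted:
        per_layout.setdefault(k, set()).add(tuple(np.round(p, 6)))
    n_premerge = sum(len(v) for v in per_layout.values())

    phys_pos: list = []
    phys_role: list = []

    def _find_or_add(p, role):
        for i, (q, r) in enumerate(zip(phys_pos, phys_role)):
            if np.linalg.norm(np.asarray(q) - p) < merge_radius_mm:
                if r == role:
                    return i
        # no same-role optode nearby; check role conflict with co-located optode
        for i, (q, r) in enumerate(zip(phys_pos, phys_role)):
            if np.linalg.norm(np.asarray(q) - p) < 1e-9 and r != role:
                log.info("role conflict at %s: duplicating optode with offset", p)
                p = p + np.array([1.0, 0.0, 0.0])
                break
        phys_pos.append(np.asarray(p, dtype=float))
        phys_role.append(role)
        return len(phys_pos) - 1

    memberships: dict = {}
    channels: list = []
    chan_index: dict = {}
    for layout in layouts:
        key = (layout.approach, layout.task)
        outer_role = "detector" if shared_role == "source" else "source"
        members = []
        for ch in layout.channels:
            idx_roles = []
            for idx in ch.pair:
                role = shared_role if idx == layout.shared_optode else outer_role
                idx_roles.append(_find_or_add(positions[idx], role))
            a, b = idx_roles
            if phys_role[a] == "source":
                src, det = a, b
            else:
                src, det = b, a
            ck = (src, det)
            if ck not in chan_index:
                chan_index[ck] = len(channels)
                channels.append({
                    "source": src, "detector": det,
                    "distance_mm": float(np.linalg.norm(
                        np.asarray(phys_pos[src]) - np.asarray(phys_pos[det]))),
                    "is_sdc": False,
                })
            members.append(chan_index[ck])
        memberships[key] = members

    # short-distance detectors: one per physical source
    pos_arr = np.array(phys_pos)
    for src_idx in [i for i, r in enumerate(phys_role) if r == "source"]:
        offset = _tangential_offset(phantom, pos_arr[src_idx], sdc_distance_mm)
        sdc_pos = pos_arr[src_idx] + offset
        phys_pos.append(sdc_pos)
        phys_role.append("detector")
        det_idx = len(phys_pos) - 1
        channels.append({"source": src_idx, "detector": det_idx,
                         "distance_mm": float(sdc_distance_mm), "is_sdc": True})

    return CombinedSetup(optode_positions=np.array(phys_pos), roles=phys_role,
                         channels=channels, memberships=memberships,
                         n_premerge_optodes=n_premerge)


def _tangential_offset(phantom, pos: np.ndarray, dist: float) -> np.ndarray:
    """Offset along the scalp surface (tangent plane) for SDC placement."""
    if phantom is None:
        normal = np.array([0.0, 0.0, 1.0])
    else:
        center = np.append(phantom.center_xy, 0.0)
        normal = pos - center
        n = np.linalg.norm(normal)
        normal = normal / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    tang = np.cross(normal, ref)
    tang /= np.linalg.norm(tang)
    return tang * dist


def layout_similarity(a: Layout, b: Layout, positions: np.ndarray):
    """(number of shared channels, Euclidean COG distance in mm)."""
    positions = np.asarray(positions, dtype=float)
    pairs_a = {c.pair for c in a.channels}
    pairs_b = {c.pair for c in b.channels}
    overlap = len(pairs_a & pairs_b)
    dist = float(np.linalg.norm(a.cog(positions) - b.cog(positions)))
    return overlap, dist
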