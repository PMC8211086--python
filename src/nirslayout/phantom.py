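"""Synthetic layered head phantoms, scalp position sets, and functional ROI cohorts.

The phantom is a concentric-layer ("onion") hemisphere on a regular voxel
grid: outside -> scalp -> skull -> CSF -> gray matter -> white matter along
depth, with optional vasculature carved as thin tubes inside scalp and gray
matter.  The geometry is deliberately idealized: the downstream algorithms
(photon transport, channel scoring, layout optimization) depend only on the
labeled tissue-depth structure, not on realistic cortical folding.

Coordinate convention: 0-based voxel indices, voxel centers at
``(i + 0.5) * resolution_mm`` millimetres, right-handed axes, hemisphere dome
pointing toward +z with the flat base at z = 0.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUES",
    "TISSUE_NAMES",
    "OpticalProperties",
    "TABLE_OPTICAL_PROPERTIES",
    "HeadPhantom",
    "PhantomConfig",
    "ScalpPositionSet",
    "ROIMap",
    "ROICohort",
    "build_phantom",
    "build_slab_phantom",
    "sample_scalp_positions",
    "generate_roi_cohort",
]

#: Integer tissue codes used in every label grid.
TISSUES = {
    "outside": 0,
    "scalp": 1,
    "skull": 2,
    "csf": 3,
    "gray_matter": 4,
    "white_matter": 5,
    "vasculature": 6,
}
TISSUE_NAMES = {v: k for k, v in TISSUES.items()}


@dataclass(frozen=True)
class OpticalProperties:
    """Per-tissue optical coefficients.

    Arrays are indexed by tissue code: ``mu_s`` scattering (mm^-1), ``g``
    anisotropy, ``mu_a`` absorption (mm^-1), ``n`` refractive index.
    Tissue code 0 (outside) carries zeros and is never traversed.
    """

    mu_s: np.ndarray
    g: np.ndarray
    mu_a: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for name in ("mu_s", "mu_a"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(np.abs(self.g) >= 1):
            raise ValueError("|g| must be < 1")

    @property
    def mu_t(self) -> np.ndarray:
        return self.mu_a + self.mu_s

    def replace(self, tissue: str, **coeffs) -> "OpticalProperties":
        code = TISSUES[tissue]
        arrays = {f.name: getattr(self, f.name).copy() for f in dataclasses.fields(self)}
        for key, value in coeffs.items():
            arrays[key][code] = value
        return OpticalProperties(**arrays)


def _default_optics() -> OpticalProperties:
    # Mean-wavelength coefficients per tissue: (mu_s, g, mu_a, n), one
    # effective wavelength for transport (no per-wavelength Jacobians).
    rows = {
        "outside": (0.0, 0.0, 0.0, 1.0),
        "scalp": (0.72, 0.01, 0.017275, 1.0),
        "skull": (0.92, 0.01, 0.011925, 1.0),
        "csf": (0.01, 0.01, 0.002500, 1.0),
        "gray_matter": (1.10, 0.01, 0.019500, 1.0),
        "white_matter": (1.35, 0.01, 0.016900, 1.0),
        "vasculature": (73.31, 0.405, 0.9825, 1.0),
    }
    n_t = len(TISSUES)
    mu_s = np.zeros(n_t)
    g = np.zeros(n_t)
    mu_a = np.zeros(n_t)
    n = np.ones(n_t)
    for name, (s, gg, a, nn) in rows.items():
        code = TISSUES[name]
        mu_s[code], g[code], mu_a[code], n[code] = s, gg, a, nn
    return OpticalProperties(mu_s=mu_s, g=g, mu_a=mu_a, n=n)


#: Default optical-property table (scattering, anisotropy, absorption,
#: refraction per tissue at the mean near-infrared wavelength).
TABLE_OPTICAL_PROPERTIES = _default_optics()


@dataclass
class HeadPhantom:
    """Labeled voxel grid plus grid metadata."""

    labels: np.ndarray  # int8, shape (nx, ny, nz)
    resolution_mm: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def center_xy(self) -> np.ndarray:
        """Center of the hemisphere base in mm (x, y)."""
        return np.asarray(self.meta.get(
            "center_xy", [self.shape[0] * self.resolution_mm / 2.0,
                          self.shape[1] * self.resolution_mm / 2.0]))

    def voxel_centers_mm(self, idx: np.ndarray) -> np.ndarray:
        return (np.asarray(idx, dtype=float) + 0.5) * self.resolution_mm

    def mm_to_voxel(self, pos_mm: np.ndarray) -> np.ndarray:
        return np.floor(np.asarray(pos_mm) / self.resolution_mm).astype(int)

    def tissue_mask(self, *names: str) -> np.ndarray:
        codes = [TISSUES[n] for n in names]
        return np.isin(self.labels, codes)

    def count_labels(self) -> dict:
        counts = np.bincount(self.labels.ravel(), minlength=len(TISSUES))
        return {TISSUE_NAMES[i]: int(c) for i, c in enumerate(counts)}

    def to_nifti(self, path, sidecar: bool = True) -> None:
        import nibabel as nib

        affine = np.diag([self.resolution_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))
        if sidecar:
            side = dict(self.meta)
            side["tissue_codes"] = TISSUES
            side["resolution_mm"] = self.resolution_mm
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=2, default=str)


@dataclass
class PhantomConfig:
    """Geometry of the onion hemisphere.

    Thicknesses are radial, in mm; everything deeper than the CSF and
    gray-matter shells is white matter.
    """

    radius_mm: float = 40.0
    scalp_mm: float = 3.0
    skull_mm: float = 4.0
    csf_mm: float = 2.0
    gm_mm: float = 4.0
    resolution_mm: float = 1.0
    margin_mm: float = 2.0
    vasculature_density: float = 0.0  # target voxel fraction inside scalp+GM
    vessel_radius_mm: float = 1.0
    vessel_length_mm: float = 15.0

    def validate(self) -> None:
        shells = self.scalp_mm + self.skull_mm + self.csf_mm + self.gm_mm
        if min(self.radius_mm, self.scalp_mm, self.skull_mm, self.csf_mm,
               self.gm_mm, self.resolution_mm) <= 0:
            raise ValueError("all geometry parameters must be positive")
        if shells >= self.radius_mm:
            raise ValueError(
                f"layer thicknesses ({shells} mm) exceed the phantom radius "
                f"({self.radius_mm} mm)")
        n = int(np.ceil(2 * (self.radius_mm + self.margin_mm) / self.resolution_mm))
        if n > 160:
            raise ValueError(f"grid of {n}^3 voxels exceeds the supported size")


def build_phantom(config: PhantomConfig, seed: int = 0) -> HeadPhantom:
    """Build a labeled onion-hemisphere phantom.

    Deterministic given ``(config, seed)``; the seed only affects vessel
    placement when ``vasculature_density > 0``.
    """
    config.validate()
    res = config.resolution_mm
    half = config.radius_mm + config.margin_mm
    n_xy = int(np.ceil(2 * half / res))
    n_z = int(np.ceil((config.radius_mm + config.margin_mm) / res))
    labels = np.zeros((n_xy, n_xy, n_z), dtype=np.int8)

    cx = cy = n_xy * res / 2.0
    ix = (np.arange(n_xy) + 0.5) * res
    iz = (np.arange(n_z) + 0.5) * res
    X, Y, Z = np.meshgrid(ix - cx, ix - cy, iz, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)

    R = config.radius_mm
    b_scalp = R - config.scalp_mm
    b_skull = b_scalp - config.skull_mm
    b_csf = b_skull - config.csf_mm
    b_gm = b_csf - config.gm_mm
    labels[(r <= R) & (r > b_scalp)] = TISSUES["scalp"]
    labels[(r <= b_scalp) & (r > b_skull)] = TISSUES["skull"]
    labels[(r <= b_skull) & (r > b_csf)] = TISSUES["csf"]
    labels[(r <= b_csf) & (r > b_gm)] = TISSUES["gray_matter"]
    labels[r <= b_gm] = TISSUES["white_matter"]

    if config.vasculature_density > 0:
        _carve_vessels(labels, r, config, seed)

    meta = {
        "kind": "onion_hemisphere",
        "config": dataclasses.asdict(config),
        "seed": int(seed),
        "center_xy": [cx, cy],
        "radius_mm": R,
        "axis_convention": "RAS-like, dome toward +z, base at z=0",
    }
    return HeadPhantom(labels=labels, resolution_mm=res, meta=meta)


def _carve_vessels(labels: np.ndarray, r: np.ndarray, config: PhantomConfig,
                   seed: int) -> None:
    """Mark thin random tube segments as vasculature inside scalp and GM."""
    rng = np.random.default_rng(seed)
    host = np.isin(labels, [TISSUES["scalp"], TISSUES["gray_matter"]])
    host_idx = np.argwhere(host)
    n_target = int(round(config.vasculature_density * host_idx.shape[0]))
    if n_target == 0:
        return
    res = config.resolution_mm
    carved = 0
    guard = 0
    while carved < n_target and guard < 10000:
        guard += 1
        start = host_idx[rng.integers(host_idx.shape[0])]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length_vox = config.vessel_length_mm / res
        t = np.arange(0, length_vox, 0.5)
        pts = np.round(start[None, :] + t[:, None] * direction[None, :]).astype(int)
        rad = max(1, int(round(config.vessel_radius_mm / res)) - 1)
        offs = np.argwhere(np.ones((2 * rad + 1,) * 3)) - rad
        vox = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        ok = np.all((vox >= 0) & (vox < np.array(labels.shape)), axis=1)
        vox = vox[ok]
        sel = host[vox[:, 0], vox[:, 1], vox[:, 2]] & (
            labels[vox[:, 0], vox[:, 1], vox[:, 2]] != TISSUES["vasculature"])
        vox = vox[sel]
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = TISSUES["vasculature"]
        carved += vox.shape[0]


def build_slab_phantom(shape=(80, 80, 60), resolution_mm: float = 1.0,
                       tissue: str = "gray_matter") -> HeadPhantom:
    """Homogeneous rectangular slab used for transport calibration.

    The entire grid carries one tissue label; the grid faces act as
    matched-index boundaries (photons leaving the grid are lost), so the
    top face approximates the boundary of a semi-infinite medium.
    """
    labels = np.full(shape, TISSUES[tissue], dtype=np.int8)
    meta = {"kind": "homogeneous_slab", "tissue": tissue}
    return HeadPhantom(labels=labels, resolution_mm=resolution_mm, meta=meta)


# ---------------------------------------------------------------------------
# Scalp positions
# ---------------------------------------------------------------------------

@dataclass
class ScalpPositionSet:
    """Quasi-uniform positions on the phantom's outer surface (mm)."""

    positions: np.ndarray  # (n, 3) mm
    labels: list

    def __len__(self):
        return self.positions.shape[0]


def _surface_voxels(phantom: HeadPhantom) -> np.ndarray:
    """Scalp voxels with at least one 6-neighbor outside the head."""
    lab = phantom.labels
    scalp = lab == TISSUES["scalp"]
    outside = lab == TISSUES["outside"]
    padded = np.pad(outside, 1, constant_values=True)
    near_out = np.zeros_like(scalp)
    for ax in range(3):
        for sh in (1, -1):
            near_out |= np.roll(padded, sh, axis=ax)[1:-1, 1:-1, 1:-1]
    return np.argwhere(scalp & near_out)


def sample_scalp_positions(phantom: HeadPhantom, n: int = 130, seed: int = 0,
                           min_spacing_mm: float = 4.0) -> ScalpPositionSet:
    """Farthest-point sampling of ``n`` surface positions.

    Emulates the extended 10-20 template as a quasi-uniform covering of the
    scalp surface; deterministic given the seed.
    """
    surf = _surface_voxels(phantom)
    if surf.shape[0] == 0:
        raise ValueError("phantom has no scalp surface")
    if n > surf.shape[0]:
        raise ValueError(
            f"requested {n} positions but only {surf.shape[0]} surface voxels "
            f"exist (achievable maximum {surf.shape[0]})")
    coords = phantom.voxel_centers_mm(surf)
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(coords.shape[0]))]
    d = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    while len(chosen) < n:
        nxt = int(np.argmax(d))
        if d[nxt] < min_spacing_mm:
            raise ValueError(
                f"cannot place {n} positions with spacing >= {min_spacing_mm} mm;"
                f" achievable maximum is {len(chosen)}")
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    positions = coords[chosen]
    labels = [f"P{i:03d}" for i in range(n)]
    return ScalpPositionSet(positions=positions, labels=labels)


# ---------------------------------------------------------------------------
# ROI maps and cohorts
# ---------------------------------------------------------------------------

@dataclass
class ROIMap:
    """Per-voxel ROI weights in [0, 1] on a phantom grid.

    ``kind`` is one of {"anatomical", "individual", "probabilistic"};
    individual maps are binary, probabilistic maps are leave-one-subject-out
    averages of the other subjects' binary maps.  Nonzero weights occur only
    in gray-matter voxels.
    """

    weights: np.ndarray
    kind: str
    task: str
    subject: str | None = None

    def __post_init__(self):
        w = self.weights
        if w.size and (w.min() < 0 or w.max() > 1):
            raise ValueError("ROI weights must lie in [0, 1]")


@dataclass
class ROICohort:
    """Per-subject individual + leave-one-out probabilistic maps, plus one
    anatomical map (on the atlas grid) and the generating geometry."""

    task: str
    individual: list  # ROIMap per subject (subject grid)
    probabilistic: list  # ROIMap per subject (subject grid)
    anatomical: ROIMap  # atlas grid
    centers_mm: np.ndarray  # (n_subjects, 3) true ROI centers
    base_center_mm: np.ndarray
    anatomical_center_mm: np.ndarray


def _cap_direction(task: str, task_angles: dict | None = None) -> np.ndarray:
    """Unit direction from the hemisphere center toward the task's ROI."""
    default = {
        "mental_calculation": (55.0, 45.0),
        "mental_rotation": (-60.0, 45.0),
        "inner_speech": (0.0, 55.0),
    }
    angles = dict(default)
    if task_angles:
        angles.update(task_angles)
    az_deg, el_deg = angles.get(task, (0.0, 60.0))
    az, el = np.deg2rad(az_deg), np.deg2rad(el_deg)
    return np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


def _gm_sphere_map(phantom: HeadPhantom, center_mm: np.ndarray,
                   radius_mm: float) -> np.ndarray:
    gm = phantom.tissue_mask("gray_matter")
    if not gm.any():
        raise ValueError("phantom has no gray-matter voxels")
    idx = np.argwhere(gm)
    coords = phantom.voxel_centers_mm(idx)
    inside = np.linalg.norm(coords - center_mm[None, :], axis=1) <= radius_mm
    w = np.zeros(phantom.shape, dtype=np.float64)
    sel = idx[inside]
    w[sel[:, 0], sel[:, 1], sel[:, 2]] = 1.0
    return w


def _tangential_jitter(rng, direction: np.ndarray, sd_mm: float) -> np.ndarray:
    """Random offset orthogonal to the radial direction."""
    v = rng.normal(size=3)
    v -= direction * (v @ direction)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        return np.zeros(3)
    return v / norm * abs(rng.normal(scale=sd_mm))


def generate_roi_cohort(phantoms: list, atlas_phantom: HeadPhantom, task: str,
                        n_subjects: int, seed: int = 0,
                        roi_radius_mm: float = 9.0,
                        center_jitter_mm: float = 5.0,
                        anatomical_offset_mm: float = 15.0,
                        task_angles: dict | None = None) -> ROICohort:
    """Generate a cohort of functional ROI maps for one mental-imagery task.

    Each subject's individual (binary) map is a gray-matter spherical cap
    centered at the task's base location plus a tangential per-subject
    jitter.  The subject's probabilistic map is the voxelwise mean of the
    *other* subjects' binary maps (leave-one-subject-out).  The anatomical
    map lives on the atlas grid and is displaced tangentially by
    ``anatomical_offset_mm``, emulating a literature-derived ROI that
    mislocates the cohort's true activation site.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for leave-one-out maps")
    if len(phantoms) != n_subjects:
        raise ValueError("one phantom per subject required")
    rng = np.random.default_rng(seed)
    direction = _cap_direction(task, task_angles)

    # Base center sits mid-gray-matter along the task direction.
    cfg = phantoms[0].meta.get("config", {})
    R = phantoms[0].meta.get("radius_mm", 40.0)
    depth = cfg.get("scalp_mm", 3.0) + cfg.get("skull_mm", 4.0) + \
        cfg.get("csf_mm", 2.0) + cfg.get("gm_mm", 4.0) / 2.0
    centers = []
    individual = []
    binaries = []
    for s, ph in enumerate(phantoms):
        base = np.append(ph.center_xy, 0.0) + direction * (R - depth)
        center = base + _tangential_jitter(rng, direction, center_jitter_mm)
        centers.append(center)
        w = _gm_sphere_map(ph, center, roi_radius_mm)
        binaries.append(w)
        individual.append(ROIMap(weights=w, kind="individual", task=task,
                                 subject=f"S{s:02d}"))

    probabilistic = []
    # Grids may differ across subjects in principle; the cohort generator
    # assumes a shared subject grid (asserted here) so the LOO mean is voxelwise.
    shapes = {b.shape for b in binaries}
    if len(shapes) != 1:
        raise ValueError("leave-one-out maps require a common subject grid")
    stack = np.stack(binaries)
    total = stack.sum(axis=0)
    for s in range(n_subjects):
        loo = (total - stack[s]) / (n_subjects - 1)
        probabilistic.append(ROIMap(weights=loo, kind="probabilistic", task=task,
                                    subject=f"S{s:02d}"))

    base_center = np.append(atlas_phantom.center_xy, 0.0) + direction * (R - depth)
    anat_center = base_center + _fixed_tangential(direction) * anatomical_offset_mm
    anat_w = _gm_sphere_map(atlas_phantom, anat_center, roi_radius_mm)
    if anat_w.sum() == 0:
        warnings.warn("anatomical ROI fell outside gray matter; empty map")
    anatomical = ROIMap(weights=anat_w, kind="anatomical", task=task)

    return ROICohort(task=task, individual=individual, probabilistic=probabilistic,
                     anatomical=anatomical, centers_mm=np.asarray(centers),
                     base_center_mm=base_center, anatomical_center_mm=anat_center)


def _fixed_tangential(direction: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to ``direction``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    v = np.cross(direction, ref)
    return v / np.linalg.norm(v)
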