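"""Voxel Monte Carlo photon transport, PMDFs, and channel-to-ROI sensitivity.

The kernel is a weighted random walk on the labeled voxel grid: step lengths
are sampled from an exponential with the total attenuation ``mu_t = mu_a +
mu_s`` of the tissue at the photon's current voxel, the fraction
``mu_a / mu_t`` of the photon weight is deposited at each interaction voxel,
scattering follows the Henyey-Greenstein phase function with the local
anisotropy ``g``, and low-weight photons are terminated by Russian roulette.
Refractive indices are all 1 (matched boundaries), so photons that leave the
grid are lost.  This is a desk-scale re-implementation of the standard
voxel photon-migration scheme; the step is sampled from the tissue at the
segment start, which blurs interfaces by at most one scattering length.

A channel's light-sensitivity profile (PMDF, the "banana") is the adjoint
product of the source and detector fluences, normalized to unit sum.  The
scalar %-sensitivity of a channel to an ROI is the PMDF mass inside the ROI
relative to the PMDF mass inside the brain domain (gray + white matter by
default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .phantom import TISSUES, HeadPhantom, OpticalProperties, ROIMap

__all__ = [
    "FluenceMap",
    "SensitivityProfile",
    "simulate_fluence",
    "compute_pmdf",
    "roi_sensitivity",
    "semi_infinite_diffusion_fluence",
    "SensitivityEngine",
]

log = logging.getLogger(__name__)

_W_MIN = 1e-3
_RR_SURVIVE = 0.1


@njit(cache=True, fastmath=True)
def _walk_kernel(labels, mu_t, albedo, g, res, x0, y0, z0, dx0, dy0, dz0,
                 n_photons, seed, dep):  # pragma: no cover - compiled
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    for _ in range(n_photons):
        x, y, z = x0, y0, z0
        ux, uy, uz = dx0, dy0, dz0
        w = 1.0
        alive = True
        while alive:
            ix = int(x / res)
            iy = int(y / res)
            iz = int(z / res)
            if x < 0.0 or y < 0.0 or z < 0.0 or ix >= nx or iy >= ny or iz >= nz:
                break
            lab = labels[ix, iy, iz]
            mt = mu_t[lab]
            if mt <= 0.0:
                # non-interacting voxel (outside): photon escaped
                break
            s = -math.log(np.random.random()) / mt
            x += ux * s
            y += uy * s
            z += uz * s
            jx = int(x / res)
            jy = int(y / res)
            jz = int(z / res)
            if x < 0.0 or y < 0.0 or z < 0.0 or jx >= nx or jy >= ny or jz >= nz:
                break
            lab2 = labels[jx, jy, jz]
            if mu_t[lab2] <= 0.0:
                break
            a = albedo[lab2]
            dep[jx, jy, jz] += w * a
            w *= 1.0 - a
            if w < _W_MIN:
                if np.random.random() > _RR_SURVIVE:
                    break
                w /= _RR_SURVIVE
            gg = g[lab2]
            if abs(gg) < 1e-6:
                ct = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                nux = st * cp
                nuy = st * sp
                nuz = ct * (1.0 if uz > 0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
            norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
            ux, uy, uz = nux / norm, nuy / norm, nuz / norm


@dataclass
class FluenceMap:
    """Deposited photon weight per voxel, normalized per emitted photon."""

    deposited: np.ndarray  # absorbed weight / photon, per voxel
    resolution_mm: float
    source_mm: np.ndarray
    photon_count: int
    seed: int

    def fluence(self, optics: OpticalProperties, labels: np.ndarray) -> np.ndarray:
        """Energy fluence per voxel (mm^-2 per emitted unit power):
        absorbed weight / (mu_a * voxel volume)."""
        mu_a = optics.mu_a[labels]
        vol = self.resolution_mm**3
        out = np.zeros_like(self.deposited)
        ok = mu_a > 0
        out[ok] = self.deposited[ok] / (mu_a[ok] * vol)
        return out


def _inward_direction(phantom: HeadPhantom, pos_mm: np.ndarray) -> np.ndarray:
    meta = phantom.meta
    if meta.get("kind") == "homogeneous_slab":
        return np.array([0.0, 0.0, 1.0]) if pos_mm[2] < \
            phantom.shape[2] * phantom.resolution_mm / 2 else np.array([0.0, 0.0, -1.0])
    center = np.append(phantom.center_xy, 0.0)
    d = center - np.asarray(pos_mm, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-9:
        return np.array([0.0, 0.0, -1.0])
    return d / n


def _check_on_surface(phantom: HeadPhantom, pos_mm: np.ndarray) -> None:
    if phantom.meta.get("kind") == "homogeneous_slab":
        return
    vox = phantom.mm_to_voxel(pos_mm)
    shape = np.array(phantom.shape)
    lo = np.maximum(vox - 2, 0)
    hi = np.minimum(vox + 3, shape)
    block = phantom.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if not np.any(block == TISSUES["scalp"]):
        raise ValueError(f"source position {pos_mm} is not on the scalp surface")


def simulate_fluence(phantom: HeadPhantom, optics: OpticalProperties,
                     position_mm, n_photons: int = 100_000, seed: int = 0,
                     direction=None) -> FluenceMap:
    """Launch a pencil beam at a scalp position and accumulate absorbed weight.

    Deterministic given the seed (single-threaded kernel).
    """
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1000")
    if np.all(optics.mu_t[1:] <= 0):
        raise ValueError("optical properties are all zero")
    pos = np.asarray(position_mm, dtype=float)
    _check_on_surface(phantom, pos)
    if direction is None:
        direction = _inward_direction(phantom, pos)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    # nudge the launch point just inside the medium
    start = pos + direction * (0.25 * phantom.resolution_mm)

    albedo = np.zeros_like(optics.mu_a)
    ok = optics.mu_t > 0
    albedo[ok] = optics.mu_a[ok] / optics.mu_t[ok]
    dep = np.zeros(phantom.shape, dtype=np.float64)
    _walk_kernel(phantom.labels, optics.mu_t, albedo, optics.g,
                 float(phantom.resolution_mm), start[0], start[1], start[2],
                 direction[0], direction[1], direction[2],
                 int(n_photons), int(seed) % (2**31 - 1), dep)
    dep /= n_photons
    return FluenceMap(deposited=dep, resolution_mm=phantom.resolution_mm,
                      source_mm=pos, photon_count=int(n_photons), seed=int(seed))


@dataclass
class SensitivityProfile:
    """Channel PMDF and its scalar %-sensitivities."""

    source_index: int
    detector_index: int
    distance_mm: float
    pmdf: np.ndarray
    roi_sensitivity_percent: dict = field(default_factory=dict)


def compute_pmdf(src_fluence: np.ndarray, det_fluence: np.ndarray) -> np.ndarray:
    """Adjoint PMDF: voxelwise product of the two fluences, unit-sum normalized."""
    if src_fluence.shape != det_fluence.shape:
        raise ValueError("source and detector fluence grids do not match")
    pmdf = src_fluence * det_fluence
    total = pmdf.sum()
    if total > 0:
        pmdf = pmdf / total
    return pmdf


def roi_sensitivity(pmdf: np.ndarray, roi, domain_mask: np.ndarray) -> float:
    """Percent of the PMDF's in-domain mass that falls inside the ROI."""
    weights = roi.weights if isinstance(roi, ROIMap) else np.asarray(roi)
    if pmdf.shape != weights.shape or pmdf.shape != domain_mask.shape:
        raise ValueError("pmdf, roi and domain grids do not match")
    denom = float(pmdf[domain_mask].sum())
    if denom <= 0:
        log.warning("PMDF carries no mass in the brain domain; sensitivity 0")
        return 0.0
    num = float((pmdf * weights)[domain_mask].sum())
    return 100.0 * num / denom


def semi_infinite_diffusion_fluence(optics: OpticalProperties, tissue: str,
                                    rho: np.ndarray, z: np.ndarray) -> np.ndarray:
    """CW diffusion-approximation fluence (mm^-2) for a pencil beam entering a
    semi-infinite homogeneous medium at the origin of the z>0 half-space.

    Uses the standard extrapolated-boundary image-source solution with the
    beam replaced by an isotropic point source at depth ``1/mu_s'``.
    """
    code = TISSUES[tissue]
    mu_a = optics.mu_a[code]
    mu_sp = optics.mu_s[code] * (1 - optics.g[code])
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = math.sqrt(mu_a / D)
    z0 = 1.0 / (mu_a + mu_sp)
    zb = 2.0 * D  # matched refractive index (A = 1)
    r1 = np.sqrt(rho**2 + (z - z0) ** 2)
    r2 = np.sqrt(rho**2 + (z + z0 + 2 * zb) ** 2)
    return (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4 * np.pi * D)


class SensitivityEngine:
    """Caches per-position fluences on one (phantom, optics) pair and scores
    channels against ROIs.

    The scalar sensitivity of channel (i, j) to an ROI factorizes into dot
    products of the two fluence vectors restricted to the brain domain, so
    pairwise denominators are a single Gram-matrix product.
    """

    def __init__(self, phantom: HeadPhantom, optics: OpticalProperties,
                 positions: np.ndarray, n_photons: int = 100_000, seed: int = 0,
                 domain: str = "gm+wm"):
        self.phantom = phantom
        self.optics = optics
        self.positions = np.asarray(positions, dtype=float)
        self.n_photons = int(n_photons)
        self.seed = int(seed)
        if domain == "gm+wm":
            names = ("gray_matter", "white_matter")
        elif domain == "gm":
            names = ("gray_matter",)
        else:
            raise ValueError(f"unknown sensitivity domain {domain!r}")
        self.domain_mask = phantom.tissue_mask(*names)
        self._mask_idx = np.flatnonzero(self.domain_mask.ravel())
        self._F = None  # (n_pos, n_mask) float32 fluence at domain voxels
        self._gram = None

    def _ensure_fluences(self) -> None:
        if self._F is not None:
            return
        n_pos = self.positions.shape[0]
        F = np.empty((n_pos, self._mask_idx.size), dtype=np.float32)
        for i in range(n_pos):
            fm = simulate_fluence(self.phantom, self.optics, self.positions[i],
                                  n_photons=self.n_photons,
                                  seed=self.seed + 7919 * i)
            flu = fm.fluence(self.optics, self.phantom.labels)
            F[i] = flu.ravel()[self._mask_idx]
        self._F = F

    @property
    def gram(self) -> np.ndarray:
        """Pairwise in-domain PMDF masses (unnormalized)."""
        self._ensure_fluences()
        if self._gram is None:
            self._gram = (self._F @ self._F.T).astype(np.float64)
        return self._gram

    def roi_numerators(self, roi) -> np.ndarray:
        """Pairwise PMDF mass inside the ROI (unnormalized)."""
        self._ensure_fluences()
        weights = roi.weights if isinstance(roi, ROIMap) else np.asarray(roi)
        w = weights.ravel()[self._mask_idx]
        sel = np.flatnonzero(w > 0)
        if sel.size == 0:
            return np.zeros((self.positions.shape[0],) * 2)
        A = self._F[:, sel] * np.sqrt(w[sel], dtype=np.float32)[None, :]
        return (A @ A.T).astype(np.float64)

    def sensitivity_matrix(self, roi) -> np.ndarray:
        """Percent sensitivity of every position pair to ``roi``."""
        num = self.roi_numerators(roi)
        den = self.gram
        out = np.zeros_like(num)
        ok = den > 0
        out[ok] = 100.0 * num[ok] / den[ok]
        return out

    def channel_pmdf(self, i: int, j: int) -> SensitivityProfile:
        self._ensure_fluences()
        fi = simulate_fluence(self.phantom, self.optics, self.positions[i],
                              n_photons=self.n_photons, seed=self.seed + 7919 * i)
        fj = simulate_fluence(self.phantom, self.optics, self.positions[j],
                              n_photons=self.n_photons, seed=self.seed + 7919 * j)
        labels = self.phantom.labels
        pmdf = compute_pmdf(fi.fluence(self.optics, labels),
                            fj.fluence(self.optics, labels))
        d = float(np.linalg.norm(self.positions[i] - self.positions[j]))
        return SensitivityProfile(source_index=i, detector_index=j,
                                  distance_mm=d, pmdf=pmdf)
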