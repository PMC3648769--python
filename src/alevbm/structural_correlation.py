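"""Voxelwise gray-matter-covariate statistics with cluster-extent thresholding.

The statistics stage starts at spatially aligned gray-matter volumes:
smooth, regress intensity on a covariate per voxel (simple linear model,
intercept + score), threshold at an uncorrected one-sided voxel p combined
with a strict cluster-extent rule (size > k_min), extract clusters and their
peaks, and report overlap with a sphere ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import measure

from .coords import Point3, VolumeGrid
from .errors import ValidationError

log = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class GMImageSet:
    """Aligned per-subject gray-matter density volumes on one grid."""

    grid: VolumeGrid
    images: np.ndarray = field(repr=False)  # (n_subjects, *grid.shape)
    subject_ids: tuple = ()

    def __post_init__(self):
        imgs = np.asarray(self.images, dtype=float)
        if imgs.ndim != 4 or imgs.shape[1:] != self.grid.shape:
            raise ValidationError(
                f"images must be (n, {self.grid.shape}), got {imgs.shape}"
            )
        if imgs.shape[0] < 3:
            raise ValidationError("need at least 3 subjects")
        ids = tuple(self.subject_ids) or tuple(
            f"sub{i + 1:03d}" for i in range(imgs.shape[0])
        )
        if len(ids) != imgs.shape[0]:
            raise ValidationError("subject_ids length mismatch")
        object.__setattr__(self, "images", imgs)
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n_subjects(self) -> int:
        return self.images.shape[0]


@dataclass(frozen=True)
class StatMap:
    """Per-voxel T statistics with one-sided upper-tail p-values."""

    grid: VolumeGrid
    t_values: np.ndarray = field(repr=False)
    df: int = 1
    p_values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        t = np.asarray(self.t_values, dtype=float)
        if t.shape != self.grid.shape:
            raise ValidationError("t_values do not match the grid shape")
        if self.df < 1:
            raise ValidationError("df must be >= 1")
        p = self.p_values
        if p is None:
            p = stats.t.sf(t, self.df)
            p = np.clip(p, np.finfo(float).tiny, 1.0)
        p = np.asarray(p, dtype=float)
        if p.shape != t.shape:
            raise ValidationError("p_values do not match the grid shape")
        object.__setattr__(self, "t_values", t)
        object.__setattr__(self, "p_values", p)


@dataclass(frozen=True)
class Cluster:
    label: int
    size_voxels: int
    size_mm3: float
    peak_world_mm: Point3
    peak_t: float
    peaks: tuple = ()  # ((Point3, t), ...) ordered, primary first
    voxel_indices: np.ndarray = field(default=None, repr=False)  # (size, 3)


@dataclass(frozen=True)
class ClusterConfig:
    p_voxel: float = 0.001
    k_min: int = 150  # strict: a cluster survives iff size > k_min
    connectivity: int = 18

    def __post_init__(self):
        if not (0 < self.p_voxel < 1):
            raise ValidationError(f"p_voxel must be in (0, 1), got {self.p_voxel}")
        if self.k_min < 0:
            raise ValidationError("k_min must be >= 0")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValidationError("connectivity must be one of 6, 18, 26")


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Separable isotropic Gaussian smoothing in mm units.

    Sigma is derived per axis from the voxel spacing, so anisotropic voxels
    are handled. The kernel is renormalized at the boundary (a constant
    volume stays constant everywhere). fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValidationError("fwhm must be >= 0")
    vol = np.asarray(volume, dtype=float)
    if vol.shape != grid.shape:
        raise ValidationError("volume does not match the grid shape")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / grid.voxel_sizes
    smoothed = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant")
    norm = ndimage.gaussian_filter(np.ones_like(vol), sigma=sigma_vox, mode="constant")
    return smoothed / norm


def voxelwise_slope_t(images: GMImageSet, covariate, mask=None) -> StatMap:
    """Per-voxel simple linear regression of intensity on the covariate.

    T = slope / SE(slope) with df = n - 2, identical to the Pearson identity
    T = r * sqrt((n - 2) / (1 - r^2)). p-values are one-sided upper tail
    (positive association). Voxels with constant intensity get T = 0, p = 1.
    """
    x = np.asarray(covariate, dtype=float)
    n = images.n_subjects
    if x.shape != (n,):
        raise ValidationError(f"covariate must have length {n}, got {x.shape}")
    if np.var(x) == 0:
        raise ValidationError("covariate is constant")
    y = images.images.reshape(n, -1)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = y - y.mean(axis=0)
    sxy = xc @ yc
    slope = sxy / sxx
    rss = np.einsum("ij,ij->j", yc, yc) - slope * sxy
    rss = np.maximum(rss, 0.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = slope / se
    const = np.einsum("ij,ij->j", yc, yc) == 0
    if const.any():
        log.warning("%d voxel(s) with constant intensity: T set to 0", const.sum())
    t[const] = 0.0
    t = np.where(np.isfinite(t), t, np.sign(slope) * 1e30)
    t[const] = 0.0
    p = stats.t.sf(t, df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[const] = 1.0
    t3 = t.reshape(images.grid.shape)
    p3 = p.reshape(images.grid.shape)
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        t3 = np.where(m, t3, 0.0)
        p3 = np.where(m, p3, 1.0)
    return StatMap(grid=images.grid, t_values=t3, df=df, p_values=p3)


def cluster_peaks(stat: StatMap, voxel_indices: np.ndarray,
                  min_separation_mm: float = 8.0):
    """Ordered peak list of a cluster: 26-neighborhood local maxima of T
    within the cluster, greedily kept by descending T (lexicographic voxel
    tie-break) subject to a minimum mutual separation in mm."""
    idx = np.asarray(voxel_indices, dtype=int)
    if len(idx) == 0:
        raise ValidationError("empty cluster")
    member = set(map(tuple, idx))
    tvals = stat.t_values
    candidates = []
    for ijk in sorted(member):
        t0 = tvals[ijk]
        is_max = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    nb = (ijk[0] + di, ijk[1] + dj, ijk[2] + dk)
                    if nb in member and tvals[nb] > t0:
                        is_max = False
                        break
                if not is_max:
                    break
            if not is_max:
                break
        if is_max:
            candidates.append(ijk)
    # descending T, lexicographic voxel index as the deterministic tie-break
    candidates.sort(key=lambda ijk: (-tvals[ijk], ijk))
    selected = []
    for ijk in candidates:
        world = stat.grid.voxel_to_world(np.array(ijk))[0]
        if all(
            np.linalg.norm(world - s[0].as_array()) >= min_separation_mm
            for s in selected
        ):
            selected.append((Point3(*world, space="world"), float(tvals[ijk])))
    return selected


def suprathreshold_clusters(stat: StatMap, cfg: ClusterConfig,
                            min_peak_separation_mm: float = 8.0):
    """Binarize at p < p_voxel, label connected components, keep those with
    size > k_min, sorted by peak T descending."""
    supra = stat.p_values < cfg.p_voxel
    labels = measure.label(supra, connectivity=_CONNECTIVITY_RANK[cfg.connectivity])
    clusters = []
    for lab in range(1, labels.max() + 1):
        idx = np.argwhere(labels == lab)
        size = len(idx)
        if size <= cfg.k_min:
            continue
        peaks = cluster_peaks(stat, idx, min_peak_separation_mm)
        clusters.append(
            Cluster(
                label=lab,
                size_voxels=size,
                size_mm3=size * stat.grid.voxel_volume,
                peak_world_mm=peaks[0][0],
                peak_t=peaks[0][1],
                peaks=tuple(peaks),
                voxel_indices=idx,
            )
        )
    clusters.sort(key=lambda c: -c.peak_t)
    return clusters


def sphere_roi(center: Point3, radius_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Binary volume of voxels whose centers lie within radius of center."""
    if not (radius_mm > 0):
        raise ValidationError("radius must be > 0")
    centers = grid.all_voxel_centers()
    d = np.linalg.norm(centers - center.as_array(), axis=1)
    vol = (d <= radius_mm).reshape(grid.shape)
    if not vol.any():
        log.warning("sphere ROI lies wholly outside the grid")
    return vol


@dataclass(frozen=True)
class OverlapReport:
    n_overlap: int
    overlap_mm3: float
    n_a: int
    n_b: int
    fraction_of_a: float
    fraction_of_b: float


def overlap_report(a: np.ndarray, b: np.ndarray, grid: VolumeGrid) -> OverlapReport:
    """Voxel overlap of two binary volumes on a shared grid."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != grid.shape or b.shape != grid.shape:
        raise ValidationError("volumes must match the grid shape")
    inter = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    return OverlapReport(
        n_overlap=inter,
        overlap_mm3=inter * grid.voxel_volume,
        n_a=na,
        n_b=nb,
        fraction_of_a=inter / na if na else 0.0,
        fraction_of_b=inter / nb if nb else 0.0,
    )
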