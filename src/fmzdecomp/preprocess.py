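"""From per-subject BP_ND maps to cluster-wise pooled occupancy.

The preprocessing chain: inter-subject baseline statistics, a validity
mask thresholding the inter-subject minimum BP_ND (default 0.1,
inclusive) inside an anatomical mask, elementwise occupancy
``1 - BP_post / BP_baseline`` (never clipped), grouping of valid voxels
into fixed blocks (default 4x4x4, a 64-fold data reduction), and
cluster-mean pooling of occupancy per occasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ElementMap, Geometry, check_same_geometry
from .synth import StudyDesign

DEFAULT_THRESHOLD = 0.1
DEFAULT_BLOCK = (4, 4, 4)

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / FWHM_PER_SIGMA


@dataclass
class ClusterSet:
    """Partition of the valid elements into spatial blocks."""

    geometry: Geometry
    labels: np.ndarray  # int, -1 outside the valid mask
    centroids_mm: np.ndarray  # (M, 3) mean member voxel-center coordinates
    block: tuple[int, int, int]
    block_index: np.ndarray  # (M, 3) integer block coordinates
    sizes: np.ndarray  # (M,) member counts

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def member_mask(self, cluster: int) -> np.ndarray:
        return self.labels == cluster


@dataclass
class OccupancyDataset:
    """Cluster x occasion pooled occupancy plus the study design."""

    occupancy: np.ndarray  # (M_Cl, n_occasions)
    clusters: ClusterSet
    design: StudyDesign

    def __post_init__(self) -> None:
        m, n = self.occupancy.shape
        if m != self.clusters.n_clusters:
            raise ValueError(f"{m} occupancy rows but {self.clusters.n_clusters} clusters")
        if n != self.design.n_occasions:
            raise ValueError(f"{n} occupancy columns but {self.design.n_occasions} occasions")
        if not np.all(np.isfinite(self.occupancy)):
            raise ValueError("occupancy matrix contains non-finite values")

    @property
    def n_clusters(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.occupancy.size)

    def drop_subjects(self, subjects: set[str]) -> "OccupancyDataset":
        keep = np.flatnonzero(~self.design.table["subject"].isin(subjects).to_numpy())
        return OccupancyDataset(self.occupancy[:, keep], self.clusters, self.design.subset(keep))


def intersubject_stats(baselines: list[ElementMap]) -> tuple[ElementMap, ElementMap]:
    """Elementwise minimum and mean across subjects' baseline maps."""
    if len(baselines) < 2:
        raise ValueError("need at least 2 baseline maps")
    check_same_geometry(baselines)
    stack = np.stack([m.data for m in baselines])
    return baselines[0].with_data(stack.min(0)), baselines[0].with_data(stack.mean(0))


def build_valid_mask(
    min_map: ElementMap,
    threshold: float = DEFAULT_THRESHOLD,
    anatomical_mask: np.ndarray | None = None,
) -> ElementMap:
    """Valid elements: inter-subject minimum >= threshold, inside the
    anatomical mask.  The comparison is inclusive."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if anatomical_mask is None:
        anatomical_mask = min_map.mask
    valid = (min_map.data >= threshold) & np.asarray(anatomical_mask, dtype=bool) & min_map.mask
    if not valid.any():
        raise ValueError("valid mask is empty: nothing to analyze")
    return ElementMap(min_map.geometry, valid.astype(float), valid)


def compute_occupancy(baseline: ElementMap, post_drug: ElementMap) -> ElementMap:
    """Occupancy = 1 - BP_post / BP_baseline, elementwise, unclipped."""
    if not baseline.same_grid(post_drug):
        raise ValueError("baseline and post-drug maps are not on the same geometry/mask")
    mask = baseline.mask
    bl = baseline.data[mask]
    bad = int((bl <= 0).sum())
    if bad:
        raise ValueError(f"baseline BP_ND <= 0 at {bad} valid element(s)")
    occ = np.zeros_like(baseline.data)
    occ[mask] = 1.0 - post_drug.data[mask] / bl
    return ElementMap(baseline.geometry, occ, mask.copy())


def define_clusters(
    geometry: Geometry,
    block: tuple[int, int, int] = DEFAULT_BLOCK,
    mask: np.ndarray | None = None,
) -> ClusterSet:
    """Group valid voxels into fixed blocks (default 4x4x4).

    Voxels sharing the same integer-division block coordinate form one
    cluster; blocks with no valid voxel are dropped.  Centroids are the
    mean member voxel-center coordinates in mm.
    """
    block = tuple(int(b) for b in block)
    if any(b < 1 for b in block):
        raise ValueError("block dims must be >= 1")
    if mask is None:
        mask = geometry.mask
    mask = np.asarray(mask, dtype=bool)

    idx = np.indices(geometry.shape)
    block_coord = np.stack([idx[d] // block[d] for d in range(3)], axis=-1)
    valid_blocks = block_coord[mask]
    uniq, inverse = np.unique(valid_blocks, axis=0, return_inverse=True)

    labels = np.full(geometry.shape, -1, dtype=np.int32)
    labels[mask] = inverse.astype(np.int32)

    centers = geometry.voxel_centers_mm()[mask]
    m = len(uniq)
    sums = np.zeros((m, 3))
    np.add.at(sums, inverse, centers)
    sizes = np.bincount(inverse, minlength=m)
    centroids = sums / sizes[:, None]
    return ClusterSet(geometry, labels, centroids, block, uniq.astype(int), sizes)


def pool_occupancy(
    occ_maps: list[ElementMap], clusters: ClusterSet, design: StudyDesign
) -> OccupancyDataset:
    """Cluster-mean occupancy per occasion."""
    if len(occ_maps) != design.n_occasions:
        raise ValueError(
            f"{len(occ_maps)} occupancy maps but {design.n_occasions} design occasions"
        )
    mask = clusters.labels >= 0
    labels = clusters.labels[mask]
    m = clusters.n_clusters
    mat = np.empty((m, len(occ_maps)))
    for j, occ in enumerate(occ_maps):
        sums = np.bincount(labels, weights=occ.data[mask], minlength=m)
        mat[:, j] = sums / clusters.sizes
    return OccupancyDataset(mat, clusters, design)


def smooth_map(emap: ElementMap, fwhm_mm: float) -> ElementMap:
    """Mask-normalized 3D Gaussian smoothing.

    Elements outside the valid mask contribute nothing; the kernel is
    renormalized by the smoothed mask so constant fields pass through
    unchanged, including at mask edges.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return emap.with_data(emap.data.copy())
    sigma_vox = fwhm_to_sigma(fwhm_mm) / emap.geometry.voxel_size_mm
    mask = emap.mask.astype(float)
    num = ndimage.gaussian_filter(emap.data * mask, sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(mask, sigma_vox, mode="constant")
    out = np.zeros_like(emap.data)
    np.divide(num, den, out=out, where=den > 1e-12)
    out[~emap.mask] = 0.0
    return emap.with_data(out)
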