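"""Component maps: cluster results back to elements and regions.

Cluster-level fractional contributions are projected to elements either
by nearest assignment (every element inherits its cluster's fractions
exactly — used for regional aggregation) or by trilinear interpolation
on the regular block lattice of cluster centers (used for visualization
and absolute maps).  Absolute contribution maps are the fractional maps
multiplied by the inter-subject mean baseline BP_ND, so in nearest mode
the component maps sum exactly back to the mean baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ElementMap, Geometry
from .occmodel import FitResult
from .preprocess import ClusterSet


@dataclass
class ComponentMaps:
    """Per-component elementwise maps (fractional or absolute)."""

    geometry: Geometry
    data: np.ndarray  # (N, nx, ny, nz)
    mask: np.ndarray
    mode: str  # "nearest" | "linear"
    kind: str = "fractional"  # or "absolute"

    @property
    def n_components(self) -> int:
        return self.data.shape[0]

    def fraction_map(self, component: int) -> ElementMap:
        """ElementMap of 1-based component index."""
        return ElementMap(self.geometry, self.data[component - 1], self.mask.copy())


def _block_value_grid(clusters: ClusterSet, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Arrange per-cluster values on the regular block lattice.

    Returns the (nbx, nby, nbz, N) value grid with missing blocks filled
    from their nearest occupied block, the occupancy mask, and the
    per-axis block-center coordinates in mm.
    """
    bi = clusters.block_index
    dims = bi.max(0) + 1
    n_val = values.shape[1]
    grid = np.zeros((*dims, n_val))
    have = np.zeros(dims, dtype=bool)
    grid[tuple(bi.T)] = values
    have[tuple(bi.T)] = True
    if not have.all():
        _, idx = ndimage.distance_transform_edt(~have, return_indices=True)
        grid = grid[tuple(idx)]
    centers = [
        (np.arange(dims[d]) + 0.5) * clusters.block[d] * clusters.geometry.voxel_size_mm
        for d in range(3)
    ]
    return grid, have, centers


def _trilinear_sample(grid: np.ndarray, centers: list[np.ndarray], points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a block-lattice value grid at physical
    points, clamping coordinates to the lattice hull (nearest-edge
    fallback outside it)."""
    dims = grid.shape[:3]
    idx0 = []
    w = []
    for d in range(3):
        c = centers[d]
        if dims[d] == 1:
            idx0.append(np.zeros(len(points), dtype=int))
            w.append(np.zeros(len(points)))
            continue
        spacing = c[1] - c[0]
        u = np.clip((points[:, d] - c[0]) / spacing, 0.0, dims[d] - 1.0)
        i0 = np.minimum(u.astype(int), dims[d] - 2)
        idx0.append(i0)
        w.append(u - i0)
    out = np.zeros((len(points), grid.shape[3]))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ix = np.minimum(idx0[0] + dx, dims[0] - 1)
                iy = np.minimum(idx0[1] + dy, dims[1] - 1)
                iz = np.minimum(idx0[2] + dz, dims[2] - 1)
                weight = (
                    (w[0] if dx else 1 - w[0])
                    * (w[1] if dy else 1 - w[1])
                    * (w[2] if dz else 1 - w[2])
                )
                out += weight[:, None] * grid[ix, iy, iz]
    return out


def interpolate_to_elements(
    fit: FitResult, clusters: ClusterSet, mode: str = "nearest"
) -> ComponentMaps:
    """Project cluster fractions to elements.

    ``nearest``: each element takes its own cluster's fractions (the
    simplex is inherited exactly).  ``linear``: trilinear interpolation
    of cluster values on the block lattice at element centers, with
    nearest-block fallback outside the lattice hull; interpolated
    fractions are renormalized per element to sum to one.
    """
    if mode not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation mode '{mode}' (use 'nearest' or 'linear')")
    geo = clusters.geometry
    n = fit.config.n_components
    valid = clusters.labels >= 0
    data = np.zeros((n, *geo.shape))
    if mode == "nearest":
        data[:, valid] = fit.fractions[clusters.labels[valid]].T
    else:
        grid, _, centers = _block_value_grid(clusters, fit.fractions)
        pts = geo.voxel_centers_mm()[valid]
        vals = _trilinear_sample(grid, centers, pts)
        vals = np.clip(vals, 0.0, None)
        vals /= np.maximum(vals.sum(1, keepdims=True), 1e-300)
        data[:, valid] = vals.T
    return ComponentMaps(geo, data, valid, mode, kind="fractional")


def absolute_contribution(cmaps: ComponentMaps, mean_baseline: ElementMap) -> ComponentMaps:
    """Absolute component contributions in BP_ND units:
    fraction x inter-subject mean baseline, per element."""
    if tuple(cmaps.geometry.shape) != tuple(mean_baseline.geometry.shape):
        raise ValueError("component maps and baseline are on different geometries")
    if cmaps.kind != "fractional":
        raise ValueError("absolute_contribution expects fractional maps")
    data = cmaps.data * mean_baseline.data[None]
    mask = cmaps.mask & mean_baseline.mask
    return ComponentMaps(cmaps.geometry, data, mask, cmaps.mode, kind="absolute")


def region_aggregate(
    maps_or_map: ComponentMaps | ElementMap,
    geometry: Geometry | None = None,
    pool_hemispheres: bool = True,
) -> pd.DataFrame:
    """Regional mean values of a map or of per-component maps.

    One row per region (or per region-hemisphere pair when
    ``pool_hemispheres`` is false) with member element counts; a region
    with no valid element yields NaN means and a zero count.
    """
    if isinstance(maps_or_map, ElementMap):
        geo = geometry or maps_or_map.geometry
        stack = maps_or_map.data[None]
        mask = maps_or_map.mask
        cols = ["mean"]
    else:
        geo = geometry or maps_or_map.geometry
        stack = maps_or_map.data
        mask = maps_or_map.mask
        cols = [f"C{k + 1}" for k in range(stack.shape[0])]

    all_ids = np.unique(geo.regions[geo.regions > 0])
    hemis = [(0, "both")] if pool_hemispheres else [(-1, "left"), (1, "right")]
    rows = []
    for rid in all_ids:
        base = geo.regions == rid
        for code, hname in hemis:
            sel = base & mask
            if code:
                sel &= geo.hemispheres == code
            row: dict = {"region": int(rid), "hemisphere": hname, "n_elements": int(sel.sum())}
            for c, comp in enumerate(cols):
                row[comp] = float(stack[c][sel].mean()) if sel.any() else float("nan")
            rows.append(row)
    df = pd.DataFrame(rows)
    return df
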