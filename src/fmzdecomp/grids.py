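"""Labeled volumetric grids and per-element value maps.

All stages of the pipeline operate on a common spatial scaffold: a
volumetric grid with hemisphere and atlas-region labels, a validity
mask, and per-element scalar values (binding potential or occupancy).
The grid is mirror-symmetric across the x axis so that left/right
asymmetry checks are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LEFT = -1
RIGHT = 1
MIDLINE = 0


@dataclass
class Geometry:
    """A labeled, mirror-symmetric volumetric grid.

    Attributes
    ----------
    shape
        Grid dimensions ``(nx, ny, nz)`` in voxels.  The x axis is the
        mirror axis and must have even length.
    voxel_size_mm
        Isotropic voxel edge length in millimetres.
    regions
        Integer atlas code per voxel (0 = unlabeled).  Region codes are
        shared between hemispheres: code ``r`` appears once per side
        with mirrored voxel sets.
    hemispheres
        Per-voxel hemisphere label: -1 left, +1 right, 0 midline.
    mask
        Boolean validity mask (anatomical extent of the grid).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float
    regions: np.ndarray
    hemispheres: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("regions", "hemispheres", "mask"):
            arr = getattr(self, name)
            if tuple(arr.shape) != tuple(self.shape):
                raise ValueError(f"{name} array shape {arr.shape} != grid shape {self.shape}")
        if self.shape[0] % 2:
            raise ValueError(
                f"mirror axis (x) has odd dimension {self.shape[0]}; an even length is required"
            )

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.regions[self.mask])
        return ids[ids > 0]

    def mirrored(self, arr: np.ndarray) -> np.ndarray:
        """Reflect an array across the mirror (x) axis."""
        return arr[::-1, ...]

    def voxel_centers_mm(self) -> np.ndarray:
        """Physical coordinates of all voxel centers, shape (*grid, 3)."""
        axes = [
            (np.arange(n) + 0.5) * self.voxel_size_mm for n in self.shape
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)


@dataclass
class ElementMap:
    """Per-element scalar values (BP_ND or occupancy) on a geometry.

    Values outside ``mask`` are carried but considered undefined.
    """

    geometry: Geometry
    data: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ValueError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )
        if self.mask is None:
            self.mask = self.geometry.mask.copy()
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values on valid elements")

    @property
    def valid_values(self) -> np.ndarray:
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "ElementMap":
        return ElementMap(self.geometry, data, self.mask.copy())

    def same_grid(self, other: "ElementMap") -> bool:
        return tuple(self.geometry.shape) == tuple(other.geometry.shape) and np.array_equal(
            self.mask, other.mask
        )


def check_same_geometry(maps: list[ElementMap]) -> None:
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError("element maps are not on the same geometry/mask")


__all__ = ["Geometry", "ElementMap", "check_same_geometry", "LEFT", "RIGHT", "MIDLINE", "replace"]
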