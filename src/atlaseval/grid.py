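"""Voxel grids with a fixed anatomical axis convention.

All volumes in this package live on a regular 3-D grid with physical voxel
spacing.  Arrays are indexed ``[ix, iy, iz]`` and the axes carry a fixed
anatomical meaning chosen so that signed coordinates are directly
interpretable in reports:

* +x — lateral (away from the midline on the treated side); −x medial
* +y — anterior; −y posterior
* +z — inferior; −z superior

Physical coordinates are expressed in **cm** (the reporting unit of the
displacement metrics); voxel spacing is stored in **mm** (the imaging
convention).  Coordinates refer to voxel *centers*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: axis order of every array in the package
AXES = ("x", "y", "z")


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice with physical spacing and origin.

    Parameters
    ----------
    shape
        Voxel counts per axis (x, y, z); each component ≥ 1.
    spacing_mm
        Voxel spacing per axis in mm; strictly positive.
    origin_cm
        Physical coordinate (cm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_cm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing_mm) != 3 or len(self.origin_cm) != 3:
            raise ValueError("grid fields must be 3-vectors")
        if any(int(n) < 1 or int(n) != n for n in self.shape):
            raise ValueError(f"shape components must be integers >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_cm", tuple(float(o) for o in self.origin_cm))

    @classmethod
    def centered(cls, shape=(96, 96, 96), spacing_mm=(2.5, 2.5, 2.5)) -> "VoxelGrid":
        """Grid whose physical center is the coordinate origin."""
        shape = tuple(int(n) for n in shape)
        spacing_mm = tuple(float(s) for s in spacing_mm)
        origin = tuple(-(n - 1) * s / 10.0 / 2.0 for n, s in zip(shape, spacing_mm))
        return cls(shape, spacing_mm, origin)

    @property
    def spacing_cm(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float) / 10.0

    @property
    def fov_cm(self) -> np.ndarray:
        """Physical extent (cm) of the grid per axis."""
        return np.asarray(self.shape, dtype=float) * self.spacing_cm

    def coordinates_cm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D arrays of voxel-center coordinates (cm) per axis."""
        return tuple(
            self.origin_cm[a] + np.arange(self.shape[a]) * self.spacing_cm[a]
            for a in range(3)
        )

    def meshgrid_cm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense voxel-center coordinate volumes (cm), shape = grid shape."""
        cx, cy, cz = self.coordinates_cm()
        return np.meshgrid(cx, cy, cz, indexing="ij")

    def world_to_voxel(self, points_cm: np.ndarray) -> np.ndarray:
        """Map physical points (cm, shape (..., 3)) to fractional voxel indices."""
        p = np.asarray(points_cm, dtype=float)
        return (p - np.asarray(self.origin_cm)) / self.spacing_cm

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to physical coordinates in cm."""
        i = np.asarray(indices, dtype=float)
        return np.asarray(self.origin_cm) + i * self.spacing_cm

    def compatible_with(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_cm, other.origin_cm, atol=tol)
        )

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible_with(other):
            raise ValueError(f"grid mismatch: {self} vs {other}")
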