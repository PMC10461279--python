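"""Contour-comparison metrics: overlap and directional displacement.

Two families of metrics quantify how an auto-segmentation (AS) differs from
its reference contour:

* **Volume overlap** — the Jaccard similarity coefficient
  ``JSC = |A ∩ B| / |A ∪ B|`` (with its Dice counterpart,
  ``J = D / (2 − D)``).  Overlap scores summarise agreement but say nothing
  about *where* a contour deviates.

* **Centroid distance variants (CDV)** — directional displacement metrics.
  For each structure, the six *directional extents* are the physical
  coordinates (cm) of its most medial, lateral, posterior, anterior,
  superior and inferior occupied voxel centers.  A *centroid distance* is
  the signed offset of each extent from a centre point (the structure's own
  centroid, or a common reference point).  The *variant* for a direction is
  ``reference distance − test distance``: zero when the contours agree,
  non-zero when the AS boundary sits elsewhere along that axis.  Because the
  sign of a variant means different things on min- and max-directions, a
  direction-aware classifier maps variants to under-/over-contouring labels.

Axis ↔ anatomy mapping (grid convention): ``min_x``=medial, ``max_x``=lateral,
``min_y``=posterior, ``max_y``=anterior, ``min_z``=superior, ``max_z``=inferior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid

#: the six directions, in reporting order
DIRECTIONS = ("min_x", "max_x", "min_y", "max_y", "min_z", "max_z")

#: anatomical aliases for the six directions
ANATOMICAL_DIRECTION = {
    "min_x": "medial",
    "max_x": "lateral",
    "min_y": "posterior",
    "max_y": "anterior",
    "min_z": "superior",
    "max_z": "inferior",
}
DIRECTION_FROM_ANATOMICAL = {v: k for k, v in ANATOMICAL_DIRECTION.items()}


@dataclass(frozen=True)
class OverlapScore:
    """Joint Jaccard/Dice overlap of two masks; ``jaccard = dice/(2 − dice)``."""

    jaccard: float
    dice: float


def jaccard(a: np.ndarray, b: np.ndarray) -> OverlapScore:
    """Voxel-count Jaccard and Dice overlap of two binary masks.

    Symmetric in its arguments.  Two empty masks are defined as identical
    (score 1); an empty mask against a non-empty one scores 0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    na, nb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
    union = na + nb - inter
    if union == 0:
        return OverlapScore(1.0, 1.0)
    return OverlapScore(inter / union, 2.0 * inter / (na + nb))


def dice_to_jaccard(d: float) -> float:
    """Convert a Dice fraction to the equivalent Jaccard fraction, D/(2−D)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"Dice fraction must lie in [0, 1], got {d}")
    return d / (2.0 - d)


def jaccard_to_dice(j: float) -> float:
    """Inverse conversion, 2J/(1+J)."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard fraction must lie in [0, 1], got {j}")
    return 2.0 * j / (1.0 + j)


def centroid(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Unweighted mean of occupied voxel-center coordinates, in cm."""
    idx = np.nonzero(np.asarray(mask, dtype=bool))
    if idx[0].size == 0:
        raise ValueError("centroid undefined for an empty mask")
    return grid.voxel_to_world(np.array([i.mean() for i in idx]))


@dataclass(frozen=True)
class DirectionalExtents:
    """Signed physical coordinates (cm) of the extreme occupied voxel centers."""

    min_x: float
    max_x: float
    min_y: float
    max_y: float
    min_z: float
    max_z: float

    def as_dict(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in DIRECTIONS}


def directional_extents(mask: np.ndarray, grid: VoxelGrid) -> DirectionalExtents:
    """Per-axis min/max physical coordinate over occupied voxels."""
    idx = np.nonzero(np.asarray(mask, dtype=bool))
    if idx[0].size == 0:
        raise ValueError("extents undefined for an empty mask")
    vals = {}
    for a, axis in enumerate("xyz"):
        coords = grid.origin_cm[a] + idx[a] * grid.spacing_cm[a]
        vals[f"min_{axis}"] = float(coords.min())
        vals[f"max_{axis}"] = float(coords.max())
    return DirectionalExtents(**vals)


@dataclass(frozen=True)
class CentroidDistances:
    """Signed distances (cm) from each directional extent to a centre point.

    ``centre_mode`` records whether the centre was the structure's own
    centroid (``"own"``) or a shared reference point (``"reference"``).
    """

    min_x: float
    max_x: float
    min_y: float
    max_y: float
    min_z: float
    max_z: float
    centre_mode: str = "own"

    def as_dict(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in DIRECTIONS}


def centroid_distances(
    ext: DirectionalExtents, centre, centre_mode: str = "own"
) -> CentroidDistances:
    """Each extent coordinate minus the centre coordinate on its axis."""
    c = np.asarray(centre, dtype=float)
    vals = {
        d: float(getattr(ext, d) - c["xyz".index(d[-1])]) for d in DIRECTIONS
    }
    return CentroidDistances(**vals, centre_mode=centre_mode)


@dataclass(frozen=True)
class CDVRecord:
    """Centroid distance variants (reference − test) for one structure.

    Negative/positive signs are interpreted per direction by
    :func:`classify_variant`; ``rounded()`` gives values at the reporting
    precision (1 decimal by default) while the raw values are retained.
    """

    structure: str
    variants: dict[str, float]
    decimals: int = 1

    def rounded(self) -> dict[str, float]:
        return {d: round(v + 0.0, self.decimals) for d, v in self.variants.items()}


def cdv(
    ref: CentroidDistances, test: CentroidDistances, structure: str = "", decimals: int = 1
) -> CDVRecord:
    """Per-direction variant: reference centroid distance minus test's."""
    if ref.centre_mode != test.centre_mode:
        raise ValueError(
            f"centre_mode mismatch: {ref.centre_mode!r} vs {test.centre_mode!r}"
        )
    variants = {d: float(getattr(ref, d) - getattr(test, d)) for d in DIRECTIONS}
    return CDVRecord(structure=structure, variants=variants, decimals=decimals)


def structure_cdv(
    ref_mask: np.ndarray,
    test_mask: np.ndarray,
    grid: VoxelGrid,
    centre_mode: str = "own",
    structure: str = "",
    decimals: int = 1,
) -> CDVRecord:
    """Convenience pipeline: extents → centroid distances → variants.

    With ``centre_mode="own"`` each structure's distances are taken from its
    own centroid (a pure translation of the test mask then cancels out);
    with ``centre_mode="reference"`` both use the reference centroid, so the
    variants recover displacement.
    """
    ref_ext = directional_extents(ref_mask, grid)
    test_ext = directional_extents(test_mask, grid)
    ref_c = centroid(ref_mask, grid)
    test_c = centroid(test_mask, grid) if centre_mode == "own" else ref_c
    return cdv(
        centroid_distances(ref_ext, ref_c, centre_mode),
        centroid_distances(test_ext, test_c, centre_mode),
        structure=structure,
        decimals=decimals,
    )


def classify_variant(record: CDVRecord, dead_band_cm: float = 0.05) -> dict[str, str]:
    """Map signed variants to under-/over-contouring labels per direction.

    For min-directions a negative variant (test boundary further out, i.e.
    less negative extent ... reference minus test < 0 means the test extent
    is *greater*, lying inside) marks under-contouring and positive marks
    over-contouring; on max-directions the interpretation flips.  Variants
    with magnitude below ``dead_band_cm`` are labelled ``"none"``.
    """
    labels = {}
    for d, v in record.variants.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite variant for direction {d}")
        if abs(v) < dead_band_cm:
            labels[d] = "none"
        elif d.startswith("min"):
            labels[d] = "under" if v < 0 else "over"
        else:
            labels[d] = "under" if v > 0 else "over"
    return labels
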