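"""Structure sets: named binary masks on a shared grid, plus case records.

The controlled vocabulary covers the structures delineated for breast and
regional-nodal radiotherapy planning: the breast clinical target volume,
axillary/supraclavicular nodal levels 1–4 (and the combined CTVs 3&4 and
1–4), interpectoral and internal mammary nodes, the brachial plexus, humeral
head, heart and lung.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

#: controlled vocabulary of structure names
STRUCTURE_NAMES = (
    "Breast",
    "Level1",
    "Level2",
    "Level3",
    "Level4",
    "Level3_4",
    "Level1_4",
    "Interpectoral",
    "IMN",
    "BrachialPlexus",
    "HumeralHead",
    "Heart",
    "Lung",
)

#: combined nodal CTVs and their member levels
COMBINED_NODES = {
    "Level3_4": ("Level3", "Level4"),
    "Level1_4": ("Level1", "Level2", "Level3", "Level4"),
}

#: the "larger structures" class used in size-stratified summaries
LARGE_STRUCTURES = frozenset({"Breast", "Heart", "Lung", "Level1"})

#: organs routinely contoured by treatment planning systems; their
#: displacement metrics are excluded from analysis unconditionally
ROUTINE_TPS_STRUCTURES = frozenset({"Heart", "Lung"})


class UnknownStructureError(ValueError):
    pass


@dataclass
class StructureSet:
    """Binary masks for named structures, all conforming to one grid."""

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, mask in self.masks.items():
            if name not in STRUCTURE_NAMES:
                raise UnknownStructureError(f"unknown structure name: {name!r}")
            mask = np.asarray(mask)
            if mask.shape != self.grid.shape:
                raise ValueError(
                    f"mask {name!r} shape {mask.shape} does not conform to grid {self.grid.shape}"
                )
            clean[name] = mask.astype(bool)
        self.masks = clean

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def combine_nodes(self) -> "StructureSet":
        """Add the combined nodal CTVs as voxelwise unions of their members.

        ``Level3_4 = Level3 ∪ Level4`` and ``Level1_4 = Level1 ∪ … ∪ Level4``.
        Existing combined masks are overwritten with the recomputed unions.
        """
        for combo, members in COMBINED_NODES.items():
            present = [m for m in members if m in self.masks]
            if len(present) == len(members):
                union = np.zeros(self.grid.shape, dtype=bool)
                for m in members:
                    union |= self.masks[m]
                self.masks[combo] = union
        return self

    def volumes_cm3(self) -> dict[str, float]:
        vox = float(np.prod(self.grid.spacing_cm))
        return {name: float(mask.sum()) * vox for name, mask in self.masks.items()}

    def copy(self) -> "StructureSet":
        return StructureSet(self.grid, {n: m.copy() for n, m in self.masks.items()})


#: intensity (HU-proxy) threshold separating body from surrounding air
BODY_THRESHOLD = -250.0


@dataclass
class CaseRecord:
    """One cohort member: CT-proxy intensity volume, structures and metadata.

    ``incline_deg`` is the breast-board incline at scan time (15° or 20°);
    ``separation_cm`` the chest-wall separation (distance between medial and
    lateral skin markers), with ``separation_class`` its small/large
    stratification; ``role`` marks the atlas/test partition.
    """

    case_id: str
    intensity: np.ndarray
    structures: StructureSet
    incline_deg: int
    separation_cm: float
    separation_class: str
    role: str = "atlas"
    body: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.incline_deg not in (15, 20):
            raise ValueError(f"unsupported breast-board incline: {self.incline_deg}")
        if self.separation_class not in ("small", "large"):
            raise ValueError(f"separation_class must be small|large, got {self.separation_class!r}")
        if self.role not in ("atlas", "test"):
            raise ValueError(f"role must be atlas|test, got {self.role!r}")
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.shape != self.grid.shape:
            raise ValueError("intensity volume does not conform to the structure grid")

    @property
    def grid(self) -> VoxelGrid:
        return self.structures.grid

    @property
    def body_mask(self) -> np.ndarray:
        """Voxels inside the patient.

        The generator stores its exact body envelope; for cases read from
        disk the envelope is recovered from the intensity volume (air
        threshold + hole filling, which keeps the lung interior inside).
        """
        if self.body is not None:
            return self.body
        from scipy import ndimage

        return ndimage.binary_fill_holes(self.intensity > BODY_THRESHOLD)
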