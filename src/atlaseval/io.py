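"""File layout: NIfTI volumes, JSON sidecars, YAML configs, CSV results.

A case is stored as::

    <dir>/<case_id>_intensity.nii.gz          CT-proxy volume (float32)
    <dir>/<case_id>_label_<Structure>.nii.gz  one uint8 mask per structure
    <dir>/<case_id>.json                      metadata sidecar

NIfTI affines are axis-aligned with spacing in mm and origin in mm (the
in-memory convention stores origins in cm).  A cohort directory additionally
carries ``cohort.json`` listing its members and provenance.  Result tables
are CSV with a leading comment line declaring units.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grid import VoxelGrid
from .structures import STRUCTURE_NAMES, CaseRecord, StructureSet, UnknownStructureError

#: comment line written at the top of every result CSV
CSV_UNITS_HEADER = (
    "# units: jaccard — fraction in [0,1]; var_* (centroid distance variants), "
    "mean/sd extents — cm; volume_cm3 — cm^3"
)


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = np.asarray(grid.origin_cm) * 10.0
    return aff


def _grid_from_nifti(img) -> VoxelGrid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError("only axis-aligned NIfTI volumes are supported")
    spacing = np.diag(aff[:3, :3])
    if np.any(spacing <= 0):
        raise ValueError("NIfTI affine must have positive axis-aligned spacing")
    return VoxelGrid(tuple(img.shape[:3]), tuple(spacing), tuple(aff[:3, 3] / 10.0))


def write_case(case: CaseRecord, out_dir: str | Path) -> Path:
    """Write one case in the documented NIfTI + JSON layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(case.grid)
    nib.save(
        nib.Nifti1Image(case.intensity.astype(np.float32), aff),
        out / f"{case.case_id}_intensity.nii.gz",
    )
    for name, mask in case.structures.masks.items():
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), aff),
            out / f"{case.case_id}_label_{name}.nii.gz",
        )
    meta = {
        "case_id": case.case_id,
        "incline_deg": case.incline_deg,
        "separation_cm": case.separation_cm,
        "separation_class": case.separation_class,
        "role": case.role,
        "structures": sorted(case.structures.names),
        "grid": {
            "shape": list(case.grid.shape),
            "spacing_mm": list(case.grid.spacing_mm),
            "origin_cm": list(case.grid.origin_cm),
        },
    }
    (out / f"{case.case_id}.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def read_case(case_dir: str | Path, case_id: str) -> CaseRecord:
    """Read a case back, validating grid metadata, names and binarity."""
    d = Path(case_dir)
    meta = json.loads((d / f"{case_id}.json").read_text())
    img = nib.load(d / f"{case_id}_intensity.nii.gz")
    grid = _grid_from_nifti(img)
    intensity = np.asarray(img.dataobj, dtype=np.float32)
    masks = {}
    for name in meta["structures"]:
        if name not in STRUCTURE_NAMES:
            raise UnknownStructureError(f"unknown structure name in sidecar: {name!r}")
        limg = nib.load(d / f"{case_id}_label_{name}.nii.gz")
        lgrid = _grid_from_nifti(limg)
        if not grid.compatible_with(lgrid):
            raise ValueError(
                f"grid mismatch between intensity and label {name!r} for case {case_id!r}"
            )
        data = np.asarray(limg.dataobj)
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"non-binary label data in {name!r} for case {case_id!r}")
        masks[name] = data.astype(bool)
    return CaseRecord(
        case_id=meta["case_id"],
        intensity=intensity,
        structures=StructureSet(grid, masks),
        incline_deg=int(meta["incline_deg"]),
        separation_cm=float(meta["separation_cm"]),
        separation_class=meta["separation_class"],
        role=meta["role"],
    )


def write_cohort(cases: list[CaseRecord], out_dir: str | Path, provenance: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_case(case, out)
    manifest = {"cases": [c.case_id for c in cases], "provenance": provenance or {}}
    (out / "cohort.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def read_cohort(cohort_dir: str | Path) -> list[CaseRecord]:
    d = Path(cohort_dir)
    manifest_path = d / "cohort.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    return [read_case(d, cid) for cid in manifest["cases"]]


def write_results_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """CSV with a leading units comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(CSV_UNITS_HEADER + "\n")
        df.to_csv(fh, index=index, lineterminator="\n")
    return path


def read_results_csv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def write_manifest(out_dir: str | Path, config: dict, seed: int, extra: dict | None = None) -> Path:
    """Run manifest: the full config plus seeds, for provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"config": config, "seed": seed, **(extra or {})}
    path = out / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
    return path
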