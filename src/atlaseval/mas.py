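"""Desk-scale multi-atlas auto-segmentation (MAS).

The pipeline mirrors the structure of commercial atlas-based segmenters:
each atlas image is brought into spatial correspondence with the test image
by rigid registration followed by deformable image registration (DIR), the
atlas contours are propagated through the composed transform, and the
candidate segmentations are fused into a consensus contour by per-voxel
voting.

The registration components are intentionally simple, transparent
implementations rather than a clinical-grade engine:

* **Rigid** — normalised cross-correlation over 3 translations + 3 small
  rotations, initialised from body centroids and refined with a local
  optimiser.
* **Deformable** — a multi-resolution optical-flow/demons scheme: the
  per-voxel update is the intensity mismatch times the fixed-image
  gradient, normalised by gradient magnitude squared plus squared mismatch
  (Thirion's rule), with Gaussian smoothing of the displacement field.
  Iteration stops on a relative sum-of-squared-differences (SSD) tolerance,
  an iteration cap, or a divergence guard; the returned field never has a
  larger full-resolution SSD than the zero field.

Transform convention (pull/resampling): transforms map **test-grid
coordinates into atlas space**.  A candidate label at test voxel ``x`` is
the atlas mask sampled at ``T_rigid(x + u(x))``, where ``u`` is the
deformation (mm, stored per voxel of the test grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .grid import VoxelGrid
from .structures import CaseRecord, StructureSet


class LeakageError(ValueError):
    """A test case appeared in its own atlas group."""


# ---------------------------------------------------------------------------
# transforms and resampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about the grid center) followed by translation (cm).

    ``apply_points`` maps test-space physical points into atlas space:
    ``p' = R (p − c) + c + t``.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls, grid: VoxelGrid | None = None) -> "RigidTransform":
        center = (0.0, 0.0, 0.0)
        if grid is not None:
            center = tuple(grid.voxel_to_world((np.asarray(grid.shape) - 1) / 2.0))
        return cls(center_cm=center)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply_points(self, points_cm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_cm, dtype=float)
        c = np.asarray(self.center_cm)
        t = np.asarray(self.translation_cm)
        return (p - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        rot = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).inv()
        t = np.asarray(self.translation_cm)
        # p = R^-1 (p' - c - t) + c  =  R^-1 (p' - c) + c + (R^-1 (-t))
        t_inv = rot.apply(-t)
        return RigidTransform(
            tuple(rot.as_euler("xyz", degrees=True)), tuple(t_inv), self.center_cm
        )


@dataclass(frozen=True)
class DeformationField:
    """Per-voxel displacement vectors (mm) on the fixed (test) grid."""

    grid: VoxelGrid
    displacement_mm: np.ndarray  # shape (3, *grid.shape)

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement_mm, dtype=np.float32)
        if disp.shape != (3, *self.grid.shape):
            raise ValueError(f"displacement shape {disp.shape} != (3, *{self.grid.shape})")
        if not np.isfinite(disp).all():
            raise ValueError("displacement field contains non-finite values")
        object.__setattr__(self, "displacement_mm", disp)

    @classmethod
    def zero(cls, grid: VoxelGrid) -> "DeformationField":
        return cls(grid, np.zeros((3, *grid.shape), dtype=np.float32))


def resample_at_points(
    volume: np.ndarray, grid: VoxelGrid, points_cm: list[np.ndarray], order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Trilinear (order=1) sampling of ``volume`` at physical points (cm)."""
    vox = [
        (points_cm[a] - grid.origin_cm[a]) / grid.spacing_cm[a] for a in range(3)
    ]
    return ndimage.map_coordinates(
        np.asarray(volume, dtype=np.float32), np.stack(vox), order=order,
        mode="constant", cval=cval,
    )


def _warp_volume(
    volume: np.ndarray,
    src_grid: VoxelGrid,
    dst_grid: VoxelGrid,
    rigid: RigidTransform | None = None,
    field: DeformationField | None = None,
    cval: float = 0.0,
) -> np.ndarray:
    """Sample ``volume`` (on src_grid) at dst-grid points mapped through
    ``x ↦ T_rigid(x + u(x))``."""
    X, Y, Z = dst_grid.meshgrid_cm()
    pts = [X, Y, Z]
    if field is not None:
        pts = [pts[a] + field.displacement_mm[a] / 10.0 for a in range(3)]
    if rigid is not None:
        stacked = np.stack([p.ravel() for p in pts], axis=-1)
        mapped = rigid.apply_points(stacked)
        pts = [mapped[:, a].reshape(dst_grid.shape) for a in range(3)]
    return resample_at_points(volume, src_grid, pts, cval=cval)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidParams:
    max_rotation_deg: float = 15.0       # covers the 15°↔20° incline gap
    coarse_max_dim: int = 48             # downsampled size used during refinement
    body_threshold: float = -250.0       # intensity cut for moment initialisation
    maxiter: int = 60


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def rigid_register(
    fixed: np.ndarray, moving: np.ndarray, grid: VoxelGrid,
    params: RigidParams = RigidParams(),
) -> RigidTransform:
    """Rigid alignment maximising normalised cross-correlation (NCC).

    Translation is initialised from the body-mask centroid offset, then
    translation and small rotations are refined with Powell's method on a
    downsampled copy.  Translations are bounded to ± a quarter of the field
    of view around the initial value and rotations to
    ±``params.max_rotation_deg``.  Registering a volume to itself returns a
    transform within half a voxel / 0.5° of identity.
    """
    fixed = np.asarray(fixed, dtype=np.float32)
    moving = np.asarray(moving, dtype=np.float32)
    if fixed.shape != grid.shape or moving.shape != grid.shape:
        raise ValueError("volumes must live on the given grid")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("similarity undefined for constant volumes")

    def com(vol):
        mask = vol > params.body_threshold
        if not mask.any():
            mask = vol > vol.mean()
        return grid.voxel_to_world(ndimage.center_of_mass(mask))

    t0 = com(moving) - com(fixed)
    center = tuple(grid.voxel_to_world((np.asarray(grid.shape) - 1) / 2.0))

    step = max(1, int(np.ceil(max(grid.shape) / params.coarse_max_dim)))
    sl = (slice(None, None, step),) * 3
    coarse_grid = VoxelGrid(
        tuple(len(range(0, n, step)) for n in grid.shape),
        tuple(s * step for s in grid.spacing_mm),
        grid.origin_cm,
    )
    f_c = fixed[sl]
    cval = float(moving.min())

    def objective(p):
        tr = RigidTransform(tuple(p[3:]), tuple(p[:3]), center)
        m_c = _warp_volume(moving, grid, coarse_grid, rigid=tr, cval=cval)
        return -_ncc(f_c, m_c)

    x0 = np.concatenate([t0, np.zeros(3)])
    quarter_fov = grid.fov_cm / 4.0
    bounds = [(t0[a] - quarter_fov[a], t0[a] + quarter_fov[a]) for a in range(3)]
    bounds += [(-params.max_rotation_deg, params.max_rotation_deg)] * 3
    res = optimize.minimize(
        objective, x0, method="Powell", bounds=bounds,
        options={"maxiter": params.maxiter, "xtol": 1e-3, "ftol": 1e-6},
    )
    p = res.x
    return RigidTransform(tuple(p[3:]), tuple(p[:3]), center)


# ---------------------------------------------------------------------------
# deformable registration (demons / optical flow)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemonsParams:
    levels: int = 3
    iterations_per_level: int = 50
    field_sigma_voxels: float = 1.5     # diffusion-like regularisation
    update_sigma_voxels: float = 1.0    # fluid-like smoothing of each update
    rel_tolerance: float = 1e-4         # stop when relative SSD improvement falls below
    divergence_patience: int = 3        # consecutive SSD increases before aborting
    max_step_voxels: float = 2.0        # per-iteration displacement cap


@dataclass
class DemonsReport:
    ssd_initial: float
    ssd_final: float
    iterations: int
    diverged: bool = False


def _downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return vol
    return ndimage.zoom(vol, 1.0 / factor, order=1)


def deformable_register(
    fixed: np.ndarray, moving: np.ndarray, grid: VoxelGrid,
    params: DemonsParams = DemonsParams(),
) -> tuple[DeformationField, DemonsReport]:
    """Demons-style deformable registration of ``moving`` onto ``fixed``.

    Both volumes must already be rigidly aligned on ``grid``.  Returns the
    displacement field (mm, pull convention: ``moving(x + u(x)) ≈ fixed(x)``)
    and a convergence report.  The full-resolution SSD of the returned field
    is never worse than the zero-field SSD: if optimisation diverges, the
    best (possibly zero) field is returned and the report flags divergence.
    """
    fixed = np.asarray(fixed, dtype=np.float32)
    moving = np.asarray(moving, dtype=np.float32)
    if fixed.shape != grid.shape or moving.shape != grid.shape:
        raise ValueError("volumes must live on the given grid")
    # common intensity normalisation keeps the demons denominator balanced
    lo = min(float(fixed.min()), float(moving.min()))
    hi = max(float(fixed.max()), float(moving.max()))
    scale = hi - lo if hi > lo else 1.0
    f0 = (fixed - lo) / scale
    m0 = (moving - lo) / scale

    spacing = np.asarray(grid.spacing_mm, dtype=float)
    u = None  # (3, *shape) in mm, on the current level's lattice
    total_iters = 0
    diverged = False

    for level in range(params.levels):
        factor = 2 ** (params.levels - 1 - level)
        f = _downsample(f0, factor)
        m = _downsample(m0, factor)
        sp = spacing * factor
        if u is None:
            u = np.zeros((3, *f.shape), dtype=np.float32)
        else:
            u = np.stack(
                [ndimage.zoom(u[a], np.asarray(f.shape) / np.asarray(u[a].shape), order=1)
                 for a in range(3)]
            ).astype(np.float32)

        grad = np.stack(np.gradient(f, *sp))  # fixed-image gradient, 1/mm units
        grad_sq = (grad**2).sum(axis=0)
        base = np.stack(
            np.meshgrid(*[np.arange(n, dtype=np.float32) for n in f.shape], indexing="ij")
        )

        def warped_ssd(u_field):
            coords = base + u_field / sp[:, None, None, None]
            mw = ndimage.map_coordinates(m, coords, order=1, mode="nearest")
            diff = mw - f
            return mw, diff, float((diff**2).sum())

        _, diff, ssd_prev = warped_ssd(u)
        best_u, best_ssd = u.copy(), ssd_prev
        bad_streak = 0
        for _ in range(params.iterations_per_level):
            if ssd_prev <= 1e-12:
                break
            total_iters += 1
            denom = grad_sq + diff**2
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(denom > 1e-9, -diff / denom, 0.0)[None] * grad
            max_step = params.max_step_voxels * sp.min()
            mag = np.sqrt((step**2).sum(axis=0))
            over = mag > max_step
            if over.any():
                step = np.where(over[None], step * (max_step / np.maximum(mag, 1e-12))[None], step)
            if params.update_sigma_voxels > 0:
                step = np.stack(
                    [ndimage.gaussian_filter(step[a], params.update_sigma_voxels) for a in range(3)]
                )
            u = u + step.astype(np.float32)
            if params.field_sigma_voxels > 0:
                u = np.stack(
                    [ndimage.gaussian_filter(u[a], params.field_sigma_voxels) for a in range(3)]
                ).astype(np.float32)
            _, diff, ssd = warped_ssd(u)
            if ssd < best_ssd:
                best_u, best_ssd = u.copy(), ssd
            if ssd > ssd_prev:
                bad_streak += 1
                if bad_streak >= params.divergence_patience:
                    diverged = True
                    break
            else:
                bad_streak = 0
            if ssd_prev > 0 and (ssd_prev - ssd) / ssd_prev < params.rel_tolerance:
                ssd_prev = ssd
                break
            ssd_prev = ssd
        u = best_u
        if diverged:
            break

    # bring the field to full resolution and enforce the SSD contract
    if u.shape[1:] != grid.shape:
        u = np.stack(
            [ndimage.zoom(u[a], np.asarray(grid.shape) / np.asarray(u[a].shape), order=1)
             for a in range(3)]
        ).astype(np.float32)
    base = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float32) for n in grid.shape], indexing="ij")
    )
    ssd0 = float(((m0 - f0) ** 2).sum())
    coords = base + u / spacing[:, None, None, None]
    mw = ndimage.map_coordinates(m0, coords, order=1, mode="nearest")
    ssd_final = float(((mw - f0) ** 2).sum())
    if ssd_final > ssd0:
        diverged = True
        u = np.zeros_like(u)
        ssd_final = ssd0
    field = DeformationField(grid, u)
    return field, DemonsReport(ssd0, ssd_final, total_iters, diverged)


# ---------------------------------------------------------------------------
# label propagation and fusion
# ---------------------------------------------------------------------------


def propagate_labels(
    atlas_structures: StructureSet,
    rigid: RigidTransform,
    field: DeformationField,
    threshold: float = 0.5,
) -> StructureSet:
    """Resample every atlas mask through the composed transform.

    Masks are interpolated trilinearly and binarised at ``threshold``
    (default 0.5).  Identity transforms return the input masks unchanged.
    """
    out_grid = field.grid
    masks = {}
    for name, mask in atlas_structures.masks.items():
        warped = _warp_volume(
            mask.astype(np.float32), atlas_structures.grid, out_grid,
            rigid=rigid, field=field, cval=0.0,
        )
        masks[name] = warped >= threshold
    return StructureSet(out_grid, masks)


@dataclass(frozen=True)
class FusionPolicy:
    """Consensus rule for combining candidate segmentations.

    A voxel enters the consensus when the fraction of candidates containing
    it reaches ``vote_fraction`` (0.5 = majority).  ``atlas_preselect_k``
    optionally keeps only the k atlases most similar to the test image after
    rigid alignment; off by default (all atlases in a group are fused).
    """

    method: str = "majority"
    vote_fraction: float = 0.5
    atlas_preselect_k: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.vote_fraction <= 1.0:
            raise ValueError("vote_fraction must lie in (0, 1]")
        if self.method not in ("majority", "threshold"):
            raise ValueError(f"unknown fusion method {self.method!r}")


def fuse(candidates: list[StructureSet], policy: FusionPolicy = FusionPolicy()) -> StructureSet:
    """Per-voxel vote across candidate structure sets.

    Included iff the candidate fraction containing the voxel ≥
    ``vote_fraction``; permutation-invariant; a single candidate is returned
    unchanged; ``vote_fraction=1.0`` is the voxelwise intersection.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    grid = candidates[0].grid
    names = set(candidates[0].names)
    for c in candidates[1:]:
        grid.require_compatible(c.grid)
        names &= set(c.names)
    n = len(candidates)
    fused = {}
    for name in names:
        votes = np.zeros(grid.shape, dtype=np.int32)
        for c in candidates:
            votes += c[name]
        fused[name] = votes >= policy.vote_fraction * n - 1e-9
    return StructureSet(grid, fused)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MASParams:
    rigid: RigidParams = field(default_factory=RigidParams)
    demons: DemonsParams = field(default_factory=DemonsParams)


def auto_segment(
    test: CaseRecord,
    atlas_group: list[CaseRecord],
    policy: FusionPolicy = FusionPolicy(),
    params: MASParams = MASParams(),
    _allow_leakage: bool = False,
) -> StructureSet:
    """Multi-atlas auto-segmentation of one test case.

    Per atlas: rigid registration, demons DIR, label propagation; then
    fusion of all candidates (optionally the ``atlas_preselect_k`` atlases
    ranked by post-rigid NCC).  Deterministic given inputs and parameters.
    Raises :class:`LeakageError` if the test case id appears in the atlas
    group (``_allow_leakage`` exists only for sanity checks).
    """
    if not atlas_group:
        raise ValueError("atlas group is empty")
    if not _allow_leakage and any(a.case_id == test.case_id for a in atlas_group):
        raise LeakageError(
            f"test case {test.case_id!r} appears in its own atlas group"
        )
    grid = test.grid
    aligned = []
    for atlas in atlas_group:
        rigid = rigid_register(test.intensity, atlas.intensity, grid, params.rigid)
        moved = _warp_volume(
            atlas.intensity, atlas.grid, grid, rigid=rigid, cval=float(atlas.intensity.min())
        )
        aligned.append((atlas, rigid, moved, _ncc(test.intensity, moved)))
    if policy.atlas_preselect_k is not None:
        aligned = sorted(aligned, key=lambda t: -t[3])[: policy.atlas_preselect_k]
    candidates = []
    for atlas, rigid, moved, _ in aligned:
        fld, report = deformable_register(test.intensity, moved, grid, params.demons)
        if report.diverged:
            warnings.warn(
                f"deformable registration diverged for atlas {atlas.case_id!r}; "
                "using best field found",
                RuntimeWarning,
                stacklevel=2,
            )
        candidates.append(propagate_labels(atlas.structures, rigid, fld))
    return fuse(candidates, policy)
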