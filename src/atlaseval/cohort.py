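"""Seeded synthetic thorax phantoms and controlled contour perturbations.

This module makes every downstream stage testable without clinical data.  A
phantom is a stack of analytic primitives on a shared grid: an elliptic
trunk whose lateral half-width scales with the chest-wall separation, a
half-ellipsoid breast on the anterior chest wall, a chain of nodal-level
ellipsoids running from the most superior-medial (level 4) to the most
inferior-lateral (level 1), interpectoral and internal-mammary nodes, a thin
tubular brachial plexus, a spherical humeral head, and ellipsoidal heart and
lung.  The breast-board incline (15°/20°) is applied as a rotation of the
anatomy about the lateral (x) axis.  Shape realism is deliberately
sacrificed for controllability: every structure has a closed-form ground
truth, and all randomness (per-case jitter, intensity noise, boundary
perturbations) is seeded and reproducible.

Small nodal structures carry no intensity contrast of their own — as on CT,
where nodal CTVs are drawn from anatomical context rather than visible
boundaries — so registration is driven by the body outline, lung, heart,
breast and bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .structures import CaseRecord, StructureSet

DEFAULT_GRID = VoxelGrid.centered((96, 96, 96), (2.5, 2.5, 2.5))

#: separation (cm) at or below which a case is classed "small"
DEFAULT_SEPARATION_CUT_CM = 19.0


class AnatomyOutsideGridError(ValueError):
    """A structure would extend beyond the voxel grid."""


@dataclass(frozen=True)
class CaseMeta:
    """Per-case generation parameters."""

    case_id: str
    incline_deg: int = 15
    separation_cm: float = 18.0
    separation_class: str = "small"
    role: str = "atlas"
    grid: VoxelGrid = DEFAULT_GRID


def _ellipsoid(X, Y, Z, center, semi):
    cx, cy, cz = center
    ax, ay, az = semi
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _segment_distance(X, Y, Z, p0, p1):
    """Distance (cm) from each voxel center to the segment p0–p1."""
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    dd = float(d @ d)
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / dd
    t = np.clip(t, 0.0, 1.0)
    return np.sqrt(
        (X - (p0[0] + t * d[0])) ** 2
        + (Y - (p0[1] + t * d[1])) ** 2
        + (Z - (p0[2] + t * d[2])) ** 2
    )


def make_phantom(meta: CaseMeta, seed: int) -> CaseRecord:
    """Generate one thorax phantom.

    Identical ``(meta, seed)`` yields bit-identical output.  Raises
    :class:`AnatomyOutsideGridError` when the grid cannot contain the
    anatomy and ``ValueError`` for unsupported incline values.
    """
    if meta.incline_deg not in (15, 20):
        raise ValueError(f"unsupported breast-board incline: {meta.incline_deg}")
    grid = meta.grid
    if np.any(grid.fov_cm < 21.0):
        raise AnatomyOutsideGridError(
            f"grid field of view {grid.fov_cm} cm too small to contain the anatomy (needs >= 21 cm)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    jit = lambda scale=0.25: rng.uniform(-scale, scale, size=3)  # noqa: E731
    szj = lambda: rng.uniform(0.95, 1.05, size=3)  # noqa: E731

    X, Y, Z = grid.meshgrid_cm()
    # incline applied as rotation of the anatomy about x; 15° is canonical
    theta = np.deg2rad(meta.incline_deg - 15.0)
    if theta != 0.0:
        Ya = Y * np.cos(theta) + Z * np.sin(theta)
        Za = -Y * np.sin(theta) + Z * np.cos(theta)
    else:
        Ya, Za = Y, Z

    s = meta.separation_cm / 2.0  # trunk lateral half-width
    trunk = ((X / s) ** 2 + (Ya / 8.0) ** 2 <= 1.0) & (np.abs(Za) <= 10.3)

    masks: dict[str, np.ndarray] = {}
    masks["Breast"] = (
        _ellipsoid(X, Ya, Za, (0.45 * s + jit()[0], 3.5 + jit()[1], 3.5 + jit()[2]),
                   np.array([0.32 * s, 3.2, 4.2]) * szj())
        & (Ya >= 1.0)
    )
    masks["Heart"] = _ellipsoid(
        X, Ya, Za, np.array([-0.30 * s, 0.0, 4.5]) + jit(), np.array([3.4, 3.2, 4.2]) * szj()
    )
    masks["Lung"] = _ellipsoid(
        X, Ya, Za, np.array([0.35 * s, -1.5, -1.0]) + jit(),
        np.array([0.28 * s + 1.5, 4.5, 7.5]) * szj(),
    )
    # nodal chain: level 4 superior-medial -> level 1 inferior-lateral
    p_sup = np.array([0.12 * s, 2.0, -8.0])
    p_inf = np.array([0.62 * s, 0.5, -3.5])
    semis = {
        "Level4": (0.9, 0.8, 1.2),
        "Level3": (1.0, 0.9, 1.3),
        "Level2": (1.1, 0.9, 1.4),
        "Level1": (1.6, 1.2, 1.8),
    }
    for k, name in enumerate(("Level4", "Level3", "Level2", "Level1")):
        c = p_sup + (k / 3.0) * (p_inf - p_sup) + jit(0.15)
        masks[name] = _ellipsoid(X, Ya, Za, c, np.asarray(semis[name]) * szj())
    l2c = p_sup + (2 / 3.0) * (p_inf - p_sup)
    masks["Interpectoral"] = _ellipsoid(
        X, Ya, Za, l2c + np.array([0.0, 1.8, 0.0]) + jit(0.15), np.array([0.8, 0.6, 1.0]) * szj()
    )
    imn_x, imn_y = 0.08 * s + jit(0.1)[0], 2.5 + jit(0.1)[1]
    masks["IMN"] = ((X - imn_x) ** 2 + (Ya - imn_y) ** 2 <= 0.45**2) & (Za >= -7.0) & (Za <= -1.0)
    bp0 = np.array([0.10 * s, 2.2, -9.0]) + jit(0.1)
    bp1 = np.array([0.55 * s, 0.8, -5.5]) + jit(0.1)
    masks["BrachialPlexus"] = _segment_distance(X, Ya, Za, bp0, bp1) <= 0.45
    masks["HumeralHead"] = _ellipsoid(
        X, Ya, Za, np.array([0.66 * s, -0.5, -7.5]) + jit(0.15), 1.6 * szj()
    )

    # the body envelope is the trunk plus every structure (skin bulges over
    # the breast and shoulder), guaranteeing anatomical containment
    body = trunk.copy()
    for m in masks.values():
        body |= m

    intensity = np.full(grid.shape, -1000.0, dtype=np.float32)
    intensity[body] = 30.0
    intensity[masks["Breast"]] = -80.0
    intensity[masks["Lung"]] = -750.0
    intensity[masks["Heart"]] = 45.0
    intensity[masks["HumeralHead"]] = 600.0
    intensity = ndimage.gaussian_filter(intensity, sigma=0.8)
    intensity += rng.normal(0.0, 10.0, size=grid.shape).astype(np.float32)

    structures = StructureSet(grid, masks).combine_nodes()
    for name, m in structures.masks.items():
        if not m.any():
            raise AnatomyOutsideGridError(f"structure {name!r} empty on grid {grid.shape}")
    return CaseRecord(
        case_id=meta.case_id,
        intensity=intensity.astype(np.float32),
        structures=structures,
        incline_deg=meta.incline_deg,
        separation_cm=meta.separation_cm,
        separation_class=meta.separation_class,
        role=meta.role,
        body=body,
    )


# ---------------------------------------------------------------------------
# controlled perturbations (pseudo-auto-segmentations with known ground truth)
# ---------------------------------------------------------------------------


class PerturbationOutsideGridError(ValueError):
    """The requested transform pushes a structure outside the grid."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Known, controllable deviation applied to reference structures.

    Each mask is scaled about its own centroid, translated by
    ``translation_cm``, then boundary-perturbed by a smooth seeded noise
    field of standard deviation ``boundary_noise_sd_cm`` (a signed normal
    displacement of the surface) and re-binarised.
    """

    translation_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    boundary_noise_sd_cm: float = 0.0
    smoothing_radius_voxels: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.scale):
            raise ValueError("scale factors must be > 0")
        if self.boundary_noise_sd_cm < 0:
            raise ValueError("boundary noise sd must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            not any(self.translation_cm)
            and all(f == 1.0 for f in self.scale)
            and self.boundary_noise_sd_cm == 0.0
        )


def perturb(ref: StructureSet, spec: PerturbationSpec) -> StructureSet:
    """Apply a :class:`PerturbationSpec` to every mask of a structure set."""
    grid = ref.grid
    t = np.asarray(spec.translation_cm, float)
    scale = np.asarray(spec.scale, float)
    out: dict[str, np.ndarray] = {}
    coords_1d = grid.coordinates_cm()
    lo = np.array([c[0] for c in coords_1d]) - grid.spacing_cm / 2
    hi = np.array([c[-1] for c in coords_1d]) + grid.spacing_cm / 2

    for k, name in enumerate(sorted(ref.masks)):
        mask = ref.masks[name]
        if spec.is_identity:
            out[name] = mask.copy()
            continue
        idx = np.nonzero(mask)
        centroid = grid.voxel_to_world(np.stack([i.mean() for i in idx]))
        # forward map: x' = c + scale*(x-c) + t ; check the transformed bbox
        bb_lo = grid.voxel_to_world([i.min() for i in idx])
        bb_hi = grid.voxel_to_world([i.max() for i in idx])
        corners = np.array(
            [[bb_lo[a] if (c >> a) & 1 == 0 else bb_hi[a] for a in range(3)] for c in range(8)]
        )
        fwd = centroid + scale * (corners - centroid) + t
        if np.any(fwd < lo) or np.any(fwd > hi):
            raise PerturbationOutsideGridError(
                f"transform pushes structure {name!r} outside the grid"
            )
        # pull resampling: source = c + (target - t - c)/scale
        Xt, Yt, Zt = grid.meshgrid_cm()
        src = [
            centroid[a] + ([Xt, Yt, Zt][a] - t[a] - centroid[a]) / scale[a] for a in range(3)
        ]
        vox = [(src[a] - grid.origin_cm[a]) / grid.spacing_cm[a] for a in range(3)]
        moved = ndimage.map_coordinates(
            mask.astype(np.float32), np.stack(vox), order=1, mode="constant", cval=0.0
        )
        new = moved >= 0.5
        if spec.boundary_noise_sd_cm > 0:
            rng = np.random.default_rng(np.random.SeedSequence((spec.seed, k)))
            noise = rng.normal(size=grid.shape)
            sigma = max(spec.smoothing_radius_voxels, 1e-6)
            noise = ndimage.gaussian_filter(noise, sigma=sigma)
            sd = noise.std()
            if sd > 0:
                noise = noise / sd * spec.boundary_noise_sd_cm
            # signed distance to the surface (cm): positive outside
            sdist = ndimage.distance_transform_edt(
                ~new, sampling=grid.spacing_cm
            ) - ndimage.distance_transform_edt(new, sampling=grid.spacing_cm)
            new = sdist <= noise
        out[name] = new
    return StructureSet(grid, out)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterMix:
    """Requested cohort composition.

    ``p_incline20`` / ``p_large`` are the fractions of cases scanned at 20°
    incline and of large chest-wall separation; realised counts are the
    nearest integers.  Separations are drawn uniformly within
    ``cut ± [0.5, 3.0]`` cm on the matching side of ``separation_cut_cm``,
    keeping the class labels consistent with the cut by construction.
    """

    p_incline20: float = 0.5
    p_large: float = 0.5
    separation_cut_cm: float = DEFAULT_SEPARATION_CUT_CM

    def __post_init__(self) -> None:
        for p in (self.p_incline20, self.p_large):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mix proportions must lie in [0, 1], got {p}")


def case_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Stable per-case seed: cohorts extend without reshuffling earlier cases."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def make_cohort(
    n: int,
    mix: ParameterMix = ParameterMix(),
    seed: int = 0,
    n_test: int | None = None,
    grid: VoxelGrid = DEFAULT_GRID,
) -> list[CaseRecord]:
    """Generate a seeded cohort of ``n`` phantoms.

    The realised incline/separation composition matches ``mix`` to within
    integer rounding.  The last ``n_test`` cases (default ``max(1, n // 10)``)
    are assigned the test role; the rest are atlases.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    n_test = max(1, n // 10) if n_test is None else n_test
    if not 0 <= n_test <= n:
        raise ValueError("n_test must lie in [0, n]")
    n20 = round(n * mix.p_incline20)
    n_large = round(n * mix.p_large)

    master = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2**20,)))
    incline_flags = np.zeros(n, dtype=bool)
    incline_flags[master.permutation(n)[:n20]] = True
    large_flags = np.zeros(n, dtype=bool)
    large_flags[master.permutation(n)[:n_large]] = True

    cases = []
    for i in range(n):
        rng = np.random.default_rng(case_seed(seed, i))
        offset = rng.uniform(0.5, 3.0)
        sep = mix.separation_cut_cm + offset if large_flags[i] else mix.separation_cut_cm - offset
        meta = CaseMeta(
            case_id=f"case{i:03d}",
            incline_deg=20 if incline_flags[i] else 15,
            separation_cm=float(round(sep, 2)),
            separation_class="large" if large_flags[i] else "small",
            role="test" if i >= n - n_test else "atlas",
            grid=grid,
        )
        cases.append(make_phantom(meta, seed=int(rng.integers(0, 2**31 - 1))))
    return cases
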