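"""Registration, propagation and fusion against synthetic ground truth."""

import itertools

import numpy as np
import pytest

from atlaseval.cohort import CaseMeta, PerturbationSpec, make_phantom, perturb
from atlaseval.grid import VoxelGrid
from atlaseval.mas import (
    DeformationField,
    DemonsParams,
    FusionPolicy,
    LeakageError,
    MASParams,
    RigidTransform,
    auto_segment,
    deformable_register,
    fuse,
    propagate_labels,
    rigid_register,
)
from atlaseval.metrics import jaccard
from atlaseval.structures import CaseRecord, StructureSet

FAST_DEMONS = DemonsParams(levels=2, iterations_per_level=20)


@pytest.fixture(scope="module")
def blob_grid():
    return VoxelGrid.centered((48, 48, 48), (5.0, 5.0, 5.0))


@pytest.fixture(scope="module")
def blob(blob_grid):
    X, Y, Z = blob_grid.meshgrid_cm()
    return (100.0 * np.exp(-(X**2 + Y**2 + Z**2) / (2 * 3.0**2))).astype(np.float32)


class TestRigidTransform:
    def test_inverse_composes_to_identity(self):
        tr = RigidTransform((4.0, -3.0, 7.0), (1.2, -0.4, 0.9), (0.5, 0.0, -1.0))
        pts = np.random.default_rng(0).uniform(-5, 5, (20, 3))
        back = tr.inverse().apply_points(tr.apply_points(pts))
        assert np.allclose(back, pts, atol=1e-10)


class TestRigidRegister:
    def test_self_registration_is_near_identity(self, phantom64, grid64):
        tr = rigid_register(phantom64.intensity, phantom64.intensity, grid64)
        half_voxel = grid64.spacing_cm[0] / 2
        assert np.all(np.abs(tr.translation_cm) < half_voxel)
        assert np.all(np.abs(tr.rotation_deg) < 0.5)

    def test_recovers_known_translation(self, phantom64, grid64):
        # content moved +2 voxels in x; pull convention maps test coords
        # into atlas space, so the recovered translation is +0.75 cm
        moving = np.roll(phantom64.intensity, 2, axis=0)
        tr = rigid_register(phantom64.intensity, moving, grid64)
        assert tr.translation_cm[0] == pytest.approx(0.75, abs=grid64.spacing_cm[0])
        assert abs(tr.translation_cm[1]) < grid64.spacing_cm[1]
        assert abs(tr.translation_cm[2]) < grid64.spacing_cm[2]

    def test_recovers_known_rotation(self, grid64):
        # the same anatomy scanned at 20° incline is rotated 5° about x
        flat = make_phantom(CaseMeta("a", incline_deg=15, grid=grid64), seed=1)
        tilted = make_phantom(CaseMeta("a", incline_deg=20, grid=grid64), seed=1)
        tr = rigid_register(flat.intensity, tilted.intensity, grid64)
        assert abs(abs(tr.rotation_deg[0]) - 5.0) < 1.0

    def test_constant_volume_rejected(self, grid64):
        flat = np.zeros(grid64.shape, np.float32)
        with pytest.raises(ValueError, match="constant"):
            rigid_register(flat, flat, grid64)


class TestDeformableRegister:
    def test_identical_volumes_give_null_field(self, phantom64, grid64):
        field, report = deformable_register(
            phantom64.intensity, phantom64.intensity, grid64, FAST_DEMONS
        )
        max_disp_vox = np.abs(field.displacement_mm).max() / min(grid64.spacing_mm)
        assert max_disp_vox < 0.1
        assert report.ssd_final <= report.ssd_initial

    def test_recovers_known_shift_of_smooth_blob(self, blob, blob_grid):
        moving = np.roll(blob, 2, axis=0)  # content moved +2 voxels (+10 mm)
        field, report = deformable_register(blob, moving, blob_grid)
        core = blob > 30
        mean_u = [field.displacement_mm[a][core].mean() for a in range(3)]
        assert abs(mean_u[0] - 10.0) < 0.5 * blob_grid.spacing_mm[0]
        assert abs(mean_u[1]) < 0.5 * blob_grid.spacing_mm[1]
        assert report.ssd_final <= report.ssd_initial
        assert report.ssd_final < 0.05 * report.ssd_initial

    def test_agrees_with_independent_demons_implementation(self, blob, blob_grid):
        """Cross-check the mean recovered displacement against SimpleITK's
        demons filter on the same shifted-blob problem."""
        sitk = pytest.importorskip("SimpleITK")
        moving = np.roll(blob, 2, axis=0)
        field, _ = deformable_register(blob, moving, blob_grid)
        f = sitk.GetImageFromArray(blob.T.astype(np.float64))
        m = sitk.GetImageFromArray(moving.T.astype(np.float64))
        for img in (f, m):
            img.SetSpacing(tuple(blob_grid.spacing_mm))
        demons = sitk.DemonsRegistrationFilter()
        demons.SetNumberOfIterations(60)
        demons.SetStandardDeviations(1.5 * blob_grid.spacing_mm[0])
        ref_field = demons.Execute(f, m)
        ref = sitk.GetArrayFromImage(ref_field)  # (z, y, x, 3) with xyz vectors
        core = (blob > 30).T
        ref_mean_x = ref[..., 0][core].mean()
        own_mean_x = field.displacement_mm[0][blob > 30].mean()
        assert abs(own_mean_x - ref_mean_x) < 0.5 * blob_grid.spacing_mm[0]

    def test_ssd_never_worse_than_initial(self, blob, blob_grid, rng):
        noisy = (blob + rng.normal(0, 15, blob.shape)).astype(np.float32)
        _, report = deformable_register(blob, noisy, blob_grid, FAST_DEMONS)
        assert report.ssd_final <= report.ssd_initial


class TestPropagateLabels:
    def test_identity_transform_is_identity_on_masks(self, phantom64, grid64):
        out = propagate_labels(
            phantom64.structures,
            RigidTransform.identity(grid64),
            DeformationField.zero(grid64),
        )
        for name in out.names:
            assert np.array_equal(out[name], phantom64.structures[name])

    def test_whole_voxel_translation_shifts_masks_exactly(self, phantom64, grid64):
        # atlas content sits +2 voxels from the test case; the pull
        # transform samples the atlas at x + 0.75 cm
        rigid = RigidTransform(translation_cm=(0.75, 0.0, 0.0))
        shifted_structs = StructureSet(
            grid64, {n: np.roll(m, 2, axis=0) for n, m in phantom64.structures.masks.items()}
        )
        out = propagate_labels(shifted_structs, rigid, DeformationField.zero(grid64))
        for name in out.names:
            assert np.array_equal(out[name], phantom64.structures[name])

    def test_fractional_shift_roughly_preserves_volume(self, blob_grid):
        X, Y, Z = blob_grid.meshgrid_cm()
        sphere = (X**2 + Y**2 + Z**2) <= 3.0**2
        structs = StructureSet(blob_grid, {"Heart": sphere})
        rigid = RigidTransform(translation_cm=(blob_grid.spacing_cm[0] / 2, 0, 0))
        out = propagate_labels(structs, rigid, DeformationField.zero(blob_grid))
        assert out["Heart"].sum() == pytest.approx(sphere.sum(), rel=0.15)


class TestFuse:
    def test_majority_rule_on_all_presence_patterns(self, grid48):
        # enumerate all 8 patterns of one voxel across 3 candidates
        for pattern in itertools.product([0, 1], repeat=3):
            sets = []
            for present in pattern:
                m = np.zeros(grid48.shape, bool)
                m[5, 5, 5] = bool(present)
                sets.append(StructureSet(grid48, {"Heart": m}))
            fused = fuse(sets, FusionPolicy(vote_fraction=0.5))
            assert fused["Heart"][5, 5, 5] == (sum(pattern) / 3 >= 0.5)

    def test_permutation_invariance(self, grid48, rng):
        sets = [
            StructureSet(grid48, {"Lung": rng.random(grid48.shape) < 0.4}) for _ in range(4)
        ]
        a = fuse(sets, FusionPolicy(vote_fraction=0.5))
        b = fuse(sets[::-1], FusionPolicy(vote_fraction=0.5))
        assert np.array_equal(a["Lung"], b["Lung"])

    def test_unanimity_is_intersection_and_singleton_identity(self, grid48, rng):
        masks = [rng.random(grid48.shape) < 0.5 for _ in range(3)]
        sets = [StructureSet(grid48, {"Lung": m}) for m in masks]
        strict = fuse(sets, FusionPolicy(vote_fraction=1.0))
        assert np.array_equal(strict["Lung"], masks[0] & masks[1] & masks[2])
        solo = fuse(sets[:1], FusionPolicy())
        assert np.array_equal(solo["Lung"], masks[0])

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fuse([], FusionPolicy())


class TestAutoSegment:
    def test_leakage_is_detected(self, phantom64):
        with pytest.raises(LeakageError):
            auto_segment(phantom64, [phantom64])

    def test_discordant_atlas_is_outvoted(self, phantom64, grid64):
        """With two concordant atlases and one grossly displaced one, the
        majority consensus follows the concordant pair."""

        def clone(case, case_id, structures=None, intensity=None):
            return CaseRecord(
                case_id,
                case.intensity if intensity is None else intensity,
                case.structures if structures is None else structures,
                case.incline_deg,
                case.separation_cm,
                case.separation_class,
                "atlas",
                case.body,
            )

        good1 = clone(phantom64, "good1")
        good2 = clone(phantom64, "good2")
        shifted = StructureSet(
            grid64,
            {n: np.roll(m, 8, axis=2) for n, m in phantom64.structures.masks.items()},
        )
        bad = clone(
            phantom64, "bad",
            structures=shifted,
            intensity=np.roll(phantom64.intensity, 8, axis=2),
        )
        test = clone(phantom64, "test")
        out = auto_segment(
            test, [good1, good2, bad], FusionPolicy(vote_fraction=0.5),
            MASParams(demons=FAST_DEMONS),
        )
        concordant = phantom64.structures
        for name in ("Breast", "Heart", "Lung"):
            agreement = np.mean(out[name] == concordant[name])
            assert agreement >= 0.95

    def test_accuracy_does_not_degrade_with_cleaner_atlases(self, grid64, phantom64):
        """Seeded end-to-end monotonicity: lowering boundary noise in the
        atlas contours does not lower the mean JSC of the consensus."""
        atlases = [
            make_phantom(CaseMeta(f"atl{i}", grid=grid64), seed=20 + i) for i in range(2)
        ]

        def with_noise(sd):
            out = []
            for a in atlases:
                structs = (
                    a.structures
                    if sd == 0
                    else perturb(a.structures, PerturbationSpec(boundary_noise_sd_cm=sd, seed=4))
                )
                out.append(
                    CaseRecord(
                        a.case_id, a.intensity, structs, a.incline_deg,
                        a.separation_cm, a.separation_class, "atlas", a.body,
                    )
                )
            return out

        params = MASParams(demons=FAST_DEMONS)
        scores = []
        for sd in (1.0, 0.0):
            auto = auto_segment(phantom64, with_noise(sd), params=params)
            scores.append(
                np.mean(
                    [
                        jaccard(phantom64.structures[n], auto[n]).jaccard
                        for n in ("Breast", "Heart", "Lung", "Level1")
                    ]
                )
            )
        assert scores[1] >= scores[0]
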