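# Methods

This note documents the models, conventions and numerical choices behind
`atlaseval`, and what its synthetic experiments can and cannot say about
clinical data.

## Coordinate and sign conventions

All volumes live on regular grids indexed `[ix, iy, iz]` with a fixed
anatomical meaning: +x lateral, +y anterior, +z inferior. Physical
coordinates are cm at voxel centers (0-based indices mapped through origin
and spacing); voxel spacing is stored in mm. This orientation makes the
reported signs directly interpretable: `min_z` is the superior extent,
`max_z` the inferior, etc.

Directional extents use occupied voxel **centers**, not voxel boundaries,
so every extent-based quantity is exact on the lattice and discretisation
error is at most one voxel.

## Synthetic cohort

The generator emulates a planning-CT cohort for breast/nodal radiotherapy
as analytic primitives on a shared grid (default 96³ at 2.5 mm isotropic —
small enough for minutes-scale registration, fine enough that 0.1 cm
reporting precision is resolvable):

* elliptic trunk whose lateral half-width is `separation_cm / 2`, so the
  chest-wall separation stratifier has a direct geometric meaning;
* half-ellipsoid breast on the anterior chest wall; ellipsoidal heart and
  lung; spherical humeral head (bone intensity);
* nodal levels as an ellipsoid chain ordered level 4 (superior-medial) to
  level 1 (inferior-lateral), plus interpectoral and internal-mammary
  nodes and a thin tubular brachial plexus. Combined CTVs (levels 3&4,
  1–4) are voxelwise unions by construction;
* breast-board incline applied as a rotation of the anatomy about x, with
  15° as the canonical orientation (a 20° case is the same anatomy rotated
  5°);
* per-case seeded jitter (±0.25 cm centres, ±5 % sizes) for inter-patient
  variation.

The intensity proxy assigns CT-like tissue classes (air −1000, soft tissue
≈30, lung −750, fat-like breast −80, bone 600), Gaussian-smoothed (σ = 0.8
voxel) with seeded noise (SD 10). Nodal CTVs deliberately carry **no
intensity contrast** — as on CT, where they are drawn from anatomical
context — so registration is driven by the body outline and the large
organs, and small-structure accuracy is intrinsically worse. That
reproduces the qualitative clinical pattern (large structures JSC ≈ 0.8–1,
nodes/brachial plexus ≈ 0.3–0.7 in our runs) without claiming quantitative
realism.

Cohort composition: requested incline/separation proportions are realised
as exact rounded counts assigned by a seeded permutation; separations are
drawn uniformly 0.5–3 cm on the matching side of the class cut. The cut
defaults to 19 cm, is pure configuration, and the small/large label is
consistent with it by construction. Per-case random streams come from
`SeedSequence(master, spawn_key=(index,))`, a counter scheme that keeps a
case's stream independent of cohort size; the exact-count metadata
assignment, by contrast, necessarily depends on n.

Limitations: no CT physics, no organ motion, no genuinely deformable
inter-patient anatomy model — inter-patient variation is jitter plus
separation/incline. Passing tests therefore validate the *pipeline and
metric arithmetic*, not clinical segmentation accuracy; clinical headline
values (e.g. cohort-level mean JSC) are not reproducible from synthetic
data and are not asserted anywhere.

## Perturbation model (pseudo-auto-segmentations)

`perturb` applies, per structure: anisotropic scaling about the structure
centroid, then translation, then a boundary perturbation that thresholds
the signed Euclidean distance map against a smooth seeded noise field
(white noise smoothed with σ = `smoothing_radius_voxels`, rescaled to
`boundary_noise_sd_cm`). The noise therefore moves the surface by a
zero-mean displacement of known SD. Whole-voxel translations are exact
(trilinear resampling at integer offsets); a transform that would push a
structure's bounding box outside the grid raises rather than silently
clipping. This gives every downstream metric a closed-form expectation.

## Registration engine

**Rigid**: normalised cross-correlation over 3 translations + 3 rotations
about the grid centre, initialised from body-mask centroids and refined by
Powell's method on a ≤48³ downsampled copy. Search space: translations
± quarter field of view around the initialisation, rotations ±15° (covers
the 15°↔20° incline gap). Transforms use the pull convention — they map
test-grid coordinates into atlas space — so recovering an atlas whose
content sits +1 cm from the test yields translation +1 cm.

**Deformable**: multi-resolution (default 3 levels, 50 iterations/level)
demons iteration. Per voxel, with fixed image f, warped moving m and
fixed-image gradient ∇f (precomputed per level):

```
δ = −(m − f) ∇f / (|∇f|² + (m − f)²)
```

intensities normalised to [0, 1], steps capped at 2 voxels, fluid-like
smoothing of the update (σ = 1.0 voxel) and diffusion-like smoothing of
the field (σ = 1.5 voxels). Iteration stops when the relative SSD
improvement falls below 1e−4, at the iteration cap, or after 3 consecutive
SSD increases (divergence guard). The best field seen is kept, and the
returned field's full-resolution SSD is never worse than the zero field
(falling back to zero displacement, flagged in the report, otherwise).
These defaults are pragmatic choices for 2.5–5 mm synthetic volumes, all
exposed in `DemonsParams`.

**Propagation and fusion**: masks are resampled trilinearly through
`x ↦ T_rigid(x + u(x))` and binarised at 0.5. Fusion includes a voxel when
the candidate fraction containing it is ≥ `vote_fraction` (default 0.5,
i.e. majority; 1.0 is intersection), which is permutation-invariant and
reduces to identity for a single candidate. Optional atlas pre-selection
(top-k by post-rigid NCC) exists but is off by default, since the study
design fuses every atlas in a group.

## Metric definitions and decisions

* Jaccard/Dice are joint voxel-count scores; two empty masks score 1
  (identical), empty vs non-empty scores 0 — documented edge convention.
* The structure centre is the unweighted centroid of occupied voxel
  centers. Both centre modes are provided: `own` (each contour's own
  centroid; a pure displacement of the test contour cancels, leaving shape
  differences) and `reference` (shared reference centroid; variants
  recover displacement). `own` is the default.
* Variants are oriented **reference − test**. On max-directions a positive
  variant then means the auto-contour falls short (under-contouring) while
  on min-directions negative means under-contouring; rather than flipping
  signs per direction, the raw signed variants are kept (so the arithmetic
  matches published variant tables cell for cell) and
  `classify_variant` applies the direction-aware under/over rule, with a
  0.05 cm dead band below which a variant is "none" (half the 0.1 cm
  reporting precision).
* Reporting rounds to 1 decimal (cm); raw values are always retained.

The bundled worked-example table (`worked_example.py`) transcribes
published mean extents and variants for a heterogeneous atlas group from a
clinical 100-case evaluation. A few printed variants differ from the
difference of the printed means by 0.1 cm (per-case averaging vs
difference-of-means rounding); both are kept verbatim and only the
internally consistent cells are asserted in tests.

## Study design

* Groups are seeded samples without replacement from atlas-role cases
  passing the group's incline/separation filters; test-role cases are
  structurally ineligible, enforcing the no-leakage rule (additionally
  asserted at segmentation time).
* MTC test cases satisfy their group's filters; NMTC cases violate at
  least one.
* CDV exclusion: mean JSC per structure strictly below 0.5 (boundary value
  retained), plus heart and lung unconditionally.
* Aggregation uses sample SD (n−1). The "larger structures" class is
  breast, heart, lung and level 1 nodes.
* One-way ANOVA is implemented as textbook sums of squares so the
  degenerate conventions are explicit (no between-group variability →
  F = 0, p = 1; zero within-group variability → F = ∞, p = 0); it is
  cross-checked against an independent brute-force implementation and
  `scipy.stats.f_oneway` in the tests. Adjusted R² is the single-predictor
  OLS form via statsmodels and may be negative.
* Clinical-relevance flagging is data, not logic: a rule list of
  (structure, anatomical direction, threshold) checked against mean
  variants. The default list covers breast medial/posterior, level 1 and
  level 2 posterior, level 3 lateral, level 4 medial/lateral and brachial
  plexus medial/posterior/anterior at 0.3 cm — the smallest displacement
  treated as requiring an edit. Rules naming absent or excluded structures
  warn and are skipped.

## Problem sizes used in tests

The test and acceptance suites run the full pipeline at reduced sizes
chosen as the smallest grids that still resolve every structure: 64³ at
3.75 mm for registration tests, 48³ at 5 mm for study/IO tests, and one
96³ self-atlas segmentation check at the default resolution. The brachial
plexus (0.45 cm tube radius) sets the floor: at 5 mm spacing its
cross-section still contains voxel centers everywhere along the tube;
coarser grids would lose it.
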