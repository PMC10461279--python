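# atlaseval

Desk-scale evaluation of **multi-atlas auto-segmentation (MAS)** for breast
and regional-nodal radiotherapy contours.

Radiotherapy planning needs accurate contours of the breast clinical target
volume, axillary/supraclavicular nodal levels 1–4 (and the combined CTVs
3&4 and 1–4), interpectoral and internal mammary nodes, brachial plexus,
humeral head, heart and lung. Atlas-based auto-segmentation propagates
previously contoured scans (atlases) onto a new patient via rigid +
deformable registration and fuses the propagated contours into a consensus,
but the result still needs clinician editing — and the interesting
questions are *how many atlases a group needs*, *whether matching atlases
to patient characteristics (breast-board incline 15°/20°, chest-wall
separation) helps*, and *where the auto-contour deviates*, since location
determines clinical relevance.

`atlaseval` implements that whole evaluation loop at desk scale, with a
synthetic thorax cohort standing in for clinical CTs so that every result
has a known ground truth:

* `atlaseval.cohort` — seeded parametric thorax phantoms (analytic
  primitives with per-case jitter, incline applied as a rotation about the
  lateral axis, trunk width scaling with chest-wall separation) and
  controlled perturbations (translation / scaling / boundary noise) that
  act as pseudo-auto-segmentations with closed-form expected metrics.
* `atlaseval.mas` — a transparent MAS engine: NCC rigid registration,
  multi-resolution demons/optical-flow deformable registration, trilinear
  label propagation and per-voxel vote fusion, with a leakage guard (a test
  case may never sit in its own atlas group).
* `atlaseval.metrics` — the comparison metrics (see below).
* `atlaseval.study` — atlas-group construction (sizes, character-specific,
  matching/non-matching test cases), exclusion rules, descriptive
  statistics, one-way ANOVA, adjusted R², and clinical-relevance flagging.
* `atlaseval.io` / `atlaseval.cli` — NIfTI + JSON + YAML + CSV formats and
  a four-stage command line (`simulate`, `autoseg`, `evaluate`, `report`).

## Metrics

**Jaccard similarity coefficient (JSC)** of reference contour *A* and
auto-segmentation *B*, with its Dice relative:

```
JSC = |A ∩ B| / |A ∪ B|          J = D / (2 − D),  D = 2|A ∩ B| / (|A| + |B|)
```

**Centroid distance variants (CDV)** localise the deviation. On a grid with
+x lateral, +y anterior, +z inferior, the six *directional extents* of a
structure are the coordinates (cm) of its most medial/lateral,
posterior/anterior and superior/inferior occupied voxel centers. Each
extent minus a centre coordinate is a signed *centroid distance* d; the
*variant* per direction is

```
CDV_dir = d_ref,dir − d_test,dir
```

which is 0 when the contours agree. With the centre taken as each
structure's own centroid (default) a pure displacement cancels; with a
common reference centre the variants recover −t for a shift t. Because
"reference − test" means opposite things on min- and max-directions, a
direction-aware classifier maps variants to under-/over-contouring labels.
CDV is excluded for structures whose mean JSC < 0.5 and for heart and lung
(routinely contoured by treatment planning systems), and mean variants are
checked against a configurable rule map of clinically relevant locations
(default: breast medial/posterior, level 1 and 2 posterior, level 3
lateral, level 4 medial/lateral, brachial plexus medial/posterior/anterior,
at 0.3 cm).

## Worked example

`examples/demo.yaml`:

```yaml
seed: 3
cohort:
  n: 12
  n_test: 2
  p_incline20: 0.5
  p_large: 0.5
  grid: {shape: [64, 64, 64], spacing_mm: [3.75, 3.75, 3.75]}
groups:
  - {label: het3, size: 3, match_policy: none}
segmenter:
  mode: mas            # or "pseudo" for known-truth perturbations
  n_test_cases: 2
mas:
  demons: {levels: 2, iterations_per_level: 20}
metrics: {centre_mode: own}
rules: {threshold_cm: 0.3}
```

```
atlaseval simulate -c examples/demo.yaml -o runs/cohort
atlaseval evaluate -c examples/demo.yaml --cohort runs/cohort -o runs/results
atlaseval report   -c examples/demo.yaml --results runs/results -o runs/report
```

prints (about 30 s on one CPU):

```
Per-structure mean centroid distance variants (cm)

structure           medial   lateral posterior  anterior  superior  inferior
BrachialPlexus        -0.0      -0.4       0.0       0.0      -0.2       0.1
Breast                 0.5      -0.6       0.1      -0.1       0.0       0.0
Heart                   --        --        --        --        --        --
HumeralHead            0.2       0.0      -0.3       0.1      -0.0      -0.0
IMN                    0.0       0.0       0.2      -0.2       0.2      -0.0
Interpectoral           --        --        --        --        --        --
Level1                  --        --        --        --        --        --
Level1_4               0.3      -0.3      -0.1      -0.1      -0.2       0.2
Level2                  --        --        --        --        --        --
Level3                 0.0       0.2       0.0       0.0      -0.1       0.3
Level3_4              -0.1       0.1       0.0       0.0      -0.1       0.2
Level4                -0.1      -0.1      -0.0      -0.0      -0.0      -0.0
Lung                    --        --        --        --        --        --

mean JSC (all structures): 0.6 (SD 0.2)
one-way ANOVA of JSC across groups: n/a (single group)
clinically relevant variant locations flagged: 1
```

Reading it: a three-atlas group on a 64³ phantom cohort reaches a mean JSC
of 0.6 — large, high-contrast structures (lung, heart, breast) segment
well, small low-contrast nodal volumes poorly, which is exactly the pattern
the exclusion rule encodes (`--` rows: heart/lung are always withheld from
CDV analysis; level 1–2 and interpectoral nodes fell below the JSC 0.5
cut in this small run). The signed variant table localises the residual
deviations; exactly one rule-listed location — the medial aspect of the
breast, at 0.5 cm — exceeds the 0.3 cm relevance threshold and would need
review before planning (the brachial plexus lateral deviation of −0.4 cm
is not on the default rule list and is therefore not flagged).

The same pipeline with `segmenter: {mode: pseudo}` and an identity
perturbation is the null case: JSC 1.0, all variants 0, zero flags.

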