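"""Worked-example dataset: published clinical mean extents and variants.

These values are transcribed from a published clinical evaluation of
multi-atlas auto-segmentation on a 100-case breast/nodal radiotherapy
cohort: for the heterogeneous (randomly mixed) atlas group, the mean
directional extents (cm, per the medial/lateral, posterior/anterior,
superior/inferior axis convention) of the reference contours and of the
auto-segmentations, together with the printed per-direction variants
(reference − auto-segmentation).

They serve two purposes: a worked example for the displacement-metric
arithmetic (recomputing variants from the mean extents through the package's
own centroid-distance operations), and the input for the default
clinical-relevance flagging rules.

The printed table is not perfectly self-consistent: for a few cells the
printed variant differs from the difference of the printed means by 0.1 cm
(per-case averaging versus difference-of-means rounding).  Both the printed
variants and the means are kept verbatim; ``recomputed_variants`` returns
what the arithmetic actually gives.
"""

from __future__ import annotations

import pandas as pd

from .metrics import DIRECTIONS, DirectionalExtents, cdv, centroid_distances

#: (reference mean extent, auto-segmentation mean extent) in cm per
#: structure and direction, heterogeneous atlas group
HETEROGENEOUS_MEAN_EXTENTS_CM: dict[str, dict[str, tuple[float, float]]] = {
    "Breast": {
        "min_x": (0.9, 2.0), "max_x": (16.1, 16.1), "min_y": (-2.1, -1.5),
        "max_y": (8.4, 8.5), "min_z": (-9.4, -8.2), "max_z": (6.5, 7.6),
    },
    "Level1": {
        "min_x": (9.1, 9.7), "max_x": (14.3, 14.0), "min_y": (-3.3, -2.1),
        "max_y": (2.3, 2.1), "min_z": (-11.0, -11.7), "max_z": (-3.8, -4.5),
    },
    "Level2": {
        "min_x": (6.4, 6.8), "max_x": (10.6, 10.4), "min_y": (-1.0, -0.6),
        "max_y": (3.7, 3.4), "min_z": (-12.8, -12.9), "max_z": (-6.7, -6.9),
    },
    "Level3": {
        "min_x": (3.2, 3.8), "max_x": (8.8, 8.1), "min_y": (-0.1, -0.3),
        "max_y": (4.3, 4.1), "min_z": (-12.8, -13.1), "max_z": (-9.4, -9.4),
    },
    "Level4": {
        "min_x": (1.2, 1.5), "max_x": (6.0, 6.5), "min_y": (0.2, 0.7),
        "max_y": (4.2, 4.1), "min_z": (-13.2, -13.4), "max_z": (-10.6, -10.7),
    },
    "BrachialPlexus": {
        "min_x": (-0.2, 3.3), "max_x": (10.7, 10.7), "min_y": (-1.1, -0.3),
        "max_y": (4.2, 2.0), "min_z": (-12.7, -15.3), "max_z": (-4.0, -11.1),
    },
    "HumeralHead": {
        "min_x": (11.1, 11.1), "max_x": (15.7, 15.9), "min_y": (-3.7, -3.5),
        "max_y": (1.1, 1.5), "min_z": (-15.8, -16.1), "max_z": (-12.4, -12.3),
    },
}

#: per-direction variants (cm) as printed for the heterogeneous atlas group
HETEROGENEOUS_PRINTED_VARIANTS_CM: dict[str, dict[str, float]] = {
    "Breast": {"min_x": -1.2, "max_x": 0.0, "min_y": -0.7, "max_y": -0.1,
               "min_z": -1.2, "max_z": -1.1},
    "Level1": {"min_x": -0.6, "max_x": 0.3, "min_y": -1.2, "max_y": 0.1,
               "min_z": 0.8, "max_z": 0.8},
    "Level2": {"min_x": -0.4, "max_x": 0.2, "min_y": -0.4, "max_y": 0.3,
               "min_z": 0.1, "max_z": 0.2},
    "Level3": {"min_x": -0.6, "max_x": 0.7, "min_y": 0.2, "max_y": 0.2,
               "min_z": 0.3, "max_z": 0.0},
    "Level4": {"min_x": -0.3, "max_x": -0.5, "min_y": -0.5, "max_y": 0.2,
               "min_z": 0.2, "max_z": 0.1},
    "BrachialPlexus": {"min_x": -3.5, "max_x": 0.0, "min_y": -0.9, "max_y": 2.2,
                       "min_z": 2.6, "max_z": 7.1},
    "HumeralHead": {"min_x": 0.0, "max_x": -0.2, "min_y": -0.2, "max_y": -0.4,
                    "min_z": 0.3, "max_z": -0.1},
}


def mean_extents() -> pd.DataFrame:
    """Long-format table: structure, direction, ref_cm, auto_cm."""
    rows = [
        {"structure": s, "direction": d, "ref_cm": ref, "auto_cm": auto}
        for s, dirs in HETEROGENEOUS_MEAN_EXTENTS_CM.items()
        for d, (ref, auto) in dirs.items()
    ]
    return pd.DataFrame(rows)


def printed_variants() -> pd.DataFrame:
    """Printed variants, wide format: index=structure, columns var_min_x…var_max_z."""
    return pd.DataFrame(
        {
            s: {f"var_{d}": v for d, v in dirs.items()}
            for s, dirs in HETEROGENEOUS_PRINTED_VARIANTS_CM.items()
        }
    ).T[[f"var_{d}" for d in DIRECTIONS]]


def recomputed_variants(decimals: int = 1) -> pd.DataFrame:
    """Variants recomputed from the mean extents via the cdv operation.

    The six mean extents per contour are treated as directional extents in a
    common reference frame (centre at the coordinate origin, reference
    centre mode), so each variant is the reference-minus-auto difference of
    extents — the arithmetic behind the printed variant rows.
    """
    origin = (0.0, 0.0, 0.0)
    rows = {}
    for s, dirs in HETEROGENEOUS_MEAN_EXTENTS_CM.items():
        ref_ext = DirectionalExtents(**{d: dirs[d][0] for d in DIRECTIONS})
        auto_ext = DirectionalExtents(**{d: dirs[d][1] for d in DIRECTIONS})
        rec = cdv(
            centroid_distances(ref_ext, origin, "reference"),
            centroid_distances(auto_ext, origin, "reference"),
            structure=s,
            decimals=decimals,
        )
        rows[s] = {f"var_{d}": v for d, v in rec.rounded().items()}
    return pd.DataFrame(rows).T[[f"var_{d}" for d in DIRECTIONS]]
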