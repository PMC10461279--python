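"""Study design: atlas grouping, evaluation runs, statistics and flagging.

This module reproduces the evaluation protocol around the segmentation
engine: seeded construction of atlas groups (by size or by case character —
breast-board incline and chest-wall separation), selection of matching
(MTC) or deliberately non-matching (NMTC) test cases, the per-case
per-structure evaluation table (Jaccard overlap + centroid distance
variants), the exclusion rule that withholds displacement metrics from
low-overlap structures and from organs routinely contoured by treatment
planning systems, descriptive aggregation, one-way ANOVA, adjusted R², and
clinical-relevance flagging of mean variants against a configurable rule
map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import PerturbationSpec, perturb
from .mas import FusionPolicy, MASParams, auto_segment
from .metrics import DIRECTION_FROM_ANATOMICAL, DIRECTIONS, jaccard, structure_cdv
from .structures import CaseRecord, LARGE_STRUCTURES, ROUTINE_TPS_STRUCTURES

#: evaluation-table columns holding the six variants (cm)
VARIANT_COLUMNS = tuple(f"var_{d}" for d in DIRECTIONS)


class InsufficientAtlasesError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """Selection criteria for one atlas group.

    ``incline_filter``/``separation_filter`` restrict the atlas character;
    ``match_policy`` governs test-case selection: MTC test cases satisfy the
    group's filters, NMTC test cases violate at least one of them.
    """

    label: str
    size: int
    incline_filter: int | None = None          # 15 | 20 | None (any)
    separation_filter: str | None = None       # "small" | "large" | None (any)
    match_policy: str = "none"                 # "MTC" | "NMTC" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("group size must be >= 1")
        if self.incline_filter not in (None, 15, 20):
            raise ValueError(f"incline_filter must be 15, 20 or None, got {self.incline_filter}")
        if self.separation_filter not in (None, "small", "large"):
            raise ValueError(f"invalid separation_filter {self.separation_filter!r}")
        if self.match_policy not in ("MTC", "NMTC", "none"):
            raise ValueError(f"invalid match_policy {self.match_policy!r}")

    def matches(self, case: CaseRecord) -> bool:
        if self.incline_filter is not None and case.incline_deg != self.incline_filter:
            return False
        if self.separation_filter is not None and case.separation_class != self.separation_filter:
            return False
        return True


def build_group(library: list[CaseRecord], spec: GroupSpec) -> list[CaseRecord]:
    """Seeded sampling without replacement of ``spec.size`` eligible atlases.

    Only atlas-role cases matching the spec's filters are eligible, so
    designated test cases can never leak into a group.  Identical
    ``(library, spec)`` yields identical membership.
    """
    eligible = sorted(
        (c for c in library if c.role == "atlas" and spec.matches(c)),
        key=lambda c: c.case_id,
    )
    if len(eligible) < spec.size:
        raise InsufficientAtlasesError(
            f"group {spec.label!r} needs {spec.size} atlases, only {len(eligible)} eligible"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    idx = rng.choice(len(eligible), size=spec.size, replace=False)
    return [eligible[i] for i in sorted(idx)]


def select_test_cases(
    library: list[CaseRecord], spec: GroupSpec, n: int
) -> list[CaseRecord]:
    """Select ``n`` test-role cases under the group's match policy."""
    tests = sorted((c for c in library if c.role == "test"), key=lambda c: c.case_id)
    if spec.match_policy == "MTC":
        pool = [c for c in tests if spec.matches(c)]
    elif spec.match_policy == "NMTC":
        pool = [c for c in tests if not spec.matches(c)]
    else:
        pool = tests
    if len(pool) < n:
        raise ValueError(
            f"match policy {spec.match_policy!r} for group {spec.label!r}: "
            f"needs {n} test cases, only {len(pool)} available"
        )
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# evaluation runs
# ---------------------------------------------------------------------------


def evaluate_pair(
    reference, auto, grid, structures=None, centre_mode: str = "own", decimals: int = 1
) -> list[dict]:
    """Per-structure JSC + CDV rows for one (reference, AS) structure-set pair."""
    rows = []
    names = structures if structures is not None else reference.names
    vox = float(np.prod(grid.spacing_cm))
    for name in names:
        ref_mask = reference[name]
        auto_mask = auto[name] if name in auto else np.zeros(grid.shape, bool)
        row = {
            "structure": name,
            "jaccard": jaccard(ref_mask, auto_mask).jaccard,
            "volume_cm3": float(ref_mask.sum()) * vox,
            "cdv_excluded": False,
            "exclusion_reason": "",
        }
        if ref_mask.any() and auto_mask.any():
            rec = structure_cdv(ref_mask, auto_mask, grid, centre_mode, name, decimals)
            for d in DIRECTIONS:
                row[f"var_{d}"] = rec.variants[d]
        else:
            for d in DIRECTIONS:
                row[f"var_{d}"] = np.nan
            row["cdv_excluded"] = True
            row["exclusion_reason"] = "empty-mask"
        rows.append(row)
    return rows


def run_evaluation(
    groups: dict[str, list[CaseRecord]],
    test_cases: list[CaseRecord],
    mas_params: MASParams | None = None,
    policy: FusionPolicy = FusionPolicy(),
    pseudo_spec: PerturbationSpec | None = None,
    structures: tuple[str, ...] | None = None,
    centre_mode: str = "own",
) -> pd.DataFrame:
    """Evaluate every (group, test case) pair into a tidy table.

    When ``pseudo_spec`` is given, auto-segmentations are replaced by the
    known-truth perturbation of the reference structures (the pseudo-AS
    path used for closed-form validation); otherwise the full multi-atlas
    pipeline runs.  One row per (group, case, structure).
    """
    rows = []
    for label, atlases in groups.items():
        atlas_ids = {a.case_id for a in atlases}
        for case in test_cases:
            if case.case_id in atlas_ids:
                raise ValueError(
                    f"test case {case.case_id!r} is a member of group {label!r}"
                )
            if pseudo_spec is not None:
                auto = perturb(case.structures, pseudo_spec)
            else:
                auto = auto_segment(case, atlases, policy, mas_params or MASParams())
            for row in evaluate_pair(
                case.structures, auto, case.grid, structures, centre_mode
            ):
                rows.append({"group_label": label, "case_id": case.case_id, **row})
    return pd.DataFrame(rows)


def apply_cdv_exclusion(table: pd.DataFrame, jsc_threshold: float = 0.5) -> pd.DataFrame:
    """Mark CDV rows excluded from analysis.

    A structure's displacement metrics are excluded when its mean Jaccard
    across the table is strictly below ``jsc_threshold`` (reason
    ``"low-overlap"``) and, unconditionally, for the heart and lung (reason
    ``"routine-TPS structure"`` — these organs are routinely contoured by
    treatment planning systems).  A structure scoring exactly at the
    threshold is retained.
    """
    out = table.copy()
    mean_jsc = out.groupby("structure")["jaccard"].mean()
    for structure, mj in mean_jsc.items():
        sel = out["structure"] == structure
        if structure in ROUTINE_TPS_STRUCTURES:
            out.loc[sel, "cdv_excluded"] = True
            out.loc[sel, "exclusion_reason"] = "routine-TPS structure"
        elif mj < jsc_threshold:
            out.loc[sel, "cdv_excluded"] = True
            out.loc[sel, "exclusion_reason"] = "low-overlap"
    return out


def aggregate(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive summaries: mean and sample SD (n−1) of JSC and variants.

    Returns summaries keyed ``by_structure``, ``by_group`` and
    ``by_size_class`` (larger structures = breast, heart, lung, level 1
    nodes).  Variant statistics are computed over non-excluded rows only.
    Raw values are returned; round to 1 decimal for reporting.
    """
    if table.empty:
        raise ValueError("cannot aggregate an empty table")

    def summarise(df: pd.DataFrame) -> pd.Series:
        out = {"n": len(df), "jaccard_mean": df["jaccard"].mean(),
               "jaccard_sd": df["jaccard"].std(ddof=1)}
        ok = df[~df["cdv_excluded"]]
        for col in VARIANT_COLUMNS:
            out[f"{col}_mean"] = ok[col].mean() if len(ok) else np.nan
            out[f"{col}_sd"] = ok[col].std(ddof=1) if len(ok) else np.nan
        return pd.Series(out)

    t = table.sort_values(["group_label", "case_id", "structure"], kind="stable")
    by_structure = t.groupby("structure", sort=True).apply(summarise, include_groups=False)
    by_group = t.groupby(["group_label", "structure"], sort=True).apply(
        summarise, include_groups=False
    )
    t2 = t.assign(
        size_class=np.where(t["structure"].isin(sorted(LARGE_STRUCTURES)), "larger", "smaller")
    )
    by_size = t2.groupby("size_class", sort=True).apply(summarise, include_groups=False)
    return {"by_structure": by_structure, "by_group": by_group, "by_size_class": by_size}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def anova_oneway(samples: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA: between/within mean-square F and its p-value.

    Degenerate conventions: zero between-group variability gives
    ``F = 0, p = 1``; non-zero between- with zero within-group variability
    gives ``F = inf, p = 0``.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in samples]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups, each non-empty")
    n = sum(len(g) for g in groups)
    k = len(groups)
    if n - 1 < 2:
        raise ValueError("need >= 2 total degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssb <= 1e-300:
        return 0.0, 1.0
    if ssw <= 1e-300 or dfw == 0:
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return float(f), p


def adjusted_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Adjusted R² of the ordinary least-squares fit of y on x.

    Single-predictor form, 1 − (1 − R²)(n − 1)/(n − 2); may be negative.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.rsquared_adj)


# ---------------------------------------------------------------------------
# clinical-relevance flagging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelevanceRule:
    """Flag a (structure, direction) when the |mean variant| reaches threshold."""

    structure: str
    direction: str  # anatomical name: medial|lateral|posterior|anterior|superior|inferior
    threshold_cm: float = 0.3

    def __post_init__(self) -> None:
        if self.direction not in DIRECTION_FROM_ANATOMICAL:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.threshold_cm <= 0:
            raise ValueError("threshold_cm must be > 0")

    @property
    def axis_direction(self) -> str:
        return DIRECTION_FROM_ANATOMICAL[self.direction]


def default_relevance_rules(threshold_cm: float = 0.3) -> list[RelevanceRule]:
    """Variant locations that warrant review before radiotherapy planning.

    Breast: medial, posterior; level 1 and level 2 nodes: posterior;
    level 3: lateral; level 4: medial and lateral; brachial plexus: medial,
    posterior and anterior.  The 0.3 cm default is the smallest displacement
    treated as requiring a contour edit.
    """
    listed = [
        ("Breast", "medial"), ("Breast", "posterior"),
        ("Level1", "posterior"),
        ("Level2", "posterior"),
        ("Level3", "lateral"),
        ("Level4", "medial"), ("Level4", "lateral"),
        ("BrachialPlexus", "medial"), ("BrachialPlexus", "posterior"),
        ("BrachialPlexus", "anterior"),
    ]
    return [RelevanceRule(s, d, threshold_cm) for s, d in listed]


def flag_clinical(
    mean_variants: pd.DataFrame, rules: list[RelevanceRule] | None = None
) -> pd.DataFrame:
    """Apply relevance rules to a per-structure mean-variant table.

    ``mean_variants`` is indexed by structure with columns ``var_min_x`` …
    ``var_max_z`` (cm) — either an :func:`aggregate` ``by_structure`` table
    (using its ``*_mean`` columns) or a plain variant table.  Rules naming
    absent or excluded structures are skipped with a warning.  Returns one
    row per flagged (structure, direction).
    """
    rules = default_relevance_rules() if rules is None else rules
    flags = []
    for rule in rules:
        col = f"var_{rule.axis_direction}"
        mean_col = f"{col}_mean" if f"{col}_mean" in mean_variants.columns else col
        if rule.structure not in mean_variants.index:
            warnings.warn(
                f"relevance rule for absent structure {rule.structure!r} skipped",
                UserWarning, stacklevel=2,
            )
            continue
        value = mean_variants.loc[rule.structure, mean_col]
        if not np.isfinite(value):
            warnings.warn(
                f"relevance rule for excluded structure {rule.structure!r} skipped",
                UserWarning, stacklevel=2,
            )
            continue
        if abs(value) >= rule.threshold_cm:
            flags.append({
                "structure": rule.structure,
                "direction": rule.direction,
                "axis_direction": rule.axis_direction,
                "mean_variant_cm": float(value),
                "threshold_cm": rule.threshold_cm,
            })
    return pd.DataFrame(
        flags,
        columns=["structure", "direction", "axis_direction", "mean_variant_cm", "threshold_cm"],
    )
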