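"""Combined DNA-repair + NPM1/FLT3-ITD prognostic classification.

Mutation points follow the established CN-AML rule: NPM1-mutated without
FLT3-ITD is favorable (0 points), FLT3-ITD without NPM1 mutation is
adverse (2 points), any other combination is intermediate (1 point).
DNA-repair points come from the global risk group (I/II/III -> 0/1/2), so
total points range over {0..4}.  Consecutive point classes whose survival
does not differ by log-rank are merged, in ascending order, into final
groups labelled A, B, C, ... in increasing risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import SurvivalData, as_survival, logrank_test

__all__ = [
    "mutation_points",
    "combined_points",
    "merge_point_groups",
    "apply_merge_map",
    "classify_combined",
    "MergeResult",
    "GROUP_POINTS",
]

GROUP_POINTS = {"I": 0, "II": 1, "III": 2}
_LABELS = "ABCDE"


def mutation_points(npm1_mutated, flt3_itd):
    """NPM1/FLT3-ITD prognostic points: 0 favorable, 1 intermediate, 2 adverse.

    Accepts scalars (returns int) or aligned arrays/Series (returns ndarray
    or Series).  Missing flags raise: callers must exclude such patients
    explicitly.
    """
    scalar = np.isscalar(npm1_mutated) and np.isscalar(flt3_itd)
    npm1 = pd.Series(np.atleast_1d(npm1_mutated))
    itd = pd.Series(np.atleast_1d(flt3_itd))
    if len(npm1) != len(itd):
        raise ValueError("NPM1 and FLT3-ITD flags must be aligned")
    if npm1.isna().any() or itd.isna().any():
        raise ValueError("missing NPM1/FLT3-ITD flag; exclude those patients first")
    npm1 = npm1.astype(int)
    itd = itd.astype(int)
    if not npm1.isin([0, 1]).all() or not itd.isin([0, 1]).all():
        raise ValueError("mutation flags must be 0 or 1")
    pts = np.where((npm1 == 1) & (itd == 0), 0, np.where((npm1 == 0) & (itd == 1), 2, 1))
    if scalar:
        return int(pts[0])
    if isinstance(npm1_mutated, pd.Series):
        return pd.Series(pts, index=npm1_mutated.index, name="mutation_points")
    return pts


def combined_points(global_group, mut_points):
    """Total prognostic points: group I/II/III gives 0/1/2, plus mutation points."""
    scalar = isinstance(global_group, str) and np.isscalar(mut_points)
    groups = pd.Series(np.atleast_1d(global_group))
    pts = pd.Series(np.atleast_1d(mut_points))
    if not groups.isin(list(GROUP_POINTS)).all():
        bad = sorted(set(groups) - set(GROUP_POINTS))
        raise ValueError(f"invalid global group(s): {bad}")
    if not pts.isin([0, 1, 2]).all():
        raise ValueError("mutation points must be 0, 1 or 2")
    total = groups.map(GROUP_POINTS).to_numpy() + pts.to_numpy()
    if scalar:
        return int(total[0])
    if isinstance(global_group, pd.Series):
        return pd.Series(total, index=global_group.index, name="total_points")
    return total


@dataclass(frozen=True)
class MergeResult:
    merge_map: dict[int, str]  # total points (0..4) -> final label
    labels: pd.Series  # per-patient final label
    tests: pd.DataFrame  # the consecutive log-rank comparisons performed


def merge_point_groups(
    totals, data: SurvivalData, alpha: float = 0.05
) -> MergeResult:
    """Greedy ascending merge of consecutive point classes.

    Walk the non-empty point classes in ascending order; whenever the
    log-rank test between the current (possibly already merged) class and
    the next one is not significant at ``alpha``, merge them and re-test
    the merged class against the following one.  Remaining blocks are
    labelled A, B, C, ... in ascending risk (point) order.  Point totals
    unobserved in the data are mapped to the block covering their position
    so the returned map is total over 0..4.
    """
    data = as_survival(data)
    totals = pd.Series(totals).reset_index(drop=True)
    if len(totals) != data.n:
        raise ValueError("totals must align with the survival records")
    if not totals.isin(range(5)).all():
        raise ValueError("total points must lie in 0..4")
    observed = sorted(totals.unique())
    tests: list[dict] = []
    if len(observed) == 1:
        warnings.warn("all patients share one point total; single final group")
        blocks = [list(observed)]
    else:
        blocks = [[t] for t in observed]
        i = 0
        while i < len(blocks) - 1:
            left = totals.isin(blocks[i])
            right = totals.isin(blocks[i + 1])
            mask = (left | right).to_numpy()
            res = logrank_test(data.subset(mask), left[mask].to_numpy())
            tests.append(
                {
                    "left": tuple(blocks[i]),
                    "right": tuple(blocks[i + 1]),
                    "chi_square": res.chi_square,
                    "p_value": res.p_value,
                    "merged": res.p_value >= alpha,
                }
            )
            if res.p_value >= alpha:
                blocks[i] = blocks[i] + blocks.pop(i + 1)
            else:
                i += 1
    if len(blocks) > len(_LABELS):
        raise ValueError("more point classes than available labels")
    merge_map: dict[int, str] = {}
    for total in range(5):
        idx = 0
        for j, block in enumerate(blocks):
            if min(block) <= total:
                idx = j
        merge_map[total] = _LABELS[idx]
    labels = totals.map(merge_map).rename("final_group")
    return MergeResult(merge_map, labels, pd.DataFrame(tests))


def apply_merge_map(totals, merge_map) -> pd.Series:
    """Label point totals with a frozen merge map (validation cohorts)."""
    totals = pd.Series(totals)
    missing = sorted(set(totals.unique()) - set(merge_map))
    if missing:
        raise ValueError(f"merge map does not cover point total(s): {missing}")
    return totals.map(merge_map).rename("final_group")


def classify_combined(
    global_group: pd.Series,
    clinical: pd.DataFrame,
    merge_map=None,
    data: SurvivalData | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Full combined classification for a cohort.

    Needs ``clinical`` columns npm1_mutated / flt3_itd aligned with
    ``global_group``.  When ``merge_map`` is None a new map is fitted from
    ``data`` (training mode); otherwise the frozen map is applied.
    Returns the per-patient table and the merge map used.
    """
    mut = mutation_points(
        clinical.loc[global_group.index, "npm1_mutated"],
        clinical.loc[global_group.index, "flt3_itd"],
    )
    total = combined_points(global_group, mut)
    if merge_map is None:
        if data is None:
            raise ValueError("training a merge map needs survival data")
        merged = merge_point_groups(total, data, alpha=alpha)
        merge_map = merged.merge_map
        labels = merged.labels
        labels.index = global_group.index
    else:
        labels = apply_merge_map(total, merge_map)
    out = pd.DataFrame(
        {
            "mutation_points": np.asarray(mut),
            "dna_repair_points": global_group.map(GROUP_POINTS).to_numpy(),
            "total_points": np.asarray(total),
            "final_group": np.asarray(labels),
        },
        index=global_group.index,
    )
    return out, dict(merge_map)
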