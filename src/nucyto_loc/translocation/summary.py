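"""Condition-level summaries: mean normalized CI, fold-change, delta, ratios.

For each reporter group the baseline (unstimulated) condition anchors the
derived columns: ``fold_change = mean / baseline_mean`` and
``delta = mean - baseline_mean``.  When a reference reporter group is
designated, each other group's delta is additionally divided by the
reference group's delta for the same treatment (cross-group ratio).
Fold-changes and ratios are reported at full precision plus a
two-significant-figure rounding for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (NaN passes through)."""
    if not np.isfinite(x) or x == 0:
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class ConditionGroup:
    """One treatment condition within a reporter group."""

    label: str
    reporter_group: str
    ci_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ci_values = [float(v) for v in self.ci_values]
        if self.n == 0:
            raise ValueError(f"condition {self.label!r} has no CI values")

    @property
    def n(self) -> int:
        return len(self.ci_values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ci_values))

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(stats.sem(self.ci_values))


def summarize_conditions(
    groups: list[ConditionGroup],
    baseline_label: str,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Summary table with fold-change, delta and cross-group delta ratios.

    Requires the baseline condition in every reporter group.  A zero
    baseline mean leaves the fold-change undefined (NaN) with a flag; a
    zero reference delta likewise flags the cross ratio.
    """
    reporter_groups: dict[str, dict[str, ConditionGroup]] = {}
    for g in groups:
        reporter_groups.setdefault(g.reporter_group, {})
        if g.label in reporter_groups[g.reporter_group]:
            raise ValueError(f"duplicate condition {g.label!r} in group "
                             f"{g.reporter_group!r}")
        reporter_groups[g.reporter_group][g.label] = g
    for name, conds in reporter_groups.items():
        if baseline_label not in conds:
            raise ValueError(f"reporter group {name!r} lacks baseline "
                             f"{baseline_label!r}")
    if reference_group is not None and reference_group not in reporter_groups:
        raise ValueError(f"reference group {reference_group!r} not present")

    ref_deltas: dict[str, float] = {}
    if reference_group is not None:
        ref_base = reporter_groups[reference_group][baseline_label].mean
        for label, g in reporter_groups[reference_group].items():
            ref_deltas[label] = g.mean - ref_base

    rows = []
    for name, conds in reporter_groups.items():
        base_mean = conds[baseline_label].mean
        for label, g in conds.items():
            mean = g.mean
            delta = mean - base_mean
            flag = ""
            if base_mean == 0:
                fold = float("nan")
                flag = "fold-change undefined (baseline mean 0)"
            else:
                fold = mean / base_mean
            cross = float("nan")
            if (reference_group is not None and name != reference_group
                    and label != baseline_label):
                ref_delta = ref_deltas.get(label, float("nan"))
                if ref_delta == 0:
                    flag = (flag + "; " if flag else "") + \
                        "cross ratio undefined (reference delta 0)"
                elif np.isfinite(ref_delta):
                    cross = delta / ref_delta
            rows.append({
                "group": name,
                "label": label,
                "n": g.n,
                "mean": mean,
                "sem": g.sem,
                "fold_change": fold,
                "fold_change_2sf": round_sig(fold, 2),
                "delta": delta,
                "cross_ratio": cross,
                "cross_ratio_2sf": round_sig(cross, 2),
                "flag": flag,
            })
    df = pd.DataFrame(rows)
    return df.sort_values(["group", "label"]).reset_index(drop=True)
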