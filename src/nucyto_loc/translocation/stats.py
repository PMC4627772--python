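"""Group comparisons: one-way ANOVA with Dunnett's test, or t-test.

Two groups are compared by a two-tailed unpaired t-test; three or more by
one-way ANOVA plus Dunnett's many-to-one comparisons against a designated
control.  Significance stars: ns > 0.05, * <= 0.05, ** <= 0.01,
*** <= 0.001, **** <= 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def p_to_stars(p: float) -> str:
    if not np.isfinite(p):
        return "nd"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    design: str                      # "t-test" or "anova+dunnett"
    statistic: float                 # t or ANOVA F
    p_value: float                   # t-test p or ANOVA p
    per_group: dict[str, dict] = field(default_factory=dict)


def compare_groups(
    groups: dict[str, list[float]],
    control: str | None = None,
) -> GroupComparison:
    """Compare CI value groups.

    ``groups`` maps label -> values.  With exactly two groups a two-tailed
    unpaired t-test is used (control optional); with more, one-way ANOVA
    plus Dunnett's test against ``control`` (required).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")

    if len(arrays) == 2:
        (la, a), (lb, b) = arrays.items()
        res = stats.ttest_ind(a, b)
        p = float(res.pvalue)
        per = {lb if control == la else la if control == lb else lb: {
            "p": p, "stars": p_to_stars(p)}}
        return GroupComparison(
            design="t-test",
            statistic=float(res.statistic),
            p_value=p,
            per_group=per,
        )

    if control is None or control not in arrays:
        raise ValueError("Dunnett's test requires a designated control group")
    control_values = arrays[control]
    others = {k: v for k, v in arrays.items() if k != control}
    f_res = stats.f_oneway(*arrays.values())
    d_res = stats.dunnett(*others.values(), control=control_values)
    per = {}
    for (label, _), p in zip(others.items(), d_res.pvalue):
        per[label] = {"p": float(p), "stars": p_to_stars(float(p))}
    return GroupComparison(
        design="anova+dunnett",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        per_group=per,
    )
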