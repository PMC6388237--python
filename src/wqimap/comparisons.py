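"""Group comparisons of WQI distributions.

Two-group contrasts (water source, supply type, season) use Welch's
unequal-variance t-test by default — robust to the unbalanced group
sizes typical of monitoring designs — with a pooled-variance option;
multi-group contrasts (years) use classical one-way ANOVA.  Statistics
are computed from their explicit formulas; p-values come from the
scipy t and F distributions.  No multiple-testing correction is applied
by default (a Bonferroni helper is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass
class GroupComparison:
    """A fitted two-group or k-group test: statistic, df, p-value."""

    factor: str
    groups: list[GroupSummary]
    statistic: float
    p_value: float
    test: str  # "welch_t" | "pooled_t" | "anova_f"
    df: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "groups": [
                {"label": g.label, "n": g.n, "mean": g.mean, "sd": g.sd}
                for g in self.groups
            ],
        }


def _summaries(labels: Sequence[str], groups: Sequence[np.ndarray]) -> list[GroupSummary]:
    return [
        GroupSummary(lbl, len(g), float(np.mean(g)), float(np.std(g, ddof=1)))
        for lbl, g in zip(labels, groups)
    ]


def welch_t_test(
    a: Sequence[float],
    b: Sequence[float],
    factor: str = "",
    labels: tuple[str, str] = ("a", "b"),
    pooled: bool = False,
) -> GroupComparison:
    """Two-sample t-test: Welch's by default, pooled-variance on request.

    Welch's statistic is t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    with Welch-Satterthwaite degrees of freedom; the p-value is two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("each group needs >= 2 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        raise DegenerateDataError("both groups have zero variance")
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
        test = "pooled_t"
    else:
        sea, seb = va / na, vb / nb
        se = np.sqrt(sea + seb)
        df = (sea + seb) ** 2 / (sea**2 / (na - 1) + seb**2 / (nb - 1))
        test = "welch_t"
    t = float((np.mean(a) - np.mean(b)) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(
        factor=factor,
        groups=_summaries(labels, [a, b]),
        statistic=t,
        p_value=p,
        test=test,
        df=(df,),
    )


def one_way_anova(
    groups: Sequence[Sequence[float]],
    factor: str = "",
    labels: Sequence[str] | None = None,
) -> GroupComparison:
    """Classical one-way ANOVA F-test across k >= 2 groups.

    F = between-group mean square / within-group mean square on
    (k - 1, N - k) degrees of freedom.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise DegenerateDataError("ANOVA needs >= 2 groups, each with >= 2 values")
    all_vals = np.concatenate(arrays)
    if np.var(all_vals) == 0:
        raise DegenerateDataError("total variance is zero")
    k = len(arrays)
    n_total = len(all_vals)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        raise DegenerateDataError("within-group variance is zero")
    f = float((ss_between / df_b) / (ss_within / df_w))
    p = float(stats.f.sf(f, df_b, df_w))
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    return GroupComparison(
        factor=factor,
        groups=_summaries(labels, arrays),
        statistic=f,
        p_value=p,
        test="anova_f",
        df=(float(df_b), float(df_w)),
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def compare_by(df, factor: str, value_col: str = "wqi", pooled: bool = False) -> GroupComparison:
    """Compare WQI totals grouped by a metadata column of a DataFrame.

    Two levels dispatch to the t-test, three or more to ANOVA.
    """
    levels = sorted(df[factor].dropna().unique())
    groups = [df.loc[df[factor] == lv, value_col].to_numpy(dtype=float) for lv in levels]
    labels = [str(lv) for lv in levels]
    if len(groups) == 2:
        return welch_t_test(groups[0], groups[1], factor=factor,
                            labels=(labels[0], labels[1]), pooled=pooled)
    return one_way_anova(groups, factor=factor, labels=labels)
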