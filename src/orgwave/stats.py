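"""Group statistics and significance reporting.

Group comparisons use two-tailed Student's t-tests (pooled variance;
Welch available behind a flag); regional comparisons use one-way ANOVA
followed by Tukey's HSD post-hoc with p-values from the studentized-range
distribution.  Values are reported as mean ± SEM with the conventional
star mapping (* <0.05, ** <0.01, *** <0.001, **** <0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def significance_stars(p: float) -> str:
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    metric: str
    groups: tuple[str, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    statistic: float
    df: float
    p_value: float
    stars: str
    test: str
    note: str = ""


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def two_sample_t(a, b, *, metric: str = "", group_names=("a", "b"),
                 welch: bool = False) -> ComparisonResult:
    """Two-tailed Student's t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    note = ""
    pooled_var = (
        ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled_var == 0 and not welch:
        if np.mean(a) == np.mean(b):
            stat, p = 0.0, 1.0
        else:
            stat, p = np.inf, 0.0
            note = "zero pooled variance with unequal means"
        df = len(a) + len(b) - 2
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return ComparisonResult(
        metric=metric,
        groups=tuple(group_names),
        means=(float(np.mean(a)), float(np.mean(b))),
        sems=(_sem(a), _sem(b)),
        statistic=stat,
        df=df,
        p_value=p,
        stars=significance_stars(p),
        test="welch_t" if welch else "student_t",
        note=note,
    )


def oneway_anova_tukey(groups: dict[str, np.ndarray], *, metric: str = ""):
    """One-way ANOVA plus Tukey HSD pairwise table.

    Groups with fewer than 2 values are excluded with a note; fewer than
    3 usable groups is an error.  Returns (omnibus ComparisonResult,
    pairwise DataFrame).
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items()
              if len(np.asarray(v)) >= 2}
    dropped = sorted(set(groups) - set(usable))
    if len(usable) < 3:
        raise ValueError("one-way ANOVA needs at least 3 groups with n >= 2")
    names = list(usable)
    arrays = [usable[k] for k in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)
    n_total = sum(len(x) for x in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))
    omnibus = ComparisonResult(
        metric=metric,
        groups=tuple(names),
        means=tuple(float(np.mean(x)) for x in arrays),
        sems=tuple(_sem(x) for x in arrays),
        statistic=f_stat,
        df=df[0],
        p_value=p,
        stars=significance_stars(p),
        test="oneway_anova",
        note=f"dropped groups with n<2: {dropped}" if dropped else "",
    )
    degenerate = np.ptp(np.concatenate(arrays)) == 0
    tk = None if degenerate else sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p_adj = 1.0 if degenerate else float(tk.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": p_adj,
                    "stars": significance_stars(min(1.0, p_adj)),
                }
            )
    return omnibus, pd.DataFrame(rows)


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "metric": r.metric,
            "test": r.test,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "stars": r.stars,
        }
        for g, m, s in zip(r.groups, r.means, r.sems):
            row[f"mean_{g}"] = m
            row[f"sem_{g}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
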