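"""Classical inferential statistics: one-way ANOVA, Tukey HSD, pooled t.

These are computed from the textbook sums-of-squares formulas so every
intermediate (mean squares, q statistics, degrees of freedom) is exposed and
brute-force checkable; only the reference distributions (F, studentized
range, Student t) come from scipy.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import AnovaResult, TukeyPair, TukeyResult

GroupedData = Mapping[str, Sequence[float]]


def _validate(data: GroupedData, min_per_group: int = 2) -> dict[str, np.ndarray]:
    groups = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if v.size < min_per_group:
            raise ValueError(f"group {k!r} has fewer than {min_per_group} observations")
    return groups


def _within_ms(groups: dict[str, np.ndarray]) -> tuple[float, int]:
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    df_within = sum(v.size for v in groups.values()) - len(groups)
    return ss_within / df_within, df_within


def anova_oneway(data: GroupedData) -> AnovaResult:
    """One-way fixed-effects ANOVA.

    F is the ratio of the between-group to the within-group mean square;
    the p-value comes from the F(k−1, N−k) distribution. Zero within-group
    variance is rejected (the F statistic is undefined).
    """
    groups = _validate(data)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    k, N = len(groups), all_vals.size
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ms_within, df_within = _within_ms(groups)
    if ms_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    df_between = k - 1
    F = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within,
                       p=p, group_means={g: float(v.mean())
                                         for g, v in groups.items()})


def tukey_hsd(data: GroupedData, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD post hoc comparison of all group pairs.

    Uses the pooled within-group mean square; unbalanced designs use the
    Tukey-Kramer standard error. Adjusted p-values come from the
    studentized-range distribution with k groups and N−k error df.
    """
    groups = _validate(data)
    ms_within, df_within = _within_ms(groups)
    if ms_within == 0:
        raise ValueError("zero within-group variance")
    k = len(groups)
    pairs = []
    for a, b in combinations(groups, 2):
        va, vb = groups[a], groups[b]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(ms_within / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, df_within))
        p_adj = min(max(p_adj, 0.0), 1.0)
        pairs.append(TukeyPair(group_a=a, group_b=b, mean_diff=diff,
                               q=float(q), p_adj=p_adj,
                               significant=p_adj < alpha))
    return TukeyResult(pairs=pairs, alpha=alpha)


def t_test_one_tailed(a: Sequence[float], b: Sequence[float],
                      direction: str = "greater") -> float:
    """One-tailed pooled-variance (classical Student) two-sample t-test.

    ``direction="greater"`` tests the alternative mean(a) > mean(b);
    ``"less"`` tests mean(a) < mean(b). Identical samples give p = 0.5 and
    swapping the direction gives 1 − p.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p_greater = float(sps.t.sf(t, df))
    return p_greater if direction == "greater" else 1.0 - p_greater
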