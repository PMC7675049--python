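"""Between-group statistics and significance labelling.

Group comparisons follow the conventions of the source experiments:
normally-distributed (or small) per-cell mean values are compared with
one-way ANOVA plus Tukey's HSD post-hoc test; non-normal distributions with
a two-tailed Mann-Whitney U test. Significance labels use the strict
thresholds p < 0.05 (*), < 0.01 (**), < 0.005 (***), < 0.001 (****);
anything at or above 0.05 is "ns".
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sstats

from .errors import DomainError, ParameterError

EXACT_MWU_MAX_TOTAL = 12

_STAR_THRESHOLDS = ((0.001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    p_value: float
    label: str


def significance_label(p: float) -> str:
    """Star tier for a p-value (strict inequalities; boundary -> weaker)."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p-value must be in [0, 1], got {p}")
    for thr, stars in _STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a, with midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    r_a = ranks[:len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-tailed p by enumerating all group assignments (ties OK)."""
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - offset
    total = comb(n_a + n_b, n_a)
    idx = range(n_a + n_b)
    n_le = n_ge = 0
    eps = 1e-9
    for chosen in combinations(idx, n_a):
        u = ranks[list(chosen)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return min(p, 1.0)


def mann_whitney_u(a, b) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact by enumeration when n_a + n_b <= 12 (scipy's exact distribution
    when there are no ties); otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    if a.size + b.size <= EXACT_MWU_MAX_TOTAL:
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        if not has_ties:
            return float(sstats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact").pvalue)
        return _exact_mwu_p(a, b)
    return float(sstats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic",
        use_continuity=True).pvalue)


def anova_tukey(groups: dict) -> dict:
    """One-way ANOVA plus Tukey-HSD-adjusted pairwise p-values.

    ``groups`` maps name -> 1-D values, every group needing n >= 2.
    Returns {"f": F, "p": p_anova, "pairwise": [PairwiseResult, ...]}.
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ParameterError(f"group {name!r} needs n >= 2, got {arr.size}")
        arrays[name] = arr
    names = list(arrays)
    f_stat, p_anova = sstats.f_oneway(*arrays.values())
    if not np.isfinite(f_stat):        # all groups identical & constant
        f_stat, p_anova = 0.0, 1.0
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate([arrays[n] for n in names])
    labels = np.concatenate([[n] * arrays[n].size for n in names])
    if np.allclose(values, values[0]):
        pairwise = [PairwiseResult(x, y, 1.0, "ns")
                    for x, y in combinations(names, 2)]
        return {"f": 0.0, "p": 1.0, "pairwise": pairwise}
    tk = pairwise_tukeyhsd(values, labels)
    pairwise = []
    pairs = list(combinations(tk.groupsunique, 2))
    for (g1, g2), p in zip(pairs, tk.pvalues):
        p = float(min(max(p, 0.0), 1.0))
        pairwise.append(PairwiseResult(str(g1), str(g2), p,
                                       significance_label(p)))
    return {"f": float(f_stat), "p": float(p_anova), "pairwise": pairwise}
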