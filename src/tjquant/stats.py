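"""Nonparametric group comparisons used on cluster/capillary/leakage summaries.

Two groups: two-tailed Mann-Whitney U (exact enumeration for small tie-free
samples, tie-corrected normal approximation otherwise).  Three or more
groups: Kruskal-Wallis omnibus plus Dunn's pairwise z-tests with a
multiplicity adjustment (Bonferroni by default, Holm selectable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["GroupComparison", "mann_whitney_u", "kruskal_wallis_dunn"]

EXACT_MAX_N = 8  # exact enumeration up to this per-group size (tie-free)


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    adjusted: bool = False
    p_adjusted: float | None = None
    pair: tuple[str, str] | None = None
    method: str | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": list(self.group_sizes),
            "adjusted": self.adjusted,
            "p_adjusted": self.p_adjusted,
            "pair": list(self.pair) if self.pair else None,
            "method": self.method,
        }


def mann_whitney_u(
    sample_a, sample_b, method: str = "auto"
) -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    ``method='auto'`` uses exact enumeration when both samples have at most
    8 observations and no ties, and the tie-corrected normal approximation
    otherwise; 'exact' / 'asymptotic' force a choice.  The method actually
    used is recorded on the result.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    if method == "auto":
        tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (max(a.size, b.size) <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(a.size, b.size),
        method=method,
    )


def _dunn_pairwise(
    groups: list[np.ndarray], names: list[str], adjust: str
) -> list[GroupComparison]:
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # mean rank per group
    sizes = [g.size for g in groups]
    splits = np.cumsum(sizes)[:-1]
    rank_means = [r.mean() for r in np.split(ranks, splits)]
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var0 = n_total * (n_total + 1) / 12.0 - tie_term

    raw: list[GroupComparison] = []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (rank_means[i] - rank_means[j]) / se if se > 0 else 0.0
            p = float(2.0 * sps.norm.sf(abs(z)))
            raw.append(
                GroupComparison(
                    test_name="dunn",
                    statistic=float(z),
                    p_value=min(p, 1.0),
                    group_sizes=(sizes[i], sizes[j]),
                    pair=(names[i], names[j]),
                    method=adjust,
                )
            )
    m = len(raw)
    if adjust == "bonferroni":
        for c in raw:
            c.p_adjusted = min(1.0, c.p_value * m)
            c.adjusted = True
    elif adjust == "holm":
        order = np.argsort([c.p_value for c in raw])
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx].p_value * (m - rank))
            raw[idx].p_adjusted = min(1.0, running)
            raw[idx].adjusted = True
    else:
        raise ParameterError(f"unknown adjustment {adjust!r}")
    return raw


def kruskal_wallis_dunn(
    groups, names: list[str] | None = None, alpha: float = 0.05, adjust: str = "bonferroni"
) -> list[GroupComparison]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc tests.

    Returns the omnibus comparison first, followed by all pairwise Dunn
    comparisons with multiplicity-adjusted p-values (``p_adjusted``).
    Requires at least three groups (use :func:`mann_whitney_u` for two).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ParameterError("kruskal_wallis_dunn requires >= 3 groups")
    if any(a.size == 0 for a in arrays):
        raise ParameterError("all groups must be non-empty")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ParameterError("names/groups length mismatch")
    try:
        with np.errstate(invalid="ignore"):
            h, p = sps.kruskal(*arrays)
    except ValueError:
        h, p = np.nan, np.nan
    if not (np.isfinite(h) and np.isfinite(p)):
        h, p = 0.0, 1.0  # all values identical: H undefined, treat as null
    omnibus = GroupComparison(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        group_sizes=tuple(a.size for a in arrays),
        method=f"alpha={alpha}",
    )
    return [omnibus] + _dunn_pairwise(arrays, list(names), adjust)
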