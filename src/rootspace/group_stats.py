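"""Nonparametric group comparisons and the zero-intercept validation fit.

Treatment groups (solitary control vs. intra- vs. inter-specific pairs)
are compared by the Kruskal–Wallis rank test at family α = 0.05; when the
family null is rejected, every unordered pair is tested with a Wilcoxon
rank-sum (Mann–Whitney) test at the Bonferroni-style pairwise threshold
α = 0.05/3 ≈ 0.01667. Validation of voxel-based measurements against
reference values uses simple linear regression with the intercept
constrained to zero, whose slope is the captured fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairResult",
    "GroupComparison",
    "kruskal_wallis",
    "wilcoxon_each_pair",
    "regression_through_origin",
    "compare_groups",
    "ALPHA_FAMILY",
    "ALPHA_PAIRWISE",
]

ALPHA_FAMILY = 0.05
#: three treatment pairs -> 0.05 / 3
ALPHA_PAIRWISE = 0.05 / 3


@dataclass
class PairResult:
    pair: tuple[str, str]
    statistic: float  # Mann-Whitney U of the first-named group
    p_value: float
    significant: bool


@dataclass
class GroupComparison:
    """Family-level Kruskal–Wallis plus optional pairwise post-hocs."""

    parameter_name: str
    groups: dict[str, list[float]]
    H_statistic: float
    p_value: float
    posthoc: list[PairResult] = field(default_factory=list)
    alpha_family: float = ALPHA_FAMILY
    alpha_pairwise: float = ALPHA_PAIRWISE
    observation_unit: str = "individual"
    degenerate: bool = False


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value (k−1 df).

    All observations identical is a degenerate case: H is 0 by the
    tie-correction convention (p = 1).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise ValueError("empty group")
    if sum(g.size for g in arrays) < 3:
        raise ValueError("need total N >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def _rank_sum_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney for one pair.

    Exact enumeration when both groups have n < 10 and the pooled data is
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction. Identical groups give p = 1 under this
    convention.
    """
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) < 10 and len(b) < 10
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_each_pair(
    groups: Mapping[str, Sequence[float]],
    alpha_pairwise: float = ALPHA_PAIRWISE,
) -> list[PairResult]:
    """Wilcoxon rank-sum test for every unordered pair of groups.

    ``significant`` flags p <= alpha_pairwise. The p-value is symmetric in
    pair order (two-sided).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    out = []
    for na, nb in combinations(names, 2):
        a = np.asarray(groups[na], dtype=float)
        b = np.asarray(groups[nb], dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group in pair ({na}, {nb})")
        stat, p = _rank_sum_pair(a, b)
        out.append(
            PairResult(pair=(na, nb), statistic=stat, p_value=p,
                       significant=p <= alpha_pairwise)
        )
    return out


def regression_through_origin(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Least-squares slope of y = b·x (intercept constrained to 0).

    Returns ``(b, R²)`` with ``b = Σxᵢyᵢ/Σxᵢ²`` and R² computed about
    zero: ``1 − Σ(y − bx)²/Σy²`` (1.0 when y is identically zero).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if xa.size < 2:
        raise ValueError("need >= 2 points")
    sxx = float((xa * xa).sum())
    if sxx == 0:
        raise ValueError("slope undefined: all x are zero")
    b = float((xa * ya).sum() / sxx)
    syy = float((ya * ya).sum())
    if syy == 0:
        return b, 1.0
    resid = ya - b * xa
    return b, 1.0 - float((resid * resid).sum()) / syy


def compare_groups(
    parameter_name: str,
    groups: Mapping[str, Sequence[float]],
    alpha_family: float = ALPHA_FAMILY,
    alpha_pairwise: float = ALPHA_PAIRWISE,
    observation_unit: str = "individual",
) -> GroupComparison:
    """Family Kruskal–Wallis; pairwise post-hocs only on family rejection.

    ``observation_unit`` records whether values are per individual plant
    or pooled per tip/voxel — the paper-style pooling must be explicit
    because per-container replication is tiny.
    """
    h, p = kruskal_wallis([groups[k] for k in groups])
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in groups])
    degenerate = bool(np.all(pooled == pooled[0])) if pooled.size else True
    posthoc = (
        wilcoxon_each_pair(groups, alpha_pairwise) if p <= alpha_family else []
    )
    return GroupComparison(
        parameter_name=parameter_name,
        groups={k: [float(v) for v in groups[k]] for k in groups},
        H_statistic=h,
        p_value=p,
        posthoc=posthoc,
        alpha_family=alpha_family,
        alpha_pairwise=alpha_pairwise,
        observation_unit=observation_unit,
        degenerate=degenerate,
    )
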