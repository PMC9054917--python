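"""Rank-based significance testing: Friedman test and critical differences.

Given a table of performance scores for ``K`` algorithms over ``N`` blocks
(data sets, or labeling-rate conditions treated as data sets), the
algorithms are ranked within each block (rank 1 = best, average ranks for
ties).  With rank sums ``R_i`` the Friedman statistic is

    F_R = 12 / (N K (K+1)) * sum_i R_i^2  -  3 N (K+1),

approximately chi-square with ``K - 1`` degrees of freedom under the null
of no difference.  When the null is rejected, pairwise rank-sum
differences ``D_ij = R_i - R_j`` are compared against the critical
difference

    CD = z * sqrt(N K (K+1) / 6),

where ``z`` is the upper-tail normal quantile at ``alpha / (K (K-1))``
(a Bonferroni correction over ordered pairs).  Algorithm ``i`` is declared
significantly better than ``j`` when ``|D_ij| >= CD`` and ``D_ij < 0``
(lower rank = better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "RankTable",
    "FriedmanResult",
    "PosthocResult",
    "rank_blocks",
    "friedman_statistic",
    "chi2_critical",
    "critical_difference",
    "posthoc_compare",
    "friedman_test",
    "render_report",
]


@dataclass
class RankTable:
    scores: np.ndarray  # N x K
    ranks: np.ndarray  # N x K, rank 1 = best, average ranks at ties
    rank_sums: np.ndarray  # length K

    @property
    def n_blocks(self) -> int:
        return self.scores.shape[0]

    @property
    def n_algorithms(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class FriedmanResult:
    F_R: float
    df: int
    chi2_critical: float
    reject_null: bool
    alpha: float


@dataclass
class PosthocResult:
    D: np.ndarray  # K x K antisymmetric rank-sum differences
    CD: float
    decisions: np.ndarray  # K x K object array: better | worse | not-significant


def rank_blocks(scores: np.ndarray, higher_is_better: bool = True) -> RankTable:
    """Within-block ranks (1 = best) with average ranks assigned to ties."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise InvalidParameterError(f"need an N>=2 by K>=2 score table, got {scores.shape}")
    if np.isnan(scores).any():
        raise InvalidInputError("scores contain NaN")
    keyed = -scores if higher_is_better else scores
    ranks = sps.rankdata(keyed, axis=1, method="average")
    return RankTable(scores=scores, ranks=ranks, rank_sums=ranks.sum(axis=0))


def friedman_statistic(
    rank_sums: np.ndarray, N: int, K: int, alpha: float = 0.05
) -> FriedmanResult:
    """Friedman statistic from rank sums, gated by the chi-square critical value."""
    if N < 2 or K < 2:
        raise InvalidParameterError(f"need N >= 2 and K >= 2, got N={N}, K={K}")
    rank_sums = np.asarray(rank_sums, dtype=float)
    F_R = 12.0 / (N * K * (K + 1)) * float(np.sum(rank_sums**2)) - 3.0 * N * (K + 1)
    crit = chi2_critical(K - 1, alpha)
    return FriedmanResult(
        F_R=F_R, df=K - 1, chi2_critical=crit, reject_null=bool(F_R > crit), alpha=alpha
    )


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-``alpha`` quantile of the chi-square distribution."""
    if df < 1:
        raise InvalidParameterError("df must be >= 1")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    return float(sps.chi2.isf(alpha, df))


def critical_difference(N: int | None, K: int, alpha: float = 0.05) -> float:
    """Critical difference ``z * sqrt(N K (K+1) / 6)``.

    ``N`` is the number of blocks entering the rank sums.  Passing
    ``N=None`` uses 1 (a per-block-scale critical difference) and warns:
    published analyses are not always explicit about whether the
    ``sqrt(N)`` factor was applied, so the choice is left to the caller.
    """
    if N is None:
        warnings.warn(
            "critical_difference called without N; using N=1 (per-block scale). "
            "Pass the Friedman block count explicitly for the sqrt(N)-scaled value.",
            UserWarning,
            stacklevel=2,
        )
        N = 1
    if K < 2 or N < 1:
        raise InvalidParameterError("need K >= 2 and N >= 1")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    z = float(sps.norm.isf(alpha / (K * (K - 1))))
    return z * np.sqrt(N * K * (K + 1) / 6.0)


def posthoc_compare(rank_sums: np.ndarray, CD: float) -> PosthocResult:
    """Pairwise rank-sum comparisons against the critical difference.

    ``decisions[i, j] == "better"`` means algorithm ``i`` is significantly
    better than ``j`` (it achieved the lower rank sum by at least ``CD``).
    """
    rank_sums = np.asarray(rank_sums, dtype=float)
    D = rank_sums[:, None] - rank_sums[None, :]
    K = rank_sums.size
    decisions = np.full((K, K), "not-significant", dtype=object)
    sig = np.abs(D) >= CD
    decisions[sig & (D < 0)] = "better"
    decisions[sig & (D > 0)] = "worse"
    np.fill_diagonal(decisions, "not-significant")
    return PosthocResult(D=D, CD=CD, decisions=decisions)


def friedman_test(
    scores: np.ndarray,
    higher_is_better: bool = True,
    alpha: float = 0.05,
    cd_blocks: int | None = 1,
) -> tuple[RankTable, FriedmanResult, PosthocResult | None]:
    """Full pipeline: rank, Friedman gate, then post hoc if the null is rejected."""
    table = rank_blocks(scores, higher_is_better)
    fr = friedman_statistic(table.rank_sums, table.n_blocks, table.n_algorithms, alpha)
    post = None
    if fr.reject_null:
        cd = critical_difference(cd_blocks, table.n_algorithms, alpha)
        post = posthoc_compare(table.rank_sums, cd)
    return table, fr, post


def render_report(
    table: RankTable,
    fr: FriedmanResult,
    post: PosthocResult | None,
    names: list[str] | None = None,
) -> str:
    """Plain-text rendering of a Friedman + post-hoc analysis."""
    K = table.n_algorithms
    names = names or [f"alg{i + 1}" for i in range(K)]
    lines = [
        f"Friedman test over N={table.n_blocks} blocks, K={K} algorithms",
        f"  F_R = {fr.F_R:.4f}, chi2({fr.df}) critical at alpha={fr.alpha} = "
        f"{fr.chi2_critical:.3f} -> {'REJECT' if fr.reject_null else 'no rejection of'} H0",
        "  rank sums: " + ", ".join(f"{nm}={rs:.1f}" for nm, rs in zip(names, table.rank_sums)),
    ]
    if post is not None:
        lines.append(f"  post hoc critical difference CD = {post.CD:.4f}")
        for i in range(K):
            for j in range(i + 1, K):
                if post.decisions[i, j] != "not-significant":
                    rel = "better than" if post.decisions[i, j] == "better" else "worse than"
                    lines.append(
                        f"    {names[i]} {rel} {names[j]} (D = {post.D[i, j]:+.1f})"
                    )
    return "\n".join(lines) + "\n"
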