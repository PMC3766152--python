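"""Partition quality and comparison statistics.

Covers the statistics used to compare group configurations of the same
facilities: the Calinski--Harabasz pseudo-F (fit penalized by the number of
groups), a matched-membership agreement score between two partitions, the
adjusted Rand index for validation against planted structure, and the
K^N / K! estimate of the size of the partition search space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .clustering import ClusterSolution
from .data_model import InputError


def pseudo_f(r2: float, K: int, n: int) -> float:
    """Calinski--Harabasz pseudo-F: (r2/(K-1)) / ((1-r2)/(n-K)).

    Unlike r2, which only improves as K grows, pseudo-F penalizes extra
    groups, making it the fairer statistic for comparing partitions with
    different K.
    """
    if not 0.0 <= r2 < 1.0:
        raise InputError("pseudo-F requires 0 <= r2 < 1")
    if not 2 <= K < n:
        raise InputError(f"pseudo-F requires 2 <= K < n (got K={K}, n={n})")
    return (r2 / (K - 1)) / ((1.0 - r2) / (n - K))


@dataclass
class AgreementReport:
    """Agreement between two partitions restricted to common facilities."""

    common_facilities: int
    agreement_percent: float     # matched shared members / common facilities * 100
    exact_match_groups: int      # matched group pairs identical in membership
    matching: list[tuple[int, int]]  # (group in A, group in B), 1-based


def _as_label_map(sol) -> dict[str, int]:
    if isinstance(sol, ClusterSolution):
        return sol.assignments()
    return dict(sol)


def solution_agreement(sol_a, sol_b) -> AgreementReport:
    """Match groups across two partitions and score shared membership.

    Both arguments may be :class:`ClusterSolution` objects or mappings
    facility_id -> group label.  Facilities present in only one partition
    (e.g. hospitals that opened or closed between periods) are excluded
    before comparison.  Groups of A are paired with groups of B by
    maximum-weight bipartite matching on shared-member counts; the
    agreement percent is the fraction of common facilities lying in matched
    pairs, and a matched pair counts as an exact match when the two groups
    contain identical facility sets.
    """
    a, b = _as_label_map(sol_a), _as_label_map(sol_b)
    common = sorted(set(a) & set(b))
    if not common:
        raise InputError("partitions share no facilities")
    la = [a[f] for f in common]
    lb = [b[f] for f in common]
    ga = sorted(set(la), key=str)
    gb = sorted(set(lb), key=str)
    C = np.zeros((len(ga), len(gb)), dtype=int)
    for x, y in zip(la, lb):
        C[ga.index(x), gb.index(y)] += 1
    row, col = linear_sum_assignment(C, maximize=True)
    matched = int(C[row, col].sum())
    exact = 0
    matching = []
    for r, c in zip(row, col):
        if C[r, c] == 0:
            continue  # padding pair sharing nothing is not a match
        matching.append((r + 1, c + 1))
        size_a = la.count(ga[r])
        size_b = lb.count(gb[c])
        if C[r, c] == size_a == size_b:
            exact += 1
    return AgreementReport(
        common_facilities=len(common),
        agreement_percent=100.0 * matched / len(common),
        exact_match_groups=exact,
        matching=matching,
    )


def recovery_score(solution, planted_labels) -> float:
    """Adjusted Rand index between a solution and planted ground truth."""
    if isinstance(solution, ClusterSolution):
        labels = solution.labels
    else:
        labels = np.asarray(solution)
    planted = np.asarray(planted_labels)
    if labels.shape[0] != planted.shape[0]:
        raise InputError("label vectors differ in length")
    return float(adjusted_rand_score(planted, labels))


def partition_count_estimate(K: int, N: int) -> tuple[float, float]:
    """Approximate number of K-group partitions of N items, K^N / K!.

    Computed in log space (N*log10 K - log10 K!) so arbitrarily large
    counts are representable.  Returns (log10 of the count, mantissa
    rounded to one significant digit), so e.g. a result of
    9 x 10^203 comes back as (203.95..., 9.0).
    """
    if K < 1 or N < K:
        raise InputError("need 1 <= K <= N")
    log10_count = N * math.log10(K) - math.lgamma(K + 1) / math.log(10)
    mantissa = round(10 ** (log10_count - math.floor(log10_count)))
    if mantissa == 10:  # rounding carried into the next decade
        mantissa = 1
    # the matching power of ten is round(log10_count - log10(mantissa))
    return log10_count, float(mantissa)
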