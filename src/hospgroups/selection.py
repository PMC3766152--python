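"""Choosing the number of groups: incremental F and decision rules.

No statistic answers "how many clusters?" definitively, so the methodology
combines one — the incremental F statistic,

    incF_i = ((R2_i - R2_{i-1}) / (k_i - k_{i-1}))
             / ((1 - R2_i) / (n - (k_i - 1)))

which measures the fit gained by allowing one more group against the
residual unexplained variance per remaining degree of freedom — with
explicit, user-visible decision rules.  Candidate solutions are the strict
local maxima of incF over the consecutive K grid; the final K is then
picked by a three-step heuristic: (1) discard candidates whose largest
group exceeds ``max_group_size`` hospitals, (2) keep those with the fewest
single-hospital groups, (3) take the largest surviving K.

The rules are deliberately configuration, not constants: other
applications are expected to adjust them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterSolution
from .data_model import InputError


class SelectionError(RuntimeError):
    """No candidate solution survives the decision rules."""


@dataclass
class SelectionRules:
    """Decision rules for the final number of groups.

    ``max_group_size`` caps the number of underlying hospitals in any one
    group (default 20); ``minimize_single`` keeps only candidates with the
    fewest single-hospital groups; ties always resolve to the maximum K.
    """

    max_group_size: int = 20
    minimize_single: bool = True

    def __post_init__(self) -> None:
        if self.max_group_size < 1:
            raise InputError("max_group_size must be >= 1")


def incremental_f(r2_series: dict[int, float], n: int) -> dict[int, float]:
    """incF over a consecutive K grid that includes the K = 1 reference.

    ``r2_series`` maps K to R2, with R2(1) = 0 required so incF at the
    smallest clustered K is defined.  A K where R2 = 1 yields NaN (flagged
    as undefined; such points are excluded from the maxima search rather
    than clamped).
    """
    ks = sorted(r2_series)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise InputError(f"K grid {ks} is not consecutive")
    if ks[0] != 1:
        raise InputError("r2_series must include the K=1 reference (r2=0)")
    if n <= ks[-1]:
        raise InputError(f"n={n} must exceed the largest K={ks[-1]}")
    out: dict[int, float] = {}
    for prev_k, k in zip(ks, ks[1:]):
        r2, r2_prev = r2_series[k], r2_series[prev_k]
        if not (0.0 <= r2 <= 1.0):
            raise InputError(f"r2 at K={k} outside [0, 1]")
        if r2 >= 1.0:
            out[k] = float("nan")
            continue
        gain = (r2 - r2_prev) / (k - prev_k)
        resid = (1.0 - r2) / (n - (k - 1))
        out[k] = gain / resid
    return out


def find_candidates(
    incf_series: dict[int, float],
    solutions: dict[int, ClusterSolution],
    member_counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Strict local maxima of incF, annotated with solution shape.

    Returns a table with columns ``clusters`` (K), ``incF``, ``SH`` (number
    of single-hospital groups) and ``Max`` (largest group size in
    underlying hospitals).  Grid endpoints have no two-sided neighbour and
    are never candidates.  A merged tandem observation counts its
    ``member_count`` hospitals toward ``Max`` and is never counted in
    ``SH``.
    """
    ks = sorted(incf_series)
    if len(ks) < 3:
        raise InputError("need at least 3 consecutive K values to find local maxima")
    rows = []
    for prev_k, k, next_k in zip(ks, ks[1:], ks[2:]):
        f_prev, f, f_next = (incf_series[x] for x in (prev_k, k, next_k))
        if math.isnan(f):
            continue
        # strict inequality both sides; NaN neighbours never satisfy it
        if not (f > f_prev and f > f_next):
            continue
        sol = solutions[k]
        sizes = sol.group_sizes(member_counts)
        obs_per_group = np.bincount(sol.labels, minlength=sol.K)
        if member_counts is None:
            sh = int((sizes == 1).sum())
        else:
            single_obs = (obs_per_group == 1) & (sizes == 1)
            sh = int(single_obs.sum())
        rows.append({"clusters": k, "incF": f, "SH": sh, "Max": int(sizes.max())})
    return pd.DataFrame(rows, columns=["clusters", "incF", "SH", "Max"])


@dataclass
class SelectionAudit:
    """Full trail of the three-step heuristic, for transparency."""

    selected_k: int
    removed_step1: pd.DataFrame  # candidates with oversized groups
    removed_step2: pd.DataFrame  # candidates with excess single-hospital groups
    removed_step3: pd.DataFrame  # smaller-K survivors dropped by the tie rule
    survivors_step1: pd.DataFrame = field(repr=False, default=None)
    survivors_step2: pd.DataFrame = field(repr=False, default=None)


def select_k(candidates: pd.DataFrame, rules: SelectionRules | None = None) -> SelectionAudit:
    """Apply the three-step decision heuristic to a candidate table.

    Step 1 removes candidates whose largest group exceeds
    ``rules.max_group_size`` hospitals; step 2 keeps candidates with the
    minimum number of single-hospital groups; step 3 returns the maximum K
    among the survivors.  The result is order-invariant in the candidate
    rows.
    """
    if rules is None:
        rules = SelectionRules()
    if candidates.empty:
        raise SelectionError("candidate table is empty")
    cand = candidates.sort_values("clusters").reset_index(drop=True)

    oversized = cand["Max"] > rules.max_group_size
    step1 = cand[~oversized]
    if step1.empty:
        raise SelectionError(
            f"no candidate has all groups <= {rules.max_group_size} hospitals; "
            "consider relaxing max_group_size"
        )
    if rules.minimize_single:
        min_sh = step1["SH"].min()
        step2 = step1[step1["SH"] == min_sh]
    else:
        step2 = step1
    selected = int(step2["clusters"].max())
    return SelectionAudit(
        selected_k=selected,
        removed_step1=cand[oversized],
        removed_step2=step1[~step1.index.isin(step2.index)],
        removed_step3=step2[step2["clusters"] != selected],
        survivors_step1=step1,
        survivors_step2=step2,
    )


def candidate_table_from_sweep(
    solutions: list[ClusterSolution],
    n_hospitals: int | None = None,
    member_counts: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Convenience: incF series and candidate table from a sweep's output.

    ``n_hospitals`` is the number of underlying hospitals (sum of
    member_counts); defaults to the observation count.
    """
    by_k = {s.K: s for s in solutions}
    r2 = {k: by_k[k].r2 for k in by_k}
    if 1 not in r2:
        r2[1] = 0.0
    if member_counts is not None and n_hospitals is None:
        n_hospitals = int(np.asarray(member_counts).sum())
    if n_hospitals is None:
        n_hospitals = len(solutions[0].facilities)
    incf = incremental_f(r2, n_hospitals)
    return find_candidates(incf, by_k, member_counts=member_counts), incf


def write_candidate_table(candidates: pd.DataFrame, path, sep: str = ",") -> None:
    """Export with display rounding (incF to 2 decimals) per convention."""
    out = candidates.copy()
    out["incF"] = out["incF"].round(2)
    out.to_csv(path, sep=sep, index=False)
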