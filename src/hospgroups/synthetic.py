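"""Synthetic patient-flow regions for end-to-end testing.

Real statewide inpatient databases are not redistributable, so the test
bed is a generator that emulates their statistical shape: communities laid
out on a plane, facilities and areal units scattered within each
community, lognormal facility sizes, and integer patient-day flows drawn
from a gravity (Huff-type) allocation

    p(i | j)  ∝  S_i^alpha * exp(-beta * d_ij) * gamma^[same community]

so that each areal unit's demand concentrates on large, nearby,
same-community facilities.  The planted community label of every facility
is retained as ground truth for recovery experiments.

The defaults describe a strongly separated region — distinct communities
much farther apart than their internal spread — which is the regime the
grouping methodology targets; weak or absent structure is obtained by
setting ``beta=0, gamma=1, alpha=0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import DistanceMatrix, FacilityTable, InputError, UtilizationOD


@dataclass
class SyntheticConfig:
    """Parameters of the planted-community flow generator.

    Geometry is in kilometres; ``community_spacing`` is the distance
    between adjacent community centres (placed on a circle), and the
    facility/unit scatters are Gaussian within each community.  ``alpha``
    is the size-attraction exponent, ``beta`` the exponential
    distance-decay rate (per km), and ``gamma >= 1`` the extra affinity of
    a unit for its own community's facilities.
    """

    seed: int
    n_communities: int = 4
    facilities_per_community: int | tuple[int, int] = 4
    units_per_community: int | tuple[int, int] = 8
    community_spacing: float = 30.0
    facility_scatter: float = 4.0
    unit_scatter: float = 5.0
    bed_lognormal_mu: float = 5.0      # median ~150 beds
    bed_lognormal_sigma: float = 0.6
    alpha: float = 1.0
    beta: float = 0.15
    gamma: float = 5.0
    days_per_unit: float = 2500.0

    def __post_init__(self) -> None:
        if self.n_communities < 1:
            raise InputError("need at least one community")
        if self.beta < 0 or self.alpha < 0:
            raise InputError("alpha and beta must be >= 0")
        if self.gamma < 1:
            raise InputError("gamma must be >= 1")
        if self.community_spacing <= 0 and self.n_communities > 1:
            raise InputError("communities must have positive separation")


@dataclass
class SyntheticRegion:
    """A generated region: inputs for the pipeline plus ground truth."""

    config: SyntheticConfig
    facility_table: FacilityTable
    od: UtilizationOD
    dist: DistanceMatrix
    facility_coords: np.ndarray      # (n, 2)
    unit_coords: np.ndarray          # (z, 2)
    labels: np.ndarray               # (n,) planted community index per facility


def _count(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def generate_region(config: SyntheticConfig) -> SyntheticRegion:
    """Sample a region reproducibly from ``config.seed``.

    Community centres sit on a circle whose chord between neighbours is
    ``community_spacing``; a single community sits at the origin.  Each
    areal unit's total patient days are Poisson around ``days_per_unit``
    and split across facilities by a multinomial with gravity weights, so
    generated totals are conserved exactly and CI denominators behave like
    real counts.
    """
    rng = np.random.default_rng(config.seed)
    C = config.n_communities
    if C == 1:
        centers = np.zeros((1, 2))
    else:
        radius = config.community_spacing / (2.0 * np.sin(np.pi / C))
        angles = 2.0 * np.pi * np.arange(C) / C
        centers = radius * np.column_stack([np.cos(angles), np.sin(angles)])

    fac_coords, fac_labels = [], []
    unit_coords, unit_labels = [], []
    for c in range(C):
        nf = _count(rng, config.facilities_per_community)
        nu = _count(rng, config.units_per_community)
        fac_coords.append(centers[c] + rng.normal(0, config.facility_scatter, (nf, 2)))
        fac_labels += [c] * nf
        unit_coords.append(centers[c] + rng.normal(0, config.unit_scatter, (nu, 2)))
        unit_labels += [c] * nu
    fac_coords = np.vstack(fac_coords)
    unit_coords = np.vstack(unit_coords)
    fac_labels = np.array(fac_labels)
    unit_labels = np.array(unit_labels)
    n, z = len(fac_labels), len(unit_labels)

    # zero-padded ids keep lexicographic order equal to generation order
    fac_ids = [f"H{i:03d}" for i in range(n)]
    unit_ids = [f"U{j:03d}" for j in range(z)]

    beds = np.maximum(
        1, np.round(rng.lognormal(config.bed_lognormal_mu, config.bed_lognormal_sigma, n))
    ).astype(int)

    d_fu = cdist(unit_coords, fac_coords)            # (z, n)
    same = (unit_labels[:, None] == fac_labels[None, :]).astype(float)
    weights = (
        beds[None, :] ** config.alpha
        * np.exp(-config.beta * d_fu)
        * config.gamma ** same
    )
    probs = weights / weights.sum(axis=1, keepdims=True)

    counts = np.zeros((n, z))
    for j in range(z):
        total = rng.poisson(config.days_per_unit)
        counts[:, j] = rng.multinomial(total, probs[j])

    d_ff = cdist(fac_coords, fac_coords)
    d_ff = (d_ff + d_ff.T) / 2.0
    np.fill_diagonal(d_ff, 0.0)
    if n > 1 and d_ff.max() <= 0:
        raise InputError("degenerate geometry: all facilities coincide")

    table = FacilityTable(
        pd.DataFrame(
            {
                "facility_id": fac_ids,
                "name": [f"Hospital {i}" for i in range(n)],
                "member_count": 1,
                "beds": beds,
            }
        )
    )
    return SyntheticRegion(
        config=config,
        facility_table=table,
        od=UtilizationOD(facilities=fac_ids, units=unit_ids, counts=counts),
        dist=DistanceMatrix(facilities=fac_ids, d=d_ff),
        facility_coords=fac_coords,
        unit_coords=unit_coords,
        labels=fac_labels,
    )


# ---------------------------------------------------------------------------
# Published candidate-table fixture

#: The published worked example of the selection heuristic: 52 candidate
#: solutions (local maxima of incF) from a statewide run with 158
#: observations, with each candidate's incF, single-hospital group count
#: (SH) and largest group size (Max).  Transcribed from the printed table.
_CANDIDATE_ROWS = [
    (3, 94.81, 0, 91), (5, 81.11, 0, 60), (7, 33.59, 0, 61), (11, 14.88, 0, 51),
    (14, 7.93, 0, 48), (18, 6.59, 0, 45), (21, 9.38, 0, 36), (23, 6.52, 0, 36),
    (27, 6.02, 1, 24), (29, 3.56, 1, 17), (31, 3.52, 1, 17), (33, 4.11, 1, 17),
    (36, 4.35, 2, 17), (38, 4.39, 5, 17), (42, 4.05, 7, 17), (46, 4.12, 9, 16),
    (49, 3.92, 11, 16), (51, 3.71, 13, 12), (53, 3.61, 15, 12), (55, 3.53, 16, 12),
    (58, 4.02, 20, 12), (60, 3.97, 22, 12), (63, 4.02, 27, 12), (69, 4.25, 36, 12),
    (73, 4.61, 40, 12), (75, 4.43, 43, 12), (77, 4.13, 44, 9), (81, 4.38, 48, 8),
    (83, 4.17, 49, 7), (86, 4.29, 53, 7), (89, 3.77, 58, 7), (93, 3.83, 64, 7),
    (97, 4.14, 70, 7), (99, 4.37, 73, 7), (101, 4.72, 77, 7), (103, 5.22, 79, 7),
    (107, 4.94, 83, 7), (109, 3.77, 86, 7), (112, 3.79, 90, 7), (115, 3.84, 93, 7),
    (120, 3.41, 99, 7), (124, 3.08, 103, 5), (126, 2.52, 107, 5), (129, 2.44, 111, 5),
    (132, 2.39, 114, 5), (135, 2.10, 118, 5), (141, 1.91, 125, 5), (144, 1.91, 129, 4),
    (146, 1.87, 133, 4), (149, 1.99, 136, 3), (152, 1.88, 141, 3), (154, 1.92, 145, 3),
]


def transcribe_table1() -> pd.DataFrame:
    """The published 52-row candidate table (columns clusters, incF, SH, Max)."""
    return pd.DataFrame(_CANDIDATE_ROWS, columns=["clusters", "incF", "SH", "Max"])
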