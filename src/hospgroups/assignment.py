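"""Assigning a new or proposed facility to an existing group solution.

Rather than re-running the clustering with projected utilization (market
surveys are uncertain), a new facility is placed by geography alone: its
travel distances to the existing facilities are rescaled by the *original*
maximum pairwise distance, and the facility joins the group whose center
is nearest in the distance-block subspace,

    d_k = sqrt( sum_i (c_{k,i} - h_i)^2 )

where c_k is group k's center restricted to the distance columns and h is
the new facility's rescaled distance vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterSolution
from .data_model import InputError

logger = logging.getLogger(__name__)


@dataclass
class NewFacilityVector:
    """Rescaled distances from a new facility to each existing location.

    Ordered identically to the original distance matrix columns.  Entries
    may exceed 1 if the new facility lies farther out than the historical
    maximum pairwise distance.
    """

    facility_order: list[str]
    h: np.ndarray


def build_new_vector(
    raw_distances: np.ndarray, d_max: float, facility_order: list[str]
) -> NewFacilityVector:
    """Rescale raw distances by the original ``d_max`` (never recomputed)."""
    raw = np.asarray(raw_distances, dtype=float)
    if raw.ndim != 1 or raw.shape[0] != len(facility_order):
        raise InputError(
            f"distance vector has length {raw.shape[0] if raw.ndim == 1 else raw.shape}, "
            f"expected {len(facility_order)}"
        )
    if (raw < 0).any():
        raise InputError("distances must be non-negative")
    if d_max <= 0:
        raise InputError("d_max must be positive")
    h = raw / d_max
    if (h > 1).any():
        logger.info(
            "new facility lies beyond the historical maximum distance "
            "(max rescaled entry %.3f)", h.max()
        )
    return NewFacilityVector(facility_order=list(facility_order), h=h)


def assign_new_facility(
    solution: ClusterSolution, vec: NewFacilityVector, z: int
) -> tuple[int, np.ndarray]:
    """Nearest group center in the distance-block subspace.

    ``z`` is the width of the utilization block; the centers' columns
    ``z..m`` are the distance block.  Returns the winning 1-based group
    index and the full vector of d values for audit.  Exact ties go to the
    lowest group index.
    """
    if z < 0 or z >= solution.centers.shape[1]:
        raise InputError(f"utilization block width z={z} incompatible with centers")
    sub = solution.centers[:, z:]
    if sub.shape[1] != vec.h.shape[0]:
        raise InputError(
            f"distance block has {sub.shape[1]} columns but new-facility vector "
            f"has {vec.h.shape[0]} entries"
        )
    d = np.sqrt(((sub - vec.h[None, :]) ** 2).sum(axis=1))
    group = int(d.argmin())  # argmin resolves ties to the lowest index
    if (d == d[group]).sum() > 1:
        logger.info("tie in minimum d; assigned to lowest group index %d", group + 1)
    return group + 1, d
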