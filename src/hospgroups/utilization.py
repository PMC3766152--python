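"""Relevance and Commitment Index matrices from an OD patient-day matrix.

The Commitment Index ``CI[i, j] = Pd[i, j] / Pd[i]`` is the fraction of
facility *i*'s total patient days contributed by areal unit *j*: a
facility-centric, size-insensitive profile of where a hospital's patients
come from.  The Relevance Index ``RI[i, j] = Pd[i, j] / Pd[j]`` is the
fraction of unit *j*'s patient days supplied by facility *i*: a
community-centric measure of how much a unit depends on a facility.  Only
CI enters the clustering feature space; RI is provided for diagnostics and
comparison with legacy service-area methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import InputError, UtilizationOD


@dataclass
class CIMatrix:
    """Commitment Index: rows (facilities) sum to 1."""

    facilities: list[str]
    units: list[str]
    values: np.ndarray  # (n, z) in [0, 1]


@dataclass
class RIMatrix:
    """Relevance Index: columns (units) sum to <= 1 (1 when exhaustive)."""

    facilities: list[str]
    units: list[str]
    values: np.ndarray  # (n, z) in [0, 1]


def compute_ci(od: UtilizationOD) -> CIMatrix:
    """CI[i, j] = Pd[i, j] / Pd[i].

    Every facility must have at least one patient day (apply
    :func:`~hospgroups.data_model.drop_inactive` first).
    """
    totals = od.facility_totals()
    if (totals <= 0).any():
        zero = [f for f, t in zip(od.facilities, totals) if t <= 0]
        raise InputError(
            f"facilities with zero patient days: {zero}; run drop_inactive before compute_ci"
        )
    return CIMatrix(
        facilities=list(od.facilities),
        units=list(od.units),
        values=od.counts / totals[:, None],
    )


def compute_ri(od: UtilizationOD) -> RIMatrix:
    """RI[i, j] = Pd[i, j] / Pd[j]; a unit with no patient days gets zeros."""
    totals = od.unit_totals()
    safe = np.where(totals > 0, totals, 1.0)
    values = od.counts / safe[None, :]
    values[:, totals <= 0] = 0.0
    return RIMatrix(facilities=list(od.facilities), units=list(od.units), values=values)


def write_index_matrix(mat: CIMatrix | RIMatrix, path, sep: str = ",", decimals: int = 6) -> None:
    """Write an index matrix as delimited text (facility rows, unit columns)."""
    df = pd.DataFrame(mat.values, index=mat.facilities, columns=mat.units)
    df.round(decimals).to_csv(path, sep=sep)
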