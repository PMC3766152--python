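"""Domain types, file I/O, and pre-clustering normalization.

The pipeline consumes two inputs: a long-format origin--destination (OD)
table of patient days (facility, areal unit, count) and a square matrix of
inter-facility travel distances.  This module densifies the OD table into an
``n x z`` matrix, validates and symmetrizes the distance matrix, merges
facilities that report jointly ("tandem" reporters), and removes facilities
with no recorded utilization.

All orderings are fixed lexicographically so that every downstream result is
byte-for-byte reproducible from the same input files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative asymmetry above which a distance matrix is rejected rather than
#: silently averaged; road-network matrices are near- but rarely exactly
#: symmetric.
SYMMETRY_TOLERANCE = 1e-6


class InputError(ValueError):
    """Raised when an input file or table violates its contract."""


@dataclass
class FacilityTable:
    """Registry of facilities (observations) entering the clustering.

    ``member_count`` is the number of underlying facilities an observation
    represents: 1 for an ordinary hospital, >1 for a merged tandem-reporting
    group.  Merged observations are never counted as "single-facility"
    groups downstream, and contribute all their members to group sizes.
    """

    table: pd.DataFrame  # columns: facility_id, name, member_count, beds

    def __post_init__(self) -> None:
        required = {"facility_id", "member_count"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"facility table missing columns: {sorted(missing)}")
        if self.table["facility_id"].duplicated().any():
            dupes = self.table.loc[self.table["facility_id"].duplicated(), "facility_id"]
            raise InputError(f"duplicate facility ids: {sorted(set(dupes))}")
        if (self.table["member_count"] < 1).any():
            raise InputError("member_count must be >= 1")

    @classmethod
    def default(cls, facility_ids: Sequence[str]) -> "FacilityTable":
        """A registry of plain single-member facilities."""
        return cls(
            pd.DataFrame(
                {
                    "facility_id": list(facility_ids),
                    "name": list(facility_ids),
                    "member_count": 1,
                    "beds": pd.array([pd.NA] * len(facility_ids), dtype="Int64"),
                }
            )
        )

    def member_counts(self, facility_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.table["facility_id"], self.table["member_count"]))
        try:
            return np.array([lookup[f] for f in facility_ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"facility {exc.args[0]!r} not in facility table") from exc


@dataclass
class UtilizationOD:
    """Facility x areal-unit matrix of patient-day counts.

    Row ``i`` holds the patient days used at facility ``i`` by residents of
    each areal unit; row sums give ``Pd_i`` (facility totals) and column
    sums give ``Pd_j`` (unit totals).
    """

    facilities: list[str]
    units: list[str]
    counts: np.ndarray  # shape (n, z), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, z = self.counts.shape
        if n != len(self.facilities) or z != len(self.units):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.facilities)} facilities x {len(self.units)} units"
            )
        if (self.counts < 0).any():
            raise InputError("patient-day counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.facilities)

    @property
    def z(self) -> int:
        return len(self.units)

    def facility_totals(self) -> np.ndarray:
        """Pd_i: total patient days at each facility."""
        return self.counts.sum(axis=1)

    def unit_totals(self) -> np.ndarray:
        """Pd_j: total patient days used by residents of each areal unit."""
        return self.counts.sum(axis=0)


@dataclass
class DistanceMatrix:
    """Square inter-facility travel-distance matrix (e.g. road km)."""

    facilities: list[str]
    d: np.ndarray  # shape (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.facilities)
        if self.d.shape != (n, n):
            raise InputError(f"distance matrix shape {self.d.shape}, expected ({n}, {n})")
        if (self.d < 0).any():
            raise InputError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-9, rtol=0):
            raise InputError("distance matrix not symmetric within 1e-9")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise InputError("distance matrix diagonal must be zero")


# ---------------------------------------------------------------------------
# Readers / writers


def read_od_long(
    path,
    dialect: dict[str, str] | None = None,
    sep: str = ",",
) -> UtilizationOD:
    """Read a long-format OD file into a dense :class:`UtilizationOD`.

    The file must contain columns ``facility_id``, ``unit_id`` and
    ``patient_days`` (remappable through ``dialect``, e.g.
    ``{"facility_id": "hosp"}``).  Duplicate (facility, unit) rows are
    summed; unobserved pairs become zeros; facilities and units are ordered
    lexicographically.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    required = ["facility_id", "unit_id", "patient_days"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    if df.empty:
        raise InputError(f"{path}: no data rows")
    days = pd.to_numeric(df["patient_days"], errors="coerce")
    bad = days.isna() | (days < 0)
    if bad.any():
        # +2: header line plus 1-based indexing
        rows = [int(i) + 2 for i in df.index[bad][:5]]
        raise InputError(f"{path}: negative or non-numeric patient_days at file row(s) {rows}")
    df = df.assign(patient_days=days)
    wide = (
        df.groupby(["facility_id", "unit_id"], sort=True)["patient_days"]
        .sum()
        .unstack(fill_value=0.0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return UtilizationOD(
        facilities=[str(f) for f in wide.index],
        units=[str(u) for u in wide.columns],
        counts=wide.to_numpy(dtype=float),
    )


def write_od_long(od: UtilizationOD, path, sep: str = ",") -> None:
    """Write the OD matrix back to long format (zero cells omitted)."""
    i, j = np.nonzero(od.counts)
    pd.DataFrame(
        {
            "facility_id": [od.facilities[a] for a in i],
            "unit_id": [od.units[b] for b in j],
            "patient_days": od.counts[i, j],
        }
    ).to_csv(path, sep=sep, index=False)


def read_distance_matrix(path, sep: str = ",") -> DistanceMatrix:
    """Read a square labelled distance matrix.

    Asymmetries up to ``SYMMETRY_TOLERANCE`` (relative to the largest entry)
    are averaged away; larger ones are rejected.  A nonzero diagonal is reset
    to zero with a warning.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise InputError(f"{path}: matrix is {df.shape[0]} x {df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise InputError(f"{path}: row and column facility ids differ")
    order = sorted(df.index)
    df = df.loc[order, order]
    d = df.to_numpy(dtype=float)
    scale = np.abs(d).max()
    if scale > 0:
        rel_asym = np.abs(d - d.T).max() / scale
        if rel_asym > SYMMETRY_TOLERANCE:
            raise InputError(
                f"{path}: matrix asymmetric (max relative asymmetry {rel_asym:.3g} "
                f"> {SYMMETRY_TOLERANCE:g})"
            )
    d = (d + d.T) / 2.0
    if np.abs(np.diag(d)).max() > 0:
        logger.warning("%s: nonzero diagonal reset to 0", path)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(facilities=list(order), d=d)


def write_distance_matrix(dist: DistanceMatrix, path, sep: str = ",") -> None:
    pd.DataFrame(dist.d, index=dist.facilities, columns=dist.facilities).to_csv(path, sep=sep)


def read_facility_registry(path, sep: str = ",") -> tuple[FacilityTable, list[set[str]]]:
    """Read a facility registry with optional tandem-reporting labels.

    Returns the registry and the list of tandem groups (sets of facility ids
    sharing a non-empty ``tandem_group`` label).
    """
    df = pd.read_csv(path, sep=sep, dtype={"facility_id": str})
    if "facility_id" not in df.columns:
        raise InputError(f"{path}: missing facility_id column")
    if "name" not in df.columns:
        df["name"] = df["facility_id"]
    if "beds" not in df.columns:
        df["beds"] = pd.NA
    df["member_count"] = 1
    groups: list[set[str]] = []
    if "tandem_group" in df.columns:
        labelled = df[df["tandem_group"].notna() & (df["tandem_group"].astype(str) != "")]
        for _, members in labelled.groupby("tandem_group")["facility_id"]:
            if len(members) > 1:
                groups.append(set(members))
    table = FacilityTable(
        df[["facility_id", "name", "member_count", "beds"]].reset_index(drop=True)
    )
    return table, groups


# ---------------------------------------------------------------------------
# Normalization


def merge_tandem_facilities(
    od: UtilizationOD,
    dist: DistanceMatrix,
    groups: Iterable[Iterable[str]],
    registry: FacilityTable | None = None,
) -> tuple[UtilizationOD, DistanceMatrix, FacilityTable]:
    """Merge facilities that report their utilization jointly.

    Each group becomes a single observation: its OD row is the element-wise
    *sum* of member rows (patient days are conserved), while its distance
    row/column is the element-wise *mean* of member rows (the members sit at
    distinct locations, so their distances are averaged); the merged
    self-distance is forced to 0.  The returned :class:`FacilityTable`
    records ``member_count`` so a merged observation is never treated as a
    single facility downstream.
    """
    if od.facilities != dist.facilities:
        raise InputError("OD and distance facility orderings differ")
    groups = [sorted(set(g)) for g in groups]
    flat = [f for g in groups for f in g]
    if len(flat) != len(set(flat)):
        raise InputError("tandem groups overlap")
    idx = {f: i for i, f in enumerate(od.facilities)}
    for g in groups:
        for f in g:
            if f not in idx:
                raise InputError(f"tandem member {f!r} not among facilities")

    merged_of = {}  # original facility id -> merged observation id
    for g in groups:
        gid = "+".join(g)
        for f in g:
            merged_of[f] = gid

    new_ids = sorted({merged_of.get(f, f) for f in od.facilities})
    members_of = {gid: [f] for f, gid in zip(od.facilities, od.facilities) if f not in merged_of}
    for g in groups:
        members_of["+".join(g)] = g

    n_new = len(new_ids)
    counts = np.zeros((n_new, od.z))
    d_new = np.zeros((n_new, n_new))
    for a, ida in enumerate(new_ids):
        rows = [idx[f] for f in members_of[ida]]
        counts[a] = od.counts[rows].sum(axis=0)
        for b, idb in enumerate(new_ids):
            if a == b:
                continue
            cols = [idx[f] for f in members_of[idb]]
            d_new[a, b] = dist.d[np.ix_(rows, cols)].mean()
    d_new = (d_new + d_new.T) / 2.0  # exact symmetry despite float summation order

    name_of = {}
    beds_of = {}
    if registry is not None:
        name_of = dict(zip(registry.table["facility_id"], registry.table["name"]))
        if "beds" in registry.table.columns:
            beds_of = dict(zip(registry.table["facility_id"], registry.table["beds"]))
    rows = []
    for ida in new_ids:
        members = members_of[ida]
        rows.append(
            {
                "facility_id": ida,
                "name": " + ".join(str(name_of.get(f, f)) for f in members),
                "member_count": len(members),
                "beds": _sum_beds(beds_of.get(f) for f in members),
            }
        )
    table = FacilityTable(pd.DataFrame(rows))
    return (
        UtilizationOD(facilities=new_ids, units=list(od.units), counts=counts),
        DistanceMatrix(facilities=new_ids, d=d_new),
        table,
    )


def _sum_beds(values):
    vals = [v for v in values if v is not None and not pd.isna(v)]
    return int(sum(vals)) if vals else pd.NA


def drop_inactive(od: UtilizationOD) -> tuple[UtilizationOD, list[str]]:
    """Remove facilities with zero total patient days.

    Areal-unit columns with zero totals are retained: they become constant
    zero CI columns, which are harmless for clustering but preserve the
    stated unit dimension.
    """
    totals = od.facility_totals()
    keep = totals > 0
    dropped = [f for f, k in zip(od.facilities, keep) if not k]
    if not keep.any():
        raise InputError("all facilities have zero patient days")
    for f in dropped:
        logger.warning("facility %s has no patient days; removed before clustering", f)
    if not dropped:
        return od, []
    return (
        UtilizationOD(
            facilities=[f for f, k in zip(od.facilities, keep) if k],
            units=list(od.units),
            counts=od.counts[keep],
        ),
        dropped,
    )
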