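"""Clustering feature space: CI block joined with rescaled distances.

Each facility is represented by ``m = z + p`` attributes: its ``z``
Commitment-Index values and its ``p`` travel distances to facility
locations, rescaled to [0, 1] by the maximum pairwise distance.  Both
blocks then live on comparable [0, 1] scales, and the distance block gives
every facility an n-dimensional representation of location that respects
the actual travel network (unlike raw x,y coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DistanceMatrix, InputError
from .utilization import CIMatrix


@dataclass
class FeatureMatrix:
    """n facilities x (z utilization + p distance) attribute matrix.

    ``d_max`` is the maximum pairwise distance used for rescaling, kept in
    original units so that a *new* facility's distance vector can later be
    rescaled identically.
    """

    facilities: list[str]
    units: list[str]                # labels of the utilization columns
    distance_columns: list[str]     # labels of the distance columns
    values: np.ndarray              # (n, z + p)
    d_max: float                    # original-unit rescaling constant
    distance_weight: float = 1.0

    @property
    def n(self) -> int:
        return len(self.facilities)

    @property
    def z(self) -> int:
        return len(self.units)

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def utilization_block(self) -> np.ndarray:
        return self.values[:, : self.z]

    def distance_block(self) -> np.ndarray:
        return self.values[:, self.z :]


def rescale_distances(dist: DistanceMatrix) -> tuple[np.ndarray, float]:
    """Divide every entry by the maximum pairwise distance.

    Returns the rescaled matrix (entries in [0, 1], at least one entry
    exactly 1) and ``d_max`` for later use in new-facility assignment.
    """
    if len(dist.facilities) < 2:
        raise InputError("need at least two facilities to rescale distances")
    d_max = float(dist.d.max())
    if d_max <= 0:
        raise InputError("all distances are zero; cannot rescale")
    return dist.d / d_max, d_max


def build_features(
    ci: CIMatrix,
    rescaled: np.ndarray,
    d_max: float,
    distance_columns: list[str] | None = None,
    distance_weight: float = 1.0,
) -> FeatureMatrix:
    """Join the CI block and the rescaled distance block column-wise.

    ``rescaled`` has one row per facility (same ordering as ``ci``) and one
    column per facility *location*; the column count may exceed the row
    count when merged observations keep distances to all underlying
    locations.  ``distance_weight`` (default 1.0) optionally scales the
    distance block for sensitivity analysis; the methodology itself uses
    the unweighted join.
    """
    rescaled = np.asarray(rescaled, dtype=float)
    if rescaled.ndim != 2 or rescaled.shape[0] != len(ci.facilities):
        raise InputError(
            f"distance block has {rescaled.shape[0]} rows but CI has "
            f"{len(ci.facilities)} facilities; orderings must match"
        )
    if distance_columns is None:
        distance_columns = [f"d:{i}" for i in range(rescaled.shape[1])]
    if len(distance_columns) != rescaled.shape[1]:
        raise InputError("distance column labels do not match block width")
    values = np.hstack([ci.values, distance_weight * rescaled])
    return FeatureMatrix(
        facilities=list(ci.facilities),
        units=list(ci.units),
        distance_columns=list(distance_columns),
        values=values,
        d_max=float(d_max),
        distance_weight=float(distance_weight),
    )


def features_from(ci: CIMatrix, dist: DistanceMatrix, distance_weight: float = 1.0) -> FeatureMatrix:
    """Convenience: rescale ``dist`` and join with ``ci`` in one call."""
    if ci.facilities != dist.facilities:
        raise InputError("CI and distance facility orderings differ")
    rescaled, d_max = rescale_distances(dist)
    return build_features(
        ci, rescaled, d_max, distance_columns=list(dist.facilities), distance_weight=distance_weight
    )


def write_features(fm: FeatureMatrix, path, sep: str = ",") -> None:
    """Export with a two-row header: block label, then column id."""
    blocks = ["utilization"] * fm.z + ["distance"] * (fm.m - fm.z)
    cols = pd.MultiIndex.from_arrays([blocks, list(fm.units) + list(fm.distance_columns)])
    pd.DataFrame(fm.values, index=fm.facilities, columns=cols).to_csv(path, sep=sep)
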