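"""Annual region×region connectivity matrices and their temporal statistics.

``C[i, j]`` is the probability that a larva spawned in source region *i*
(row) settles into sink region *j* (column): summed settled weights divided
by the total number of particles released from *i* — mortality therefore
depresses the probabilities (a "conditional on settlement attempt" mode
normalizing by surviving weight is available). Regions are ordered by
latitude rank, north to south; the diagonal is larval retention. A stack of
annual matrices yields the elementwise mean, the coefficient of variation
(sample s.d. / mean; undefined where the mean is zero) and signed annual
anomaly matrices relative to the stack mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ocean import Domain
from .tracking import ReleaseSchedule
from .biology import SettlementRecord

__all__ = [
    "ConnectivityMatrix",
    "ConnectivityStack",
    "build_connectivity_matrix",
    "mean_connectivity",
    "cv_connectivity",
    "anomaly_matrices",
]


@dataclass
class ConnectivityMatrix:
    """One season's region×region spawn-to-settlement probabilities."""

    year: int
    values: np.ndarray  # (R, R); NaN rows where no particles were released
    region_ids: list[int]  # in latitude-rank (north→south) order
    region_names: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.region_ids):
            raise ValueError("values must be R×R matching region_ids")
        self.values = v

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def retention(self) -> np.ndarray:
        return np.diag(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        labels = self.region_names or self.region_ids
        return pd.DataFrame(self.values, index=labels, columns=labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, year: int, region_ids: list[int]) -> "ConnectivityMatrix":
        return cls(
            year=year,
            values=df.to_numpy(dtype=float),
            region_ids=list(region_ids),
            region_names=[str(c) for c in df.columns],
        )


def build_connectivity_matrix(
    settlements,
    schedule: ReleaseSchedule,
    domain: Domain,
    year: int = 0,
    conditional_on_settlement: bool = False,
) -> ConnectivityMatrix:
    """Aggregate particle-level settlement records into a probability matrix.

    ``settlements`` is either the DataFrame from
    :func:`reefdrift.biology.settlements_from_tracks` or an iterable of
    :class:`~reefdrift.biology.SettlementRecord`. The denominator is the
    number of particles released from each source region; regions that
    released nothing get a NaN (masked) row. With
    ``conditional_on_settlement=True`` the denominator is instead the summed
    settled weight of the row, giving sink proportions among settlers.
    """
    regions = domain.regions_by_rank()
    rid_to_pos = {r.region_id: i for i, r in enumerate(regions)}
    R = len(regions)
    weights = np.zeros((R, R))
    if isinstance(settlements, pd.DataFrame):
        src = settlements["source_region_id"].to_numpy()
        snk = settlements["sink_region_id"].to_numpy()
        w = settlements["weight"].to_numpy(dtype=float)
    else:
        recs: list[SettlementRecord] = list(settlements)
        src = np.array([r.source_region_id for r in recs], dtype=np.int64)
        snk = np.array([r.sink_region_id for r in recs], dtype=np.int64)
        w = np.array([r.weight for r in recs], dtype=float)
    for rid in np.union1d(src, snk) if src.size else []:
        if int(rid) not in rid_to_pos:
            raise KeyError(f"settlement references unknown region {rid}")
    if src.size:
        i = np.array([rid_to_pos[int(r)] for r in src])
        j = np.array([rid_to_pos[int(r)] for r in snk])
        np.add.at(weights, (i, j), w)

    released = schedule.region_release_totals(domain)
    denom = np.array([released.get(r.region_id, 0) for r in regions], dtype=float)
    if conditional_on_settlement:
        denom = weights.sum(axis=1)
    values = np.full((R, R), np.nan)
    ok = denom > 0
    values[ok] = weights[ok] / denom[ok, None]
    return ConnectivityMatrix(
        year=year,
        values=values,
        region_ids=[r.region_id for r in regions],
        region_names=[r.name for r in regions],
    )


@dataclass
class ConnectivityStack:
    """Ordered annual matrices sharing one region ordering."""

    matrices: list[ConnectivityMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("stack needs at least one matrix")
        ids0 = self.matrices[0].region_ids
        for m in self.matrices[1:]:
            if m.region_ids != ids0:
                raise ValueError("all matrices must share region ordering and dimension")

    @property
    def years(self) -> list[int]:
        return [m.year for m in self.matrices]

    @property
    def region_ids(self) -> list[int]:
        return self.matrices[0].region_ids

    def as_array(self) -> np.ndarray:
        return np.stack([m.values for m in self.matrices])


def mean_connectivity(stack: ConnectivityStack) -> np.ndarray:
    """Elementwise arithmetic mean over years (NaN-masked cells ignored)."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack.as_array(), axis=0)


def cv_connectivity(stack: ConnectivityStack) -> np.ndarray:
    """Per-cell coefficient of variation: sample s.d. (n−1) over mean.

    Cells whose mean connectivity is zero (never-realized connections) are
    undefined and returned as NaN, not 0 or ∞. Requires ≥ 2 years.
    """
    arr = stack.as_array()
    if arr.shape[0] < 2:
        raise ValueError("CV needs at least two years")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return cv


def anomaly_matrices(stack: ConnectivityStack) -> tuple[np.ndarray, np.ndarray]:
    """Signed annual anomalies (year − stack mean) and their sign classes.

    Returns ``(anomalies, signs)`` with shape (n_years, R, R); signs are
    +1 / −1 / 0. Per cell, anomalies sum to zero across years (up to
    rounding). Requires ≥ 2 years.
    """
    arr = stack.as_array()
    if arr.shape[0] < 2:
        raise ValueError("anomalies need at least two years")
    mean = np.nanmean(arr, axis=0)
    anom = arr - mean[None]
    # rounding guard: an anomaly at float-epsilon scale is a zero, not a sign
    tol = 1e-12 * max(float(np.nanmax(np.abs(arr), initial=0.0)), 1e-300)
    signs = np.where(np.abs(anom) <= tol, 0.0, np.sign(anom))
    return anom, signs
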