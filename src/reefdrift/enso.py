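"""ENSO linkage of connectivity: directional decomposition and regressions.

Every ordered region pair is classified by transport direction in the
Southern-Hemisphere convention (y increases northward, latitude rank
increases southward):

* same region → ``retention``;
* offshore source → inshore sink → ``across_shelf`` (Coral-Sea-intrusion
  style transport, any latitude);
* inshore source → offshore sink → ``inshore_to_offshore`` (reported but not
  one of the three headline metrics);
* same band, sink further south (higher rank) → ``poleward``; sink further
  north → ``equatorward``.

Annual directional means (averaged over central+southern source regions,
minus a configurable southernmost exclusion set) are regressed on the
yearly SOI mean: linear for poleward and equatorward connectivity,
quadratic for the U-shaped across-shelf response. The temporal-variability
relationship (mean connectivity vs its coefficient of variation) is fitted
as an exponential decay ``mean = a·exp(−b·CV)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ocean import ClimateIndexSeries, Domain
from .connectivity import ConnectivityMatrix

__all__ = [
    "DIRECTION_CLASSES",
    "yearly_mean_index",
    "classify_direction",
    "direction_class_matrix",
    "DirectionalSummary",
    "directional_summary",
    "RegressionResult",
    "regress_on_index",
    "fit_mean_vs_cv_decay",
    "default_excluded_regions",
]

DIRECTION_CLASSES = (
    "retention",
    "poleward",
    "equatorward",
    "across_shelf",
    "inshore_to_offshore",
)


def yearly_mean_index(series: ClimateIndexSeries, year: int) -> float:
    """Arithmetic mean of the season's four monthly index values."""
    return series.yearly_mean(year)


def classify_direction(source_region, sink_region) -> str:
    """Direction class of transport from ``source_region`` to ``sink_region``."""
    if source_region.region_id == sink_region.region_id:
        return "retention"
    if source_region.band == "offshore" and sink_region.band == "inshore":
        return "across_shelf"
    if source_region.band == "inshore" and sink_region.band == "offshore":
        return "inshore_to_offshore"
    if sink_region.latitude_rank > source_region.latitude_rank:
        return "poleward"
    return "equatorward"


def direction_class_matrix(domain: Domain) -> np.ndarray:
    """R×R array of direction-class indices in latitude-rank order."""
    regions = domain.regions_by_rank()
    R = len(regions)
    out = np.empty((R, R), dtype=np.int8)
    for i, ri in enumerate(regions):
        for j, rj in enumerate(regions):
            out[i, j] = DIRECTION_CLASSES.index(classify_direction(ri, rj))
    return out


def default_excluded_regions(domain: Domain, n: int = 2) -> set[int]:
    """The ``n`` southernmost regions (highest latitude rank), excluded from
    the SOI relationship because their dispersal directionality differs."""
    ranked = domain.regions_by_rank()
    return {r.region_id for r in ranked[-n:]}


@dataclass
class DirectionalSummary:
    """One season's directional connectivity summary."""

    year: int
    mean_poleward: float
    mean_equatorward: float
    mean_across_shelf: float
    poleward_fraction_pct: float  # % of realized along-shelf connections
    equatorward_fraction_pct: float
    n_poleward_connections: int
    n_equatorward_connections: int
    source_sectors: tuple[str, ...]
    excluded_regions: tuple[int, ...]


def directional_summary(
    matrix: ConnectivityMatrix,
    domain: Domain,
    source_sectors: tuple[str, ...] = ("central", "southern"),
    excluded_regions: set[int] | None = None,
    nonzero_eps: float = 0.0,
) -> DirectionalSummary:
    """Directional means and along-shelf connection fractions for one season.

    Means average ``C[i, j]`` (zeros included) over the ordered pairs of each
    direction class whose *source* lies in ``source_sectors`` and outside
    ``excluded_regions``. The poleward fraction counts realized
    (> ``nonzero_eps``) poleward cells as a percentage of realized poleward
    plus equatorward cells; fractions are NaN when no along-shelf connection
    is realized.
    """
    if excluded_regions is None:
        excluded_regions = default_excluded_regions(domain)
    regions = domain.regions_by_rank()
    unknown = excluded_regions - {r.region_id for r in regions}
    if unknown:
        raise KeyError(f"excluded regions not in domain: {sorted(unknown)}")
    classes = direction_class_matrix(domain)
    src_ok = np.array(
        [r.sector in source_sectors and r.region_id not in excluded_regions for r in regions]
    )
    C = np.nan_to_num(matrix.values, nan=0.0)

    def class_mean(name: str) -> float:
        mask = (classes == DIRECTION_CLASSES.index(name)) & src_ok[:, None]
        return float(C[mask].mean()) if mask.any() else 0.0

    pol_mask = (classes == DIRECTION_CLASSES.index("poleward")) & src_ok[:, None]
    eq_mask = (classes == DIRECTION_CLASSES.index("equatorward")) & src_ok[:, None]
    n_pol = int((C[pol_mask] > nonzero_eps).sum())
    n_eq = int((C[eq_mask] > nonzero_eps).sum())
    total = n_pol + n_eq
    pol_pct = 100.0 * n_pol / total if total else float("nan")
    return DirectionalSummary(
        year=matrix.year,
        mean_poleward=class_mean("poleward"),
        mean_equatorward=class_mean("equatorward"),
        mean_across_shelf=class_mean("across_shelf"),
        poleward_fraction_pct=pol_pct,
        equatorward_fraction_pct=100.0 - pol_pct if total else float("nan"),
        n_poleward_connections=n_pol,
        n_equatorward_connections=n_eq,
        source_sectors=tuple(source_sectors),
        excluded_regions=tuple(sorted(excluded_regions)),
    )


@dataclass
class RegressionResult:
    form: str  # "linear" | "quadratic" | "exponential-decay"
    coefficients: tuple[float, ...]  # low order first: (a0, a1[, a2]) or (a, b)
    r2: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError(f"r² out of range: {self.r2}")
        if self.n < len(self.coefficients) + 1:
            raise ValueError("too few points for the model order")


def regress_on_index(
    yearly_values, yearly_index, form: str = "linear"
) -> RegressionResult:
    """OLS of an annual connectivity metric on the yearly index mean.

    ``form="linear"`` reports the two-sided slope p-value; ``"quadratic"``
    reports the model F-test p-value. r² = 1 − SS_res/SS_tot.
    """
    y = np.asarray(yearly_values, dtype=float)
    x = np.asarray(yearly_index, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("yearly_values and yearly_index must be 1-d and aligned")
    if np.ptp(x) == 0:
        raise ValueError("index has zero variance")
    n = y.size
    order = {"linear": 1, "quadratic": 2}.get(form)
    if order is None:
        raise ValueError(f"unknown form {form!r}")
    if n < order + 2:
        raise ValueError(f"{form} fit needs at least {order + 2} points")
    X = np.vander(x, order + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = n - (order + 1)
    if form == "linear":
        sigma2 = ss_res / dof if dof > 0 else np.nan
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        tstat = beta[1] / se if se > 0 else np.inf
        p = 2 * stats.t.sf(abs(tstat), dof)
    else:
        ss_reg = ss_tot - ss_res
        f = (ss_reg / order) / (ss_res / dof) if ss_res > 0 else np.inf
        p = stats.f.sf(f, order, dof)
    return RegressionResult(
        form=form, coefficients=tuple(float(b) for b in beta),
        r2=max(0.0, min(1.0, r2)), p_value=float(p), n=n,
    )


def fit_mean_vs_cv_decay(mean_values, cv_values) -> RegressionResult:
    """Fit mean connectivity = a·exp(−b·CV) by nonlinear least squares.

    Pairs with NaN in either variable or non-positive mean are dropped. The
    initializer is the log-linear fit ln(mean) = ln(a) − b·CV; r² is
    reported on the original (untransformed) scale, with a large-sample
    normal test on b for the p-value.
    """
    m = np.asarray(mean_values, dtype=float).ravel()
    c = np.asarray(cv_values, dtype=float).ravel()
    ok = np.isfinite(m) & np.isfinite(c) & (m > 0)
    m, c = m[ok], c[ok]
    if m.size < 3:
        raise ValueError("need at least 3 valid (mean, CV) pairs")
    slope, intercept = np.polyfit(c, np.log(m), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, a, b: a * np.exp(-b * x), c, m, p0=p0, maxfev=10000
        )
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((2, 2), np.nan)
    pred = popt[0] * np.exp(-popt[1] * c)
    ss_res = float(((m - pred) ** 2).sum())
    ss_tot = float(((m - m.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    se_b = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    if np.isfinite(se_b) and se_b > 0:
        z = popt[1] / se_b
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = float("nan")
    return RegressionResult(
        form="exponential-decay",
        coefficients=(float(popt[0]), float(popt[1])),
        r2=max(0.0, min(1.0, r2)),
        p_value=float(p),
        n=int(m.size),
    )
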