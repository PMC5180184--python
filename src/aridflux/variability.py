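"""Trend/anomaly decomposition and aridity-class variance accounting.

Per-cell OLS detrending of annual cubes, interannual-variability maps,
additive per-class contributions to the global detrended variability
(covariance projection onto the global anomaly series) and to the global
trend (slope shares), plus binned-curve summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .budyko import AridityClassMap
from .errors import ValidationError
from .grid import GriddedCube, GridField, area_weights

__all__ = [
    "AnomalyDecomposition",
    "DecompositionResult",
    "decompose_trend",
    "integrate_by_class",
    "regional_contribution_iav",
    "regional_contribution_trend",
    "bin_by_aridity",
    "bin_by_value",
    "BinnedCurve",
]


@dataclass
class AnomalyDecomposition:
    """Per-cell linear trend plus detrended anomalies of an annual cube."""

    slope: GridField            # units yr-1
    intercept: GridField
    anomalies: GriddedCube      # residuals, same units as input
    iav_detrended: GridField    # population s.d. of residuals
    iav_raw: GridField          # population s.d. of the raw annual values
    iav_kind: str = "detrended"


def decompose_trend(cube: GriddedCube, ddof: int = 0) -> AnomalyDecomposition:
    """OLS linear fit against calendar year, per cell.

    Returns the slope/intercept maps, the residual (anomaly) cube, and
    both IAV maps: s.d. of residuals and s.d. of the raw values
    (population s.d. by default; ``ddof=1`` for the sample version).
    """
    if cube.freq != "annual":
        raise ValidationError("decompose_trend expects an annual cube")
    t = cube.time.astype(float)
    if t.size < 3:
        raise ValidationError("need at least 3 years to decompose")
    if np.allclose(t, t[0]):
        raise ValidationError("constant time axis")
    tc = t - t.mean()
    denom = np.sum(tc**2)
    x = cube.values
    xm = x.mean(axis=0)
    slope = np.tensordot(tc, x - xm, axes=(0, 0)) / denom
    fitted = xm[None] + tc[:, None, None] * slope[None]
    resid = x - fitted
    intercept = xm - slope * t.mean()
    g, m, u = cube.grid, cube.mask, cube.units
    return AnomalyDecomposition(
        slope=GridField(g, slope, units=f"({u}) yr-1", mask=m, name="trend_slope"),
        intercept=GridField(g, intercept, units=u, mask=m, name="trend_intercept"),
        anomalies=GriddedCube(g, resid, cube.time, freq="annual", units=u,
                              mask=m, name=f"{cube.name}_anomaly"),
        iav_detrended=GridField(g, resid.std(axis=0, ddof=ddof), units=u, mask=m,
                                name="iav_detrended"),
        iav_raw=GridField(g, x.std(axis=0, ddof=ddof), units=u, mask=m, name="iav_raw"),
    )


@dataclass
class DecompositionResult:
    """Per-class contributions to global detrended IAV and to the trend."""

    class_names: tuple[str, ...]
    iav_contributions: np.ndarray      # fractions, sum to 1
    trend_contributions: np.ndarray    # fractions, sum to 1
    class_areas: np.ndarray            # fractions of land, sum to 1
    global_anomaly_series: np.ndarray  # area-integrated (scaled by earth_area)
    years: np.ndarray
    iav_variance_shares: np.ndarray | None = None  # var_j / sum var_k alternative


def integrate_by_class(
    cube: GriddedCube,
    classes: AridityClassMap,
    weights: GridField | None = None,
    earth_area: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-integrate a cube to one series per class.

    Returns ``(series, areas)`` where ``series`` is (n_classes, n_time),
    each entry ``sum_cells value * weight * earth_area`` over the cells of
    the class, and ``areas`` the class area fractions of the common mask.
    """
    if weights is None:
        weights = area_weights(cube.grid)
    mask = cube.mask & classes.mask
    K = len(classes.class_names)
    series = np.zeros((K, cube.time.size))
    areas = np.zeros(K)
    wtot = weights.values[mask].sum()
    for k in range(K):
        sel = mask & (classes.labels == k)
        areas[k] = weights.values[sel].sum() / wtot if wtot > 0 else 0.0
        if sel.any():
            series[k] = np.tensordot(
                cube.values, np.where(sel, weights.values, 0.0), axes=([1, 2], [0, 1])
            ) * earth_area
    return series, areas


def contribution_fractions(class_series: np.ndarray) -> np.ndarray:
    """Covariance projection of class series onto their sum.

    f_j = sum_t x_{j,t} X_t / sum_t X_t^2 with X = sum_j x_j; exactly
    additive (sums to 1) for any partition, and reducing to variance
    shares when the class series are mutually uncorrelated.
    """
    X = class_series.sum(axis=0)
    denom = float(np.sum(X**2))
    if denom <= 0:
        raise ValidationError("global anomaly series is identically zero")
    return class_series @ X / denom


def regional_contribution_iav(
    anomalies: GriddedCube,
    classes: AridityClassMap,
    weights: GridField | None = None,
    earth_area: float = 1.0,
) -> DecompositionResult:
    """Per-class fractional contributions to the global detrended IAV.

    The anomaly cube is area-integrated to one series per class; each
    class's fraction is the projection of its series onto the global sum
    (see :func:`contribution_fractions`). The simple variance-share
    alternative is reported alongside.
    """
    series, areas = integrate_by_class(anomalies, classes, weights, earth_area)
    fractions = contribution_fractions(series)
    var = series.var(axis=1)
    var_shares = var / var.sum() if var.sum() > 0 else np.full_like(var, np.nan)
    return DecompositionResult(
        class_names=classes.class_names,
        iav_contributions=fractions,
        trend_contributions=_trend_fractions(series, anomalies.time),
        class_areas=areas,
        global_anomaly_series=series.sum(axis=0),
        years=anomalies.time.copy(),
        iav_variance_shares=var_shares,
    )


def _trend_fractions(class_series: np.ndarray, years: np.ndarray) -> np.ndarray:
    t = years.astype(float)
    tc = t - t.mean()
    denom = np.sum(tc**2)
    slopes = class_series @ tc / denom
    total = slopes.sum()
    if total == 0:
        return np.full(class_series.shape[0], np.nan)
    return slopes / total


def regional_contribution_trend(class_series: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Trend share of each class: OLS slope of its integrated series
    divided by the global slope (= sum of class slopes, by linearity)."""
    years = np.asarray(years, dtype=float)
    if years.size < 3:
        raise ValidationError("need at least 3 years")
    out = _trend_fractions(np.asarray(class_series, dtype=float), years)
    if np.any(np.isnan(out)):
        raise ValidationError("global trend is zero; fractions undefined")
    return out


@dataclass
class BinnedCurve:
    """Area-weighted mean/s.d. of a field per bin of a companion field."""

    edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray
    flagged: np.ndarray  # True where a bin has < min_count cells

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _binned(values, by, w, edges, min_count):
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    idx = np.digitize(by, edges) - 1
    for b in range(nb):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b] == 0:
            continue
        wb = w[sel] / w[sel].sum()
        mean[b] = np.sum(wb * values[sel])
        sd[b] = np.sqrt(np.sum(wb * (values[sel] - mean[b]) ** 2))
    return BinnedCurve(np.asarray(edges, dtype=float), mean, sd, count, count < min_count)


def bin_by_aridity(
    value: GridField,
    ai: GridField,
    edges=None,
    weights: GridField | None = None,
    min_count: int = 10,
) -> BinnedCurve:
    """Area-weighted mean and s.d. of *value* within aridity-index bins
    (default bin width 0.01 over [0, 2])."""
    if edges is None:
        edges = np.arange(0.0, 2.0 + 1e-9, 0.01)
    return bin_by_value(value, ai, edges=np.asarray(edges), weights=weights,
                        min_count=min_count)


def bin_by_value(
    y: GridField,
    x: GridField,
    bin_width: float | None = None,
    edges=None,
    weights: GridField | None = None,
    min_count: int = 10,
) -> BinnedCurve:
    """Binned curve of y against x (bins from 0 in steps of *bin_width*
    unless explicit *edges* are given)."""
    if y.grid != x.grid:
        raise ValidationError("fields must share a grid")
    mask = y.mask & x.mask
    if not mask.any():
        raise ValidationError("empty overlap between the two fields")
    if weights is None:
        weights = area_weights(y.grid)
    if edges is None:
        if bin_width is None or bin_width <= 0:
            raise ValidationError("need a positive bin_width or explicit edges")
        top = float(np.nanmax(x.values[mask]))
        edges = np.arange(0.0, top + bin_width, bin_width)
        if edges[-1] <= top:
            edges = np.append(edges, edges[-1] + bin_width)
    return _binned(y.values[mask], x.values[mask], weights.values[mask],
                   np.asarray(edges, dtype=float), min_count)
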