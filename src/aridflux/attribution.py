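"""Climate attribution of GPP variability.

Partial correlations of annual GPP with precipitation, temperature and
shortwave radiation (each controlling the other two), GPP-ET coupling
(per-cell Pearson r and regression slope beta across one or more ET
products), the sigma_GPP = beta * sigma_ET decomposition, and the binned
coupling-versus-variability curves.

Partial correlation uses the residual method: correlate the OLS
residuals of y-on-controls and x-on-controls; the two-sided p-value
comes from the t distribution with N - 2 - k degrees of freedom for k
controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .grid import GriddedCube, GridField, area_weights
from .variability import BinnedCurve, bin_by_value, decompose_trend

__all__ = [
    "partial_correlation",
    "AttributionMaps",
    "climate_attribution",
    "CouplingResult",
    "gpp_et_coupling",
    "decompose_gpp_iav",
    "coupling_vs_iav_curves",
]


def partial_correlation(y, x, controls) -> tuple[float, float]:
    """Partial Pearson correlation of y and x given one or more controls.

    Parameters
    ----------
    y, x : 1-D arrays of equal length N
    controls : array of shape (k, N) or (N,) for a single control

    Returns ``(rho, p)``; ``(nan, nan)`` when y, x or a residual series is
    constant or the controls are collinear with either variable.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(controls, dtype=float))
    if C.shape[1] != y.size:
        C = C.T
    k, N = C.shape
    if y.size != N or x.size != N:
        raise ValidationError("series lengths differ")
    if N < k + 3:
        raise ValidationError(f"need at least {k + 3} points for {k} controls")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x)) and np.all(np.isfinite(C))):
        raise ValidationError("non-finite values in input series")
    design = np.column_stack([np.ones(N), C.T])
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    ry = y - design @ beta_y
    rx = x - design @ beta_x
    sy = np.sqrt(np.sum(ry**2))
    sx = np.sqrt(np.sum(rx**2))
    # relative floor: a constant (or control-collinear) series leaves only
    # rounding noise in the residual
    if sy <= 1e-10 * max(1.0, float(np.linalg.norm(y))) or \
            sx <= 1e-10 * max(1.0, float(np.linalg.norm(x))):
        return float("nan"), float("nan")
    rho = float(np.clip(np.sum(ry * rx) / (sy * sx), -1.0, 1.0))
    dof = N - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * np.sqrt(dof / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return rho, p


def _batched_partial_corr(Y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Vectorised residual-method partial correlation.

    Y, X: (ncell, N); C: (ncell, N, k). Returns (rho, p) arrays (ncell,).
    """
    ncell, N = Y.shape
    k = C.shape[2]
    design = np.concatenate([np.ones((ncell, N, 1)), C], axis=2)  # (ncell, N, k+1)
    gram = np.einsum("cnk,cnl->ckl", design, design)
    rhs_y = np.einsum("cnk,cn->ck", design, Y)
    rhs_x = np.einsum("cnk,cn->ck", design, X)
    with np.errstate(all="ignore"):
        beta_y = np.linalg.solve(gram, rhs_y[..., None])[..., 0]
        beta_x = np.linalg.solve(gram, rhs_x[..., None])[..., 0]
    ry = Y - np.einsum("cnk,ck->cn", design, beta_y)
    rx = X - np.einsum("cnk,ck->cn", design, beta_x)
    sy = np.sqrt(np.sum(ry**2, axis=1))
    sx = np.sqrt(np.sum(rx**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.clip(np.sum(ry * rx, axis=1) / (sy * sx), -1.0, 1.0)
    floor_y = 1e-10 * np.maximum(1.0, np.linalg.norm(Y, axis=1))
    floor_x = 1e-10 * np.maximum(1.0, np.linalg.norm(X, axis=1))
    rho[(sy <= floor_y) | (sx <= floor_x)] = np.nan
    dof = N - 2 - k
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt(dof / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p[np.abs(rho) >= 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


@dataclass
class AttributionMaps:
    """Partial-correlation maps of GPP against the three climate drivers."""

    rho_p: GridField
    rho_t: GridField
    rho_sw: GridField
    p_values: dict[str, GridField]
    significant: dict[str, np.ndarray]  # boolean masks at alpha
    alpha: float
    n_undefined: int


def _check_alignment(*cubes: GriddedCube) -> np.ndarray:
    ref = cubes[0]
    for c in cubes[1:]:
        if c.grid != ref.grid or not np.array_equal(c.time, ref.time):
            raise ValidationError("cubes must share grid and years")
    mask = np.logical_and.reduce([c.mask for c in cubes])
    return mask


def climate_attribution(
    gpp: GriddedCube,
    p: GriddedCube,
    t: GriddedCube,
    sw: GriddedCube,
    alpha: float = 0.05,
    detrend: bool = False,
) -> AttributionMaps:
    """Per-cell partial correlation of annual GPP with each driver,
    controlling the other two; significance by per-cell t test at *alpha*
    (no multiple-testing correction, by design)."""
    mask = _check_alignment(gpp, p, t, sw)
    cubes = {"gpp": gpp, "p": p, "t": t, "sw": sw}
    if detrend:
        cubes = {k: decompose_trend(c).anomalies for k, c in cubes.items()}
    series = {k: c.values[:, mask].T for k, c in cubes.items()}  # (ncell, N)
    drivers = ("p", "t", "sw")
    rho_maps, p_maps, sig = {}, {}, {}
    n_undef = 0
    for d in drivers:
        others = [o for o in drivers if o != d]
        C = np.stack([series[o] for o in others], axis=2)
        rho, pv = _batched_partial_corr(series["gpp"], series[d], C)
        n_undef += int(np.sum(~np.isfinite(rho)))
        rho_full = np.full(gpp.grid.shape, np.nan)
        p_full = np.full(gpp.grid.shape, np.nan)
        rho_full[mask] = rho
        p_full[mask] = pv
        rho_maps[d] = GridField(gpp.grid, rho_full, units="1",
                                mask=mask & np.isfinite(rho_full), name=f"rho_{d}")
        p_maps[d] = GridField(gpp.grid, p_full, units="1",
                              mask=mask & np.isfinite(p_full), name=f"pval_{d}")
        sig[d] = np.where(np.isfinite(p_full), p_full < alpha, False)
    return AttributionMaps(
        rho_p=rho_maps["p"], rho_t=rho_maps["t"], rho_sw=rho_maps["sw"],
        p_values=p_maps, significant=sig, alpha=alpha, n_undefined=n_undef,
    )


@dataclass
class CouplingResult:
    """GPP-ET coupling: per-product and mean slope/correlation maps."""

    beta_mean: GridField          # g C per mm, mean across products
    r_mean: GridField             # mean Pearson r across products
    beta_per_product: dict[str, GridField]
    r_per_product: dict[str, GridField]
    beta_se_mean: GridField       # mean OLS standard error of beta
    sigma_gpp: GridField
    sigma_et_mean: GridField
    significant_r: np.ndarray     # mean-r significance at alpha (per cell)
    alpha: float


def _slope_r_se(g: np.ndarray, e: np.ndarray):
    """OLS slope, Pearson r and slope s.e. of g on e along axis 0."""
    N = g.shape[0]
    gm = g.mean(axis=0)
    em = e.mean(axis=0)
    gd = g - gm
    ed = e - em
    see = np.sum(ed**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.sum(gd * ed, axis=0) / see
        r = np.sum(gd * ed, axis=0) / np.sqrt(np.sum(gd**2, axis=0) * see)
        resid = gd - beta * ed
        se = np.sqrt(np.sum(resid**2, axis=0) / np.maximum(N - 2, 1) / see)
    bad = see <= 0
    beta[bad] = np.nan
    r[bad] = np.nan
    se[bad] = np.nan
    return beta, r, se


def gpp_et_coupling(
    gpp_anom: GriddedCube,
    et_anoms: dict[str, GriddedCube] | GriddedCube,
    alpha: float = 0.05,
) -> CouplingResult:
    """Per-cell regression of GPP anomalies on ET anomalies.

    ``et_anoms`` may be a single cube or a mapping product-name -> cube;
    the mean beta and mean r across products are reported alongside the
    per-product maps, following the averaged-product convention.
    """
    if isinstance(et_anoms, GriddedCube):
        et_anoms = {"et": et_anoms}
    betas, rs, ses = {}, {}, {}
    mask = gpp_anom.mask.copy()
    for name, et in et_anoms.items():
        m = _check_alignment(gpp_anom, et)
        mask &= m
        beta, r, se = _slope_r_se(gpp_anom.values, et.values)
        g = gpp_anom.grid
        betas[name] = GridField(g, beta, units="g C mm-1", mask=m & np.isfinite(beta),
                                name=f"beta_{name}")
        rs[name] = GridField(g, r, units="1", mask=m & np.isfinite(r), name=f"r_{name}")
        ses[name] = se
    g = gpp_anom.grid
    beta_mean = np.nanmean(np.stack([b.values for b in betas.values()]), axis=0)
    r_mean = np.nanmean(np.stack([r.values for r in rs.values()]), axis=0)
    se_mean = np.nanmean(np.stack(list(ses.values())), axis=0)
    N = gpp_anom.time.size
    sigma_gpp = gpp_anom.values.std(axis=0)
    sigma_et = np.nanmean(
        np.stack([et.values.std(axis=0) for et in et_anoms.values()]), axis=0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r_mean * np.sqrt((N - 2) / (1.0 - r_mean**2))
    pval = 2.0 * stats.t.sf(np.abs(tstat), N - 2)
    sig = np.where(np.isfinite(pval), pval < alpha, False)
    fin = mask & np.isfinite(beta_mean)
    return CouplingResult(
        beta_mean=GridField(g, beta_mean, units="g C mm-1", mask=fin, name="beta_mean"),
        r_mean=GridField(g, r_mean, units="1", mask=fin, name="r_et_mean"),
        beta_per_product=betas,
        r_per_product=rs,
        beta_se_mean=GridField(g, se_mean, units="g C mm-1", mask=fin, name="beta_se"),
        sigma_gpp=GridField(g, sigma_gpp, units=gpp_anom.units, mask=mask, name="sigma_gpp"),
        sigma_et_mean=GridField(g, sigma_et, units="mm yr-1", mask=mask, name="sigma_et"),
        significant_r=sig,
        alpha=alpha,
    )


def decompose_gpp_iav(
    beta: GridField, sigma_et: GridField, sigma_gpp: GridField
) -> tuple[GridField, GridField]:
    """Predicted sigma_GPP = |beta| * sigma_ET and its ratio to the actual.

    The ratio is ~1 where GPP and ET are tightly coupled and < 1 where
    GPP carries variability independent of ET.
    """
    mask = beta.mask & sigma_et.mask & sigma_gpp.mask
    pred = np.abs(beta.values) * sigma_et.values
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(sigma_gpp.values > 0, pred / sigma_gpp.values, np.nan)
    g = beta.grid
    return (
        GridField(g, pred, units=sigma_gpp.units, mask=mask & np.isfinite(pred),
                  name="sigma_gpp_predicted"),
        GridField(g, ratio, units="1", mask=mask & np.isfinite(ratio),
                  name="sigma_gpp_ratio"),
    )


def coupling_vs_iav_curves(
    coeff_maps: dict[str, GridField],
    sigma_gpp: GridField,
    bin_width: float = 10.0,
) -> dict[str, BinnedCurve]:
    """Area-weighted mean/s.d. of each coefficient map per sigma_GPP bin
    (default width 10 g C m-2 yr-1, bins from 0)."""
    w = area_weights(sigma_gpp.grid)
    return {
        name: bin_by_value(fld, sigma_gpp, bin_width=bin_width, weights=w)
        for name, fld in coeff_maps.items()
    }
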