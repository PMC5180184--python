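"""Budyko water-balance framework.

Analytical evapotranspiration ``ET(P, PET, n)``, its closed-form
sensitivities, first-order propagation of interannual variability from
precipitation, aridity-index computation/classification, and the inverse
problem of fitting the landscape exponent ``n``.

The analytical curve is the n-exponent form

    ET = P * PET / (P**n + PET**n)**(1/n)

which is symmetric in (P, PET), bounded by min(P, PET), and degree-1
homogeneous. An alternative (Fu's curve) is provided for sensitivity
studies behind the ``curve=`` switch of :func:`evapotranspiration`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .grid import GridField, GridSpec, area_weights

__all__ = [
    "BudykoParams",
    "AridityClassMap",
    "ARIDITY_BOUNDS",
    "ARIDITY_CLASSES",
    "budyko_et",
    "fu_et",
    "evapotranspiration",
    "budyko_sensitivity",
    "predict_et_iav",
    "aridity_index",
    "classify_aridity",
    "fit_n",
]

#: Default admissible range of the landscape exponent.
N_RANGE = (0.5, 2.0)

#: FAO/UNEP aridity-class boundaries (half-open [lower, upper)).
ARIDITY_BOUNDS = (0.05, 0.2, 0.5, 0.65)
ARIDITY_CLASSES = ("hyper-arid", "arid", "semi-arid", "dry sub-humid", "humid")


@dataclass(frozen=True)
class BudykoParams:
    """Landscape exponent n (scalar or per-cell) plus envelope values."""

    n: float | np.ndarray = 1.0
    envelope: tuple[float, float, float] = (0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        if np.any(n <= 0):
            raise ValidationError("Budyko exponent n must be > 0")


def _validate(P, PET, n):
    P = np.asarray(P, dtype=float)
    PET = np.asarray(PET, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValidationError("Budyko exponent n must be > 0")
    if np.any(P < 0) or np.any(PET < 0):
        raise ValidationError("P and PET must be non-negative")
    return P, PET, n


def budyko_et(P, PET, n):
    """Analytical ET = P*PET/(P^n + PET^n)^(1/n), numerically stable.

    The max(P, PET) factor is pulled out before exponentiation so the
    expression never overflows: ET = min * (1 + (min/max)^n)^(-1/n).
    Accepts scalars or broadcastable arrays; 0 <= ET <= min(P, PET).
    """
    P, PET, n = _validate(P, PET, n)
    big = np.maximum(P, PET)
    small = np.minimum(P, PET)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(big > 0, small / np.where(big > 0, big, 1.0), 0.0)
        et = small * (1.0 + ratio**n) ** (-1.0 / n)
    et = np.where(small == 0, 0.0, et)
    if np.any((P == 0) & (PET == 0)):
        raise ValidationError("P and PET may not both be zero")
    return et if et.ndim else float(et)


def fu_et(P, PET, w):
    """Fu's curve ET = P + PET - (P^w + PET^w)^(1/w), for w > 1."""
    P, PET, wv = _validate(P, PET, w)
    if np.any(wv <= 1):
        raise ValidationError("Fu exponent w must be > 1")
    big = np.maximum(P, PET)
    small = np.minimum(P, PET)
    with np.errstate(invalid="ignore"):
        ratio = np.where(big > 0, small / np.where(big > 0, big, 1.0), 0.0)
        et = P + PET - big * (1.0 + ratio**wv) ** (1.0 / wv)
    et = np.where(big == 0, 0.0, np.maximum(et, 0.0))
    return et if et.ndim else float(et)


def evapotranspiration(P, PET, n, curve: str = "budyko-n"):
    """Dispatch between the default n-form and Fu's alternative."""
    if curve == "budyko-n":
        return budyko_et(P, PET, n)
    if curve == "fu":
        return fu_et(P, PET, n)
    raise ValidationError(f"unknown curve {curve!r}")


def budyko_sensitivity(P, PET, n):
    """Closed-form (dET/dP, dET/dPET) of the analytical solution.

    dET/dP  = PET^(n+1) / (P^n + PET^n)^((n+1)/n) = (PET/S)^(n+1)
    dET/dPET = (P/S)^(n+1),     S = (P^n + PET^n)^(1/n)

    Both lie in (0, 1); dET/dP -> 1 as P/PET -> 0 and -> 0 as
    P/PET -> infinity. At P = 0 (or PET = 0) the limit values (1, 0)
    (resp. (0, 1)) are returned.
    """
    P, PET, n = _validate(P, PET, n)
    big = np.maximum(P, PET)
    small = np.minimum(P, PET)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(big > 0, small / np.where(big > 0, big, 1.0), 0.0)
        s_over_big = (1.0 + ratio**n) ** (1.0 / n)  # S / max(P, PET)
        dP = (PET / (big * s_over_big)) ** (n + 1.0)
        dPET = (P / (big * s_over_big)) ** (n + 1.0)
    dP = np.where(P == 0, 1.0, np.where(PET == 0, 0.0, dP))
    dPET = np.where(PET == 0, 1.0, np.where(P == 0, 0.0, dPET))
    if dP.ndim:
        return dP, dPET
    return float(dP), float(dPET)


def predict_et_iav(P_mean, P_sd, PET_mean, PET_sd, n):
    """First-order (delta-method) ET interannual variability.

    contribution_P  = |dET/dP|  * sigma_P
    contribution_PET = |dET/dPET| * sigma_PET
    sigma_ET = sqrt(contribution_P^2 + contribution_PET^2)

    assuming independent P and PET fluctuations. The components are
    returned separately so the claim that the PET term is negligible can
    be checked rather than assumed.
    """
    P_mean = np.asarray(P_mean, dtype=float)
    PET_mean = np.asarray(PET_mean, dtype=float)
    if np.any(P_mean <= 0) or np.any(PET_mean <= 0):
        raise ValidationError("means must be positive")
    P_sd = np.asarray(P_sd, dtype=float)
    PET_sd = np.asarray(PET_sd, dtype=float)
    if np.any(P_sd < 0) or np.any(PET_sd < 0):
        raise ValidationError("standard deviations must be non-negative")
    dP, dPET = budyko_sensitivity(P_mean, PET_mean, n)
    contrib_p = np.abs(dP) * P_sd
    contrib_pet = np.abs(dPET) * PET_sd
    sigma_et = np.hypot(contrib_p, contrib_pet)
    if np.ndim(sigma_et):
        return sigma_et, contrib_p, contrib_pet
    return float(sigma_et), float(contrib_p), float(contrib_pet)


def aridity_index(P_mean: GridField, PET_mean: GridField) -> GridField:
    """AI = climatological P / PET, cell-wise on the shared mask.

    Cells with non-positive PET on land are masked out (counted in the
    returned field's ``name`` suffix is avoided; callers can diff masks).
    """
    if P_mean.grid != PET_mean.grid:
        raise ValidationError("P and PET grids differ")
    mask = P_mean.mask & PET_mean.mask
    bad = mask & ~(PET_mean.values > 0)
    mask = mask & (PET_mean.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(mask, P_mean.values / np.where(mask, PET_mean.values, 1.0), np.nan)
    fld = GridField(P_mean.grid, ai, units="1", mask=mask, name="aridity_index")
    if bad.any():
        import warnings

        warnings.warn(f"{int(bad.sum())} land cells had PET <= 0 and were masked")
    return fld


@dataclass
class AridityClassMap:
    """Per-cell aridity class labels plus the boundary table used."""

    grid: GridSpec
    labels: np.ndarray  # int class index, -1 where masked
    class_names: tuple[str, ...]
    bounds: tuple[float, ...]
    mask: np.ndarray

    def area_fractions(self) -> dict[str, float]:
        """Area fraction of each class among unmasked land cells."""
        w = area_weights(self.grid).values
        wl = np.where(self.mask, w, 0.0)
        tot = wl.sum()
        return {
            name: float(wl[self.labels == k].sum() / tot)
            for k, name in enumerate(self.class_names)
        }

    def class_mask(self, name: str) -> np.ndarray:
        k = self.class_names.index(name)
        return (self.labels == k) & self.mask


def classify_aridity(
    ai: GridField,
    bounds: tuple[float, ...] = ARIDITY_BOUNDS,
    class_names: tuple[str, ...] = ARIDITY_CLASSES,
) -> AridityClassMap:
    """Classify an AI field with half-open [lower, upper) boundaries.

    Defaults to the FAO/UNEP table: hyper-arid < 0.05 <= arid < 0.2 <=
    semi-arid < 0.5 <= dry sub-humid < 0.65 <= humid.
    """
    if len(class_names) != len(bounds) + 1:
        raise ValidationError("need exactly one more class name than boundary")
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValidationError("boundaries must be strictly increasing")
    vals = ai.values
    if np.any(vals[ai.mask] < 0):
        raise ValidationError("aridity index must be non-negative")
    labels = np.full(ai.grid.shape, -1, dtype=np.int64)
    edges = np.asarray(bounds, dtype=float)
    labels[ai.mask] = np.searchsorted(edges, vals[ai.mask], side="right")
    return AridityClassMap(ai.grid, labels, tuple(class_names), tuple(bounds), ai.mask.copy())


def classify_value(ai_value: float, bounds=ARIDITY_BOUNDS, class_names=ARIDITY_CLASSES) -> str:
    """Classify a single aridity-index value (convenience wrapper)."""
    if ai_value < 0:
        raise ValidationError("aridity index must be non-negative")
    return class_names[int(np.searchsorted(np.asarray(bounds), ai_value, side="right"))]


@dataclass(frozen=True)
class FitNResult:
    n_hat: float
    rss: float
    converged: bool
    ambiguous: bool = False


def fit_n(P, PET, ET, bounds: tuple[float, float] = (0.05, 20.0)) -> FitNResult:
    """Least-squares fit of the landscape exponent from (P, PET, ET) samples.

    Minimises sum((ET - budyko_et(P, PET, n))^2) over a bracketed 1-D
    search. A single observation (or observations carrying no constraint)
    is flagged ambiguous.
    """
    P = np.atleast_1d(np.asarray(P, dtype=float))
    PET = np.atleast_1d(np.asarray(PET, dtype=float))
    ET = np.atleast_1d(np.asarray(ET, dtype=float))
    if not (P.size == PET.size == ET.size):
        raise ValidationError("P, PET, ET must have equal lengths")

    def rss(n):
        return float(np.sum((ET - budyko_et(P, PET, n)) ** 2))

    res = minimize_scalar(rss, bounds=bounds, method="bounded",
                          options={"xatol": 1e-10})
    # flatness probe: an under-determined fit has a near-flat objective
    span = max(rss(bounds[0]), rss(bounds[1]))
    ambiguous = P.size < 3 or span - res.fun < 1e-12 * max(1.0, span)
    return FitNResult(float(res.x), float(res.fun), bool(res.success), ambiguous)
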