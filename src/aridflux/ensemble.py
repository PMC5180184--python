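"""SIF-proxy weighting of a multi-model GPP ensemble.

Per-biome Pearson correlations between each model's GPP and SIF (spatial
or temporal mode), biome-area-weighted model scores, order-gamma weights
W_i = max(score_i, 0)**gamma / sum_k max(score_k, 0)**gamma, the weighted
and unweighted ensemble cubes, and a leave-one-model-out stability
comparison of the two averaging schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .grid import BiomeFractions, GriddedCube, GridField, area_weights, to_annual

__all__ = [
    "ModelEnsemble",
    "CorrelationMatrix",
    "ScoreVector",
    "WeightVector",
    "weighted_pearson",
    "biome_correlations",
    "correlation_matrix",
    "biome_area_fractions",
    "model_score",
    "ensemble_weights",
    "weighted_ensemble",
    "unweighted_ensemble",
    "leave_one_out_stability",
]

MIN_EFFECTIVE_SAMPLES = 3


@dataclass
class ModelEnsemble:
    """Named collection of per-model GPP cubes on a common grid/time axis."""

    names: list[str]
    cubes: dict[str, GriddedCube]

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValidationError("ensemble needs at least one model")
        if set(self.names) != set(self.cubes):
            raise ValidationError("names and cube keys differ")
        ref = self.cubes[self.names[0]]
        for name in self.names[1:]:
            c = self.cubes[name]
            if c.grid != ref.grid or not np.array_equal(c.time, ref.time):
                raise ValidationError(f"model {name!r} is not on the common grid/time axis")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> GriddedCube:
        return self.cubes[name]

    def subset(self, names) -> "ModelEnsemble":
        names = list(names)
        return ModelEnsemble(names, {n: self.cubes[n] for n in names})

    @property
    def grid(self):
        return self.cubes[self.names[0]].grid

    @property
    def time(self) -> np.ndarray:
        return self.cubes[self.names[0]].time


@dataclass
class CorrelationMatrix:
    """r[i, j]: model i vs SIF within biome j; NaN marks undefined entries."""

    model_names: list[str]
    biome_labels: list[str]
    r: np.ndarray
    mode: str
    training_years: np.ndarray

    def row(self, model: str) -> np.ndarray:
        return self.r[self.model_names.index(model)]


@dataclass
class ScoreVector:
    model_names: list[str]
    scores: np.ndarray
    area_fractions: np.ndarray = field(default=None)  # a_j actually used

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.model_names),):
            raise ValidationError("score length does not match model list")


@dataclass
class WeightVector:
    model_names: list[str]
    weights: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.model_names),):
            raise ValidationError("weight length does not match model list")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must be non-negative and sum to 1")


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation under non-negative sample weights.

    Returns NaN when either variable has zero weighted variance or the
    weights carry fewer than :data:`MIN_EFFECTIVE_SAMPLES` positive entries.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    if np.count_nonzero(w > 0) < MIN_EFFECTIVE_SAMPLES:
        return float("nan")
    w = w / w.sum()
    mx = np.sum(w * x)
    my = np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def _as_annual(cube: GriddedCube, how: str) -> GriddedCube:
    return to_annual(cube, how) if cube.freq == "monthly" else cube


def biome_correlations(
    model_gpp: GriddedCube,
    sif: GriddedCube,
    biomes: BiomeFractions,
    mode: str = "spatial",
    training_years=None,
    weights: GridField | None = None,
) -> np.ndarray:
    """Per-biome Pearson correlation of one model's GPP with SIF.

    ``spatial`` mode: average both fields over the training years to one
    annual map each, then correlate across land cells within each biome,
    each cell weighted by area x biome fraction.

    ``temporal`` mode: for every month of the training window, reduce each
    field to one biome-mean value (area-and-fraction weighted), then
    correlate the two monthly sequences per biome.

    Biomes with fewer than three effective samples come back as NaN.
    """
    if mode not in ("spatial", "temporal"):
        raise ValidationError(f"mode must be 'spatial' or 'temporal', got {mode!r}")
    if model_gpp.grid != sif.grid or model_gpp.grid != biomes.grid:
        raise ValidationError("model GPP, SIF and biome fractions must share one grid")
    if weights is None:
        weights = area_weights(model_gpp.grid)
    mask = model_gpp.mask & sif.mask
    J = biomes.n_biomes
    out = np.full(J, np.nan)

    if mode == "spatial":
        gpp_a = _as_annual(model_gpp, "sum")
        sif_a = _as_annual(sif, "mean")
        if training_years is not None:
            gpp_a = gpp_a.select_years(training_years)
            sif_a = sif_a.select_years(training_years)
        gmap = gpp_a.values.mean(axis=0)
        smap = sif_a.values.mean(axis=0)
        for j in range(J):
            w = weights.values * biomes.fractions[j]
            w = np.where(mask, w, 0.0)
            out[j] = weighted_pearson(gmap[mask], smap[mask], w[mask])
        return out

    # temporal mode
    if model_gpp.freq != "monthly" or sif.freq != "monthly":
        raise ValidationError("temporal mode needs monthly cubes")
    gpp_m, sif_m = model_gpp, sif
    if training_years is not None:
        gpp_m = gpp_m.select_years(training_years)
        sif_m = sif_m.select_years(training_years)
    for j in range(J):
        w = np.where(mask, weights.values * biomes.fractions[j], 0.0)
        wsum = w.sum()
        if wsum <= 0 or np.count_nonzero(w > 0) < MIN_EFFECTIVE_SAMPLES:
            continue
        g_series = np.tensordot(gpp_m.values, w, axes=([1, 2], [0, 1])) / wsum
        s_series = np.tensordot(sif_m.values, w, axes=([1, 2], [0, 1])) / wsum
        if g_series.size >= MIN_EFFECTIVE_SAMPLES:
            out[j] = weighted_pearson(g_series, s_series, np.ones_like(g_series))
    return out


def correlation_matrix(
    models: ModelEnsemble,
    sif: GriddedCube,
    biomes: BiomeFractions,
    mode: str = "spatial",
    training_years=None,
    weights: GridField | None = None,
) -> CorrelationMatrix:
    """Stack :func:`biome_correlations` rows for every model."""
    r = np.vstack([
        biome_correlations(models[name], sif, biomes, mode, training_years, weights)
        for name in models.names
    ])
    ty = np.asarray(training_years if training_years is not None else models.cubes[models.names[0]].years)
    return CorrelationMatrix(list(models.names), list(biomes.labels), r, mode, ty)


def biome_area_fractions(biomes: BiomeFractions, mask: np.ndarray | None = None,
                         weights: GridField | None = None) -> np.ndarray:
    """a_j: each biome's share of total (masked) land area, summing to 1."""
    if weights is None:
        weights = area_weights(biomes.grid)
    w = weights.values if mask is None else np.where(mask, weights.values, 0.0)
    areas = np.array([np.sum(w * biomes.fractions[j]) for j in range(biomes.n_biomes)])
    tot = areas.sum()
    if tot <= 0:
        raise ValidationError("biome fractions cover no area")
    return areas / tot


def model_score(corr_row: np.ndarray, a: np.ndarray) -> float:
    """score_i = sum_j a_j r_{i,j} over defined entries, a renormalised."""
    corr_row = np.asarray(corr_row, dtype=float)
    a = np.asarray(a, dtype=float)
    if corr_row.shape != a.shape:
        raise ValidationError("correlation row and area fractions misaligned")
    ok = np.isfinite(corr_row)
    if not ok.any():
        raise ValidationError("all correlation entries undefined; cannot score model")
    a_ok = a[ok]
    if a_ok.sum() <= 0:
        raise ValidationError("defined biomes carry zero area")
    return float(np.sum(a_ok / a_ok.sum() * corr_row[ok]))


def ensemble_weights(scores, gamma: float) -> WeightVector | np.ndarray:
    """W_i = max(score_i, 0)^gamma, normalised to sum 1.

    Negative scores are floored at zero: a model anti-correlated with SIF
    gets no weight. Errors out when no model has a positive score.
    """
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    if isinstance(scores, ScoreVector):
        names, vals = scores.model_names, scores.scores
    else:
        names, vals = None, np.asarray(scores, dtype=float)
    floored = np.maximum(vals, 0.0)
    top = floored.max()
    if top <= 0:
        raise ValidationError("no model has a positive score; cannot form weights")
    powered = (floored / top) ** gamma  # scale out the max so tiny scores never underflow
    w = powered / powered.sum()
    w = w / w.sum()  # exact renormalisation to 1e-12
    if names is None:
        return w
    return WeightVector(names, w, gamma)


def weighted_ensemble(models: ModelEnsemble, w: WeightVector) -> GriddedCube:
    """GPP_ens(t, cell) = sum_i W_i GPP_i(t, cell)."""
    if list(w.model_names) != list(models.names):
        if set(w.model_names) != set(models.names):
            raise ValidationError("weight vector does not match ensemble models")
        order = [w.model_names.index(n) for n in models.names]
        weights = w.weights[order]
    else:
        weights = w.weights
    ref = models[models.names[0]]
    acc = np.zeros_like(ref.values)
    for wi, name in zip(weights, models.names):
        acc += wi * models[name].values
    mask = np.logical_and.reduce([models[n].mask for n in models.names])
    return GriddedCube(ref.grid, acc, ref.time, freq=ref.freq, units=ref.units,
                       mask=mask, name="gpp_ensemble")


def unweighted_ensemble(models: ModelEnsemble) -> GriddedCube:
    """Simple mean across models (equal weights)."""
    m = len(models)
    w = WeightVector(list(models.names), np.full(m, 1.0 / m), gamma=1.0)
    cube = weighted_ensemble(models, w)
    cube.name = "gpp_ensemble_unweighted"
    return cube


def _statistic_map(cube: GriddedCube, statistic: str) -> np.ndarray:
    if statistic == "annual_gpp":
        return cube.values.mean(axis=0)
    if statistic == "gpp_sd":
        return cube.values.std(axis=0)
    raise ValidationError(f"unknown statistic {statistic!r}")


def leave_one_out_stability(
    models: ModelEnsemble,
    sif: GriddedCube,
    biomes: BiomeFractions,
    gamma: float = 2.0,
    statistic: str = "annual_gpp",
    mode: str = "spatial",
    training_years=None,
) -> tuple[GridField, GridField]:
    """Stability of the two averaging schemes under leave-one-model-out.

    For each left-out model the score/weight computation is repeated on
    the remaining M-1 models and the chosen per-cell statistic of both
    ensembles is recorded; returned are the per-cell standard deviations
    across the M replicates (weighted scheme, unweighted scheme).
    """
    if len(models) < 3:
        raise ValidationError("leave-one-out needs at least 3 models")
    a = biome_area_fractions(biomes)
    maps_w, maps_u = [], []
    for left_out in models.names:
        rest = models.subset([n for n in models.names if n != left_out])
        cm = correlation_matrix(rest, sif, biomes, mode, training_years)
        scores = ScoreVector(rest.names, [model_score(cm.row(n), a) for n in rest.names])
        wv = ensemble_weights(scores, gamma)
        maps_w.append(_statistic_map(weighted_ensemble(rest, wv), statistic))
        maps_u.append(_statistic_map(unweighted_ensemble(rest), statistic))
    grid = models.grid
    mask = models[models.names[0]].mask
    sd_w = np.std(np.stack(maps_w), axis=0)
    sd_u = np.std(np.stack(maps_u), axis=0)
    units = models[models.names[0]].units
    return (
        GridField(grid, sd_w, units=units, mask=mask, name=f"loo_sd_weighted_{statistic}"),
        GridField(grid, sd_u, units=units, mask=mask, name=f"loo_sd_unweighted_{statistic}"),
    )
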