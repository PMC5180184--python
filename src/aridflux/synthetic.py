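"""Seeded synthetic planet with known ground truth.

Generates climate (P, PET, T, SW), a Budyko-consistent ET field, a truth
GPP field whose interannual behaviour switches from water-limited
(GPP = WUE * ET) below aridity index 1 to radiation-driven above it, a
noisy SIF proxy proportional to truth GPP per biome, and an M-member
model ensemble with known multiplicative biases and noise levels. Every
downstream stage of the pipeline can therefore be tested against the
parameters the generator wrote down.

All distributional choices are stand-ins for the observational data they
emulate and are recorded in the truth table emitted by the CLI.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .budyko import budyko_et
from .ensemble import ModelEnsemble
from .errors import ValidationError
from .grid import BiomeFractions, GriddedCube, GridField, GridSpec

__all__ = ["ModelSpec", "WorldConfig", "SyntheticWorld", "build_world",
           "sample_precipitation_series", "default_config"]

#: Precipitation series are truncated at this fraction of the mean.
P_FLOOR_FRACTION = 0.05


@dataclass(frozen=True)
class ModelSpec:
    """One synthetic GPP model: output = bias * truth + noise."""

    name: str
    bias: float = 1.0
    noise_rel: float = 0.1  # s.d. of monthly noise relative to mean monthly GPP

    def __post_init__(self) -> None:
        if self.bias <= 0 or self.noise_rel < 0:
            raise ValidationError(f"bad model spec {self.name!r}")


def _default_models() -> tuple[ModelSpec, ...]:
    levels = (0.05, 0.15, 0.30, 0.50, 0.75, 1.00)
    biases = (1.05, 0.9, 1.1, 0.95, 1.2, 0.8)
    return tuple(
        ModelSpec(f"model_{i:02d}", bias=b, noise_rel=s)
        for i, (b, s) in enumerate(zip(biases, levels))
    )


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world; defaults give a desk-scale planet."""

    nlat: int = 20
    nlon: int = 40
    lat_range: tuple[float, float] = (-57.0, 57.0)
    years: tuple[int, int] = (2000, 2011)           # analysis window, inclusive
    training_years: tuple[int, int] = (2007, 2011)  # ensemble training window
    n_biomes: int = 4
    models: tuple[ModelSpec, ...] = field(default_factory=_default_models)
    seed: int = 0

    # mean-climate gradient
    ai_range: tuple[float, float] = (0.02, 3.0)     # log-spaced across longitude
    pet_base: float = 1100.0                        # mm yr-1
    pet_amplitude: float = 300.0                    # latitudinal modulation

    # Budyko landscape exponent field, within [0.5, 2]
    n_range: tuple[float, float] = (0.8, 1.8)

    # interannual variability of the drivers
    cv_p_base: float = 0.06       # CV of annual P in the wet limit
    cv_p_amplitude: float = 0.35  # extra CV in the dry limit
    cv_p_scale: float = 0.22      # e-folding of CV with aridity index
    shared_anomaly_fraction: float = 0.6  # weight of the common interannual mode
    cv_pet: float = 0.02
    et_noise_rel: float = 0.01

    # carbon coupling
    wue_min: float = 0.4          # g C per mm of ET
    wue_max: float = 2.8
    wue_sat_ai: float = 0.3       # AI at which WUE saturates
    trend: float = 0.005          # fractional GPP trend per year
    gpp_noise_rel: float = 0.02   # annual GPP noise, relative to mean GPP
    humid_sw_coupling: float = 0.25
    humid_p_coupling: float = 0.05
    humid_noise_rel: float = 0.012

    # radiation / temperature
    sw_base: float = 180.0        # W m-2
    sw_amplitude: float = 60.0
    sw_p_coupling: float = -0.3   # relative SW anomaly per relative P anomaly
    sw_noise_rel: float = 0.05
    t_p_coupling: float = -1.0    # degC per unit relative P anomaly
    t_noise_sd: float = 0.4       # degC

    # SIF proxy
    sif_noise: float = 0.15       # mW m-2 sr-1 nm-1, monthly additive noise
    sif_k_base: float = 0.006     # biome j slope: k_j = base + step * j
    sif_k_step: float = 0.003     # (mW m-2 sr-1 nm-1) per (g C m-2 month-1)
    seasonal_amplitude: float = 0.6

    def __post_init__(self) -> None:
        if self.n_range[0] < 0.5 or self.n_range[1] > 2.0 or self.n_range[0] > self.n_range[1]:
            raise ValidationError("n_range must lie within [0.5, 2]")
        if self.ai_range[0] <= 0 or self.pet_base <= 0:
            raise ValidationError("P and PET scales must be positive")
        for cv in (self.cv_p_base, self.cv_p_amplitude, self.cv_pet,
                   self.gpp_noise_rel, self.humid_noise_rel, self.sw_noise_rel):
            if cv < 0:
                raise ValidationError("coefficients of variation must be >= 0")
        if len(self.models) < 2:
            raise ValidationError("need at least 2 models")
        if self.n_biomes < 1:
            raise ValidationError("need at least 1 biome")
        if self.years[0] > self.years[1]:
            raise ValidationError("empty analysis window")
        if not (self.years[0] <= self.training_years[0]
                and self.training_years[1] <= self.years[1]):
            raise ValidationError("training window must lie inside the analysis window")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @property
    def training_list(self) -> np.ndarray:
        return np.arange(self.training_years[0], self.training_years[1] + 1)


def default_config(**overrides) -> WorldConfig:
    return WorldConfig(**overrides)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent stream per (seed, field-name): adding a field never
    perturbs the draws of the others."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def sample_precipitation_series(mean: float, cv: float, years: int,
                                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Annual precipitation: mean * (1 + eps), eps ~ N(0, cv), independent
    across years, floored at 5% of the mean so values stay positive."""
    if mean <= 0:
        raise ValidationError("mean precipitation must be positive")
    if cv < 0:
        raise ValidationError("cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), "precip_series")
    eps = rng.normal(0.0, cv, size=years) if cv > 0 else np.zeros(years)
    return np.maximum(mean * (1.0 + eps), P_FLOOR_FRACTION * mean)


@dataclass
class SyntheticWorld:
    """Synthetic planet: data cubes plus the truth used to build them."""

    config: WorldConfig
    grid: GridSpec
    biomes: BiomeFractions
    # annual cubes
    gpp_truth: GriddedCube
    et: GriddedCube
    p: GriddedCube
    pet: GriddedCube
    t: GriddedCube
    sw: GriddedCube
    # monthly cubes
    gpp_truth_monthly: GriddedCube
    sif_monthly: GriddedCube
    # model ensembles (annual + monthly share names)
    models: ModelEnsemble
    models_monthly: ModelEnsemble
    # truth maps
    n_map: GridField
    wue_map: GridField
    ai_map: GridField
    water_limited: np.ndarray  # boolean, AI < 1

    @property
    def quality_ranking(self) -> list[str]:
        """Model names best-first (smallest noise level = best)."""
        specs = sorted(self.config.models, key=lambda m: m.noise_rel)
        return [m.name for m in specs]

    def truth_table(self):
        """Per-cell and per-model ground truth as two pandas frames."""
        import pandas as pd

        lat_idx, lon_idx = np.meshgrid(
            np.arange(self.grid.nlat), np.arange(self.grid.nlon), indexing="ij"
        )
        cells = pd.DataFrame({
            "lat": self.grid.lat[lat_idx.ravel()],
            "lon": self.grid.lon[lon_idx.ravel()],
            "n": self.n_map.values.ravel(),
            "wue_gC_per_mm": self.wue_map.values.ravel(),
            "aridity_index": self.ai_map.values.ravel(),
            "water_limited": self.water_limited.ravel(),
        })
        models = pd.DataFrame({
            "model": [m.name for m in self.config.models],
            "bias": [m.bias for m in self.config.models],
            "noise_rel": [m.noise_rel for m in self.config.models],
        })
        return cells, models


def _seasonal_shapes(config: WorldConfig) -> np.ndarray:
    """Fixed per-biome monthly shares (J, 12), each summing to 1."""
    months = np.arange(12)
    shapes = np.empty((config.n_biomes, 12))
    for j in range(config.n_biomes):
        peak = (j * 12) // max(config.n_biomes, 1)
        s = 1.0 + config.seasonal_amplitude * np.cos(2 * np.pi * (months - peak) / 12.0)
        shapes[j] = s / s.sum()
    return shapes


def _biome_fractions(grid: GridSpec, config: WorldConfig) -> BiomeFractions:
    """Smooth latitudinal membership functions, normalised to sum 1."""
    J = config.n_biomes
    lat = grid.lat
    lo, hi = lat.min(), lat.max()
    centers = np.linspace(lo, hi, J) if J > 1 else np.array([(lo + hi) / 2])
    width = (hi - lo) / max(J, 1) * 0.35 + 1e-9
    member = np.exp(-0.5 * ((lat[None, :] - centers[:, None]) / width) ** 2)
    member /= member.sum(axis=0, keepdims=True)
    fr = np.repeat(member[:, :, None], grid.nlon, axis=2)
    labels = [f"biome_{j}" for j in range(J)]
    return BiomeFractions(grid, fr, labels=labels)


def build_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Deterministically build the synthetic planet for ``config.seed``."""
    cfg = config or WorldConfig()
    grid = GridSpec(
        np.linspace(cfg.lat_range[0], cfg.lat_range[1], cfg.nlat),
        np.linspace(-180.0 + 360.0 / cfg.nlon / 2, 180.0 - 360.0 / cfg.nlon / 2, cfg.nlon),
    )
    years = cfg.year_list
    ny = years.size
    nlat, nlon = grid.shape
    lat_rad = np.deg2rad(grid.lat)[:, None]

    # --- mean climate -----------------------------------------------------
    ai_lon = np.geomspace(cfg.ai_range[0], cfg.ai_range[1], nlon)[None, :]
    ai_jitter = 1.0 + 0.1 * np.sin(3.0 * lat_rad)  # deterministic texture
    ai_mean = ai_lon * ai_jitter
    pet_mean = cfg.pet_base + cfg.pet_amplitude * np.cos(lat_rad) * np.ones((1, nlon))
    p_mean = ai_mean * pet_mean
    u = (grid.lat - grid.lat.min()) / max(np.ptp(grid.lat), 1e-12)
    n_map = (cfg.n_range[0] + (cfg.n_range[1] - cfg.n_range[0]) * u)[:, None] * np.ones((1, nlon))
    wue = cfg.wue_min + (cfg.wue_max - cfg.wue_min) * np.clip(ai_mean / cfg.wue_sat_ai, 0, 1)
    water_limited = ai_mean < 1.0

    # --- interannual driver anomalies ------------------------------------
    cv_p = cfg.cv_p_base + cfg.cv_p_amplitude * np.exp(-ai_mean / cfg.cv_p_scale)
    # one common interannual mode plus independent cell noise; the shared
    # part keeps class-integrated anomaly series stable at desk scale
    c = np.clip(cfg.shared_anomaly_fraction, 0.0, 1.0)
    z_shared = _rng(cfg.seed, "precip_mode").normal(0.0, 1.0, ny)[:, None, None]
    z_local = _rng(cfg.seed, "precip").normal(0.0, 1.0, (ny, nlat, nlon))
    eps_p = (c * z_shared + np.sqrt(1.0 - c**2) * z_local) * cv_p
    p_cube = np.maximum(p_mean * (1.0 + eps_p), P_FLOOR_FRACTION * p_mean)
    eps_p_eff = p_cube / p_mean - 1.0  # after flooring

    eps_pet = _rng(cfg.seed, "pet").normal(0.0, cfg.cv_pet, (ny, nlat, nlon))
    pet_cube = pet_mean * (1.0 + eps_pet)

    et_noise = _rng(cfg.seed, "et").normal(0.0, cfg.et_noise_rel, (ny, nlat, nlon))
    et_cube = budyko_et(p_cube, pet_cube, n_map) * (1.0 + et_noise)

    sw_anom = (cfg.sw_p_coupling * eps_p_eff
               + _rng(cfg.seed, "sw").normal(0.0, cfg.sw_noise_rel, (ny, nlat, nlon)))
    sw_mean = cfg.sw_base + cfg.sw_amplitude * np.cos(lat_rad) * np.ones((1, nlon))
    sw_cube = sw_mean * (1.0 + sw_anom)

    t_mean = 28.0 * np.cos(lat_rad) * np.ones((1, nlon)) - 2.0
    t_cube = (t_mean + cfg.t_p_coupling * eps_p_eff
              + _rng(cfg.seed, "temperature").normal(0.0, cfg.t_noise_sd, (ny, nlat, nlon)))

    # --- truth GPP --------------------------------------------------------
    t0 = years.mean()
    trend_factor = 1.0 + cfg.trend * (years - t0)[:, None, None]
    et_clim = budyko_et(p_mean, pet_mean, n_map)
    gpp_mean = wue * et_clim
    gpp_noise = _rng(cfg.seed, "gpp").normal(0.0, 1.0, (ny, nlat, nlon)) * (
        cfg.gpp_noise_rel * gpp_mean
    )
    gpp_wl = wue * et_cube * trend_factor + gpp_noise
    humid_noise = _rng(cfg.seed, "gpp_humid").normal(0.0, cfg.humid_noise_rel, (ny, nlat, nlon))
    gpp_humid = gpp_mean * trend_factor * (
        1.0 + cfg.humid_sw_coupling * sw_anom + cfg.humid_p_coupling * eps_p_eff + humid_noise
    )
    gpp_cube = np.maximum(np.where(water_limited, gpp_wl, gpp_humid), 0.0)

    # --- monthly truth, SIF, models --------------------------------------
    biomes = _biome_fractions(grid, cfg)
    shapes = _seasonal_shapes(cfg)  # (J, 12)
    cell_shape = np.einsum("jkl,jm->mkl", biomes.fractions, shapes)  # (12, nlat, nlon)
    months = np.array([y * 100 + m for y in years for m in range(1, 13)], dtype=np.int64)
    gpp_monthly = (gpp_cube[:, None, :, :] * cell_shape[None, :, :, :]).reshape(
        12 * ny, nlat, nlon
    )

    k_j = cfg.sif_k_base + cfg.sif_k_step * np.arange(cfg.n_biomes)
    k_cell = np.einsum("jkl,j->kl", biomes.fractions, k_j)
    sif_monthly = k_cell * gpp_monthly
    if cfg.sif_noise > 0:
        sif_monthly = sif_monthly + _rng(cfg.seed, "sif").normal(
            0.0, cfg.sif_noise, gpp_monthly.shape
        )

    mask = np.ones(grid.shape, dtype=bool)

    def cube(vals, time, freq, units, name):
        return GriddedCube(grid, vals, time, freq=freq, units=units, mask=mask, name=name)

    monthly_models: dict[str, GriddedCube] = {}
    annual_models: dict[str, GriddedCube] = {}
    mean_monthly = gpp_mean / 12.0
    for spec in cfg.models:
        noise = _rng(cfg.seed, f"model:{spec.name}").normal(0.0, 1.0, gpp_monthly.shape)
        vals = spec.bias * gpp_monthly + noise * (spec.noise_rel * mean_monthly)
        monthly_models[spec.name] = cube(vals, months, "monthly", "g C m-2 month-1", spec.name)
        annual = vals.reshape(ny, 12, nlat, nlon).sum(axis=1)
        annual_models[spec.name] = cube(annual, years, "annual", "g C m-2 yr-1", spec.name)
    names = [m.name for m in cfg.models]

    return SyntheticWorld(
        config=cfg,
        grid=grid,
        biomes=biomes,
        gpp_truth=cube(gpp_cube, years, "annual", "g C m-2 yr-1", "gpp_truth"),
        et=cube(et_cube, years, "annual", "mm yr-1", "et"),
        p=cube(p_cube, years, "annual", "mm yr-1", "precip"),
        pet=cube(pet_cube, years, "annual", "mm yr-1", "pet"),
        t=cube(t_cube, years, "annual", "degC", "temperature"),
        sw=cube(sw_cube, years, "annual", "W m-2", "shortwave"),
        gpp_truth_monthly=cube(gpp_monthly, months, "monthly", "g C m-2 month-1", "gpp_truth"),
        sif_monthly=cube(sif_monthly, months, "monthly", "mW m-2 sr-1 nm-1", "sif"),
        models=ModelEnsemble(names, annual_models),
        models_monthly=ModelEnsemble(names, monthly_models),
        n_map=GridField(grid, n_map, units="1", mask=mask, name="budyko_n"),
        wue_map=GridField(grid, wue, units="g C mm-1", mask=mask, name="wue"),
        ai_map=GridField(grid, ai_mean, units="1", mask=mask, name="aridity_index"),
        water_limited=water_limited,
    )
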