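"""Gridded data model and I/O.

Defines the regular lat-lon grid (:class:`GridSpec`), single 2-D fields
(:class:`GridField`), time-stacked cubes (:class:`GriddedCube`) and
fractional land-cover maps (:class:`BiomeFractions`), together with the
area weighting, land-cover aggregation and time aggregation used by every
analysis stage.

Conventions
-----------
* Cell-center coordinates with uniform spacing along each axis.
* Relative cell area proportional to cos(latitude of cell center),
  normalised so the sum over *all* cells of the grid is 1.
* The land mask is boolean, ``True`` on valid cells, and is identical
  across the time steps of a cube.
* Monthly time axes are encoded as integers ``year*100 + month``; annual
  axes as plain years. Whole calendar years only.
* Units are declared strings validated against a small alias table and
  never silently converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xarray as xr

from .errors import FormatError, UnitsError, ValidationError

__all__ = [
    "GridSpec",
    "GridField",
    "GriddedCube",
    "BiomeFractions",
    "read_cube",
    "write_cube",
    "area_weights",
    "aggregate_fractions",
    "to_annual",
    "global_total",
    "EARTH_LAND_AREA_M2",
]

#: Nominal global land area (m^2), used as the default integration domain.
EARTH_LAND_AREA_M2 = 1.485e14

_AXIS_TOL = 1e-6

# canonical unit -> accepted spellings (lower-cased, compared verbatim)
_UNIT_ALIASES = {
    "g C m-2 yr-1": {"g c m-2 yr-1", "gc m-2 yr-1", "gc/m2/yr", "g c m^-2 yr^-1"},
    "g C m-2 month-1": {"g c m-2 month-1", "gc/m2/month", "g c m^-2 month^-1"},
    "mm yr-1": {"mm yr-1", "mm/yr", "mm yr^-1", "mm"},
    "mm month-1": {"mm month-1", "mm/month"},
    "mW m-2 sr-1 nm-1": {"mw m-2 sr-1 nm-1", "mw/m2/sr/nm", "mw m^-2 sr^-1 nm^-1"},
}

GRAMS_PER_PETAGRAM = 1e15


def canonical_units(units: str) -> str:
    """Return the canonical spelling of *units*, or the input unchanged."""
    low = units.strip().lower()
    for canon, aliases in _UNIT_ALIASES.items():
        if low == canon.lower() or low in aliases:
            return canon
    return units.strip()


def _check_axis(name: str, values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValidationError(f"{name} axis must be a non-empty 1-D array")
    diffs = np.diff(values)
    if values.size > 1:
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError(f"{name} axis must be strictly monotonic")
        if np.max(np.abs(diffs - diffs[0])) > _AXIS_TOL:
            raise ValidationError(f"{name} axis spacing is not uniform (tol {_AXIS_TOL})")
    if values.min() < lo - _AXIS_TOL or values.max() > hi + _AXIS_TOL:
        raise ValidationError(f"{name} values outside [{lo}, {hi}]")
    return values


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid defined by cell-center coordinates."""

    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        lat = _check_axis("lat", self.lat, -90.0, 90.0)
        lon = np.asarray(self.lon, dtype=float)
        if lon.size and lon.min() >= -180.0 - _AXIS_TOL and lon.max() < 180.0:
            lon = _check_axis("lon", lon, -180.0, 180.0 - 1e-12)
        else:
            lon = _check_axis("lon", lon, 0.0, 360.0 - 1e-12)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        self.lat.flags.writeable = False
        self.lon.flags.writeable = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def nlon(self) -> int:
        return self.lon.size

    def __eq__(self, other) -> bool:  # value equality, tolerant to tiny fp noise
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=_AXIS_TOL)
            and np.allclose(self.lon, other.lon, atol=_AXIS_TOL)
        )

    def __hash__(self) -> int:
        return hash(self.shape)


def _full_mask(shape: tuple[int, ...]) -> np.ndarray:
    return np.ones(shape, dtype=bool)


@dataclass
class GridField:
    """A single 2-D field on a :class:`GridSpec` with units and a land mask."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValidationError("mask shape does not match grid")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValidationError("non-finite values on unmasked cells")

    def masked(self) -> np.ndarray:
        """Values with masked cells set to NaN."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out


@dataclass
class GriddedCube:
    """A time x lat x lon stack of fields sharing one grid and land mask.

    ``time`` holds integer calendar years for annual cubes and
    ``year*100 + month`` codes for monthly cubes (``freq`` records which).
    """

    grid: GridSpec
    values: np.ndarray
    time: np.ndarray
    freq: str = "annual"  # "annual" | "monthly"
    units: str = ""
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=np.int64)
        if self.freq not in ("annual", "monthly"):
            raise ValidationError(f"unknown freq {self.freq!r}")
        if self.values.ndim != 3:
            raise ValidationError("cube values must be 3-D (time, lat, lon)")
        if self.values.shape[0] != self.time.size:
            raise ValidationError("time axis length does not match values")
        if self.values.shape[1:] != self.grid.shape:
            raise ValidationError("cube spatial shape does not match grid")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time axis must be strictly increasing, no duplicates")
        if self.mask is None:
            self.mask = np.all(np.isfinite(self.values), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValidationError("mask shape does not match grid")
        if not np.all(np.isfinite(self.values[:, self.mask])):
            raise ValidationError("non-finite values on unmasked cells")

    @property
    def years(self) -> np.ndarray:
        """Calendar years covered (unique, sorted)."""
        if self.freq == "annual":
            return self.time.copy()
        return np.unique(self.time // 100)

    def select_years(self, years) -> "GriddedCube":
        years = np.asarray(years, dtype=np.int64)
        key = self.time if self.freq == "annual" else self.time // 100
        sel = np.isin(key, years)
        if not sel.any():
            raise ValidationError(f"no time steps in years {years.tolist()}")
        return replace(self, values=self.values[sel], time=self.time[sel])

    def field(self, index: int) -> GridField:
        return GridField(self.grid, self.values[index], units=self.units,
                         mask=self.mask, name=self.name)

    def time_mean(self) -> GridField:
        return GridField(self.grid, self.values.mean(axis=0), units=self.units,
                         mask=self.mask, name=self.name)


@dataclass
class BiomeFractions:
    """Fractional cover per biome class: J x lat x lon, per-cell sum <= 1."""

    grid: GridSpec
    fractions: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 3 or self.fractions.shape[1:] != self.grid.shape:
            raise ValidationError("fractions must be (J, nlat, nlon) on the grid")
        if not self.labels:
            self.labels = [f"biome_{j}" for j in range(self.fractions.shape[0])]
        if len(self.labels) != self.fractions.shape[0]:
            raise ValidationError("label count does not match biome axis")
        if np.nanmin(self.fractions) < -1e-12 or np.nanmax(self.fractions) > 1 + 1e-6:
            raise ValidationError("fractions must lie in [0, 1]")
        sums = np.nansum(self.fractions, axis=0)
        if np.nanmax(sums) > 1 + 1e-6:
            raise ValidationError("per-cell fraction sum exceeds 1")

    @property
    def n_biomes(self) -> int:
        return self.fractions.shape[0]


# ---------------------------------------------------------------------------
# I/O (NetCDF via xarray's scipy backend; CF-style attributes)
# ---------------------------------------------------------------------------

def write_cube(cube: GriddedCube, path: str | Path, variable: str | None = None) -> Path:
    """Write *cube* to a self-describing NetCDF file.

    Masked cells are stored as NaN (`_FillValue`). The time encoding
    (annual years or year-month codes) is recorded in attributes so that
    :func:`read_cube` round-trips exactly.
    """
    path = Path(path)
    varname = variable or cube.name or "value"
    data = cube.values.copy()
    data[:, ~cube.mask] = np.nan
    da = xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={"time": cube.time, "lat": cube.grid.lat, "lon": cube.grid.lon},
        name=varname,
        attrs={"units": cube.units, "long_name": varname, "time_encoding": cube.freq},
    )
    ds = da.to_dataset()
    ds["lat"].attrs.update(units="degrees_north", long_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", long_name="longitude")
    ds["time"].attrs.update(
        units="year" if cube.freq == "annual" else "yearmonth",
        long_name="time",
    )
    try:
        ds.to_netcdf(path, engine="scipy")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path


def read_cube(path: str | Path, variable: str | None = None) -> GriddedCube:
    """Read a gridded cube from NetCDF; missing values become masked cells.

    A 2-D file (no time axis) is promoted to a single-step annual cube.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        if variable is None:
            candidates = [v for v in ds.data_vars if v not in ("lat", "lon", "time")]
            if len(candidates) != 1:
                raise FormatError(
                    f"{path} holds {len(candidates)} variables; pass variable= explicitly"
                )
            variable = candidates[0]
        if variable not in ds.data_vars:
            raise FormatError(f"variable {variable!r} not found in {path}")
        da = ds[variable].load()
    for axis in ("lat", "lon"):
        if axis not in da.coords:
            raise FormatError(f"{path} lacks a {axis!r} coordinate")
    grid = GridSpec(da["lat"].values, da["lon"].values)
    if "time" in da.dims:
        time = np.asarray(da["time"].values, dtype=np.int64)
        values = da.transpose("time", "lat", "lon").values
    else:
        time = np.array([0], dtype=np.int64)
        values = da.values[None, :, :]
    freq = str(da.attrs.get("time_encoding", "annual"))
    mask = np.all(np.isfinite(values), axis=0)
    return GriddedCube(
        grid, values, time, freq=freq,
        units=str(da.attrs.get("units", "")), mask=mask, name=variable,
    )


# ---------------------------------------------------------------------------
# Weights and aggregation
# ---------------------------------------------------------------------------

def area_weights(grid: GridSpec) -> GridField:
    """Relative cell areas, proportional to cos(lat), summing to 1 globally."""
    w = np.cos(np.deg2rad(grid.lat))[:, None] * np.ones((1, grid.nlon))
    w /= w.sum()
    return GridField(grid, w, units="1", name="area_weight")


def aggregate_fractions(fine: BiomeFractions, factor: int) -> BiomeFractions:
    """Coarsen biome fractions by an integer *factor* per axis.

    Each coarse fraction is the area-weighted (cos-lat of the fine cells)
    mean of its factor x factor block, which conserves the area-weighted
    global fraction of every class exactly.
    """
    if factor < 1 or not isinstance(factor, (int, np.integer)):
        raise ValidationError("factor must be a positive integer")
    nlat, nlon = fine.grid.shape
    if nlat % factor or nlon % factor:
        raise ValidationError(
            f"grid {nlat}x{nlon} not divisible by aggregation factor {factor}"
        )
    w = np.cos(np.deg2rad(fine.grid.lat))[:, None] * np.ones((1, nlon))
    J = fine.n_biomes
    cl, cn = nlat // factor, nlon // factor
    wb = w.reshape(cl, factor, cn, factor)
    wsum = wb.sum(axis=(1, 3))
    coarse = np.empty((J, cl, cn))
    for j in range(J):
        fj = (fine.fractions[j] * w).reshape(cl, factor, cn, factor).sum(axis=(1, 3))
        coarse[j] = fj / wsum
    lat = fine.grid.lat.reshape(cl, factor).mean(axis=1)
    lon = fine.grid.lon.reshape(cn, factor).mean(axis=1)
    return BiomeFractions(GridSpec(lat, lon), coarse, labels=list(fine.labels))


_MONTH_RULES = {"sum": np.sum, "mean": np.mean}


def to_annual(cube: GriddedCube, method: str = "sum") -> GriddedCube:
    """Collapse a monthly cube to annual fields.

    ``"sum"`` for fluxes (GPP, P, ET), ``"mean"`` for state-like
    quantities (SIF, temperature). Every year must have all 12 months.
    """
    if method not in _MONTH_RULES:
        raise ValidationError(f"method must be 'sum' or 'mean', got {method!r}")
    if cube.freq != "monthly":
        raise ValidationError("to_annual expects a monthly cube")
    years = np.unique(cube.time // 100)
    missing: dict[int, list[int]] = {}
    for y in years:
        months = sorted(cube.time[cube.time // 100 == y] % 100)
        gap = sorted(set(range(1, 13)) - set(int(m) for m in months))
        if gap:
            missing[int(y)] = gap
    if missing:
        raise ValidationError(f"partial years, missing months: {missing}")
    out = np.empty((years.size,) + cube.grid.shape)
    for k, y in enumerate(years):
        sel = cube.time // 100 == y
        out[k] = _MONTH_RULES[method](cube.values[sel], axis=0)
    units = cube.units
    if method == "sum":
        units = units.replace("month-1", "yr-1") if "month-1" in units else units
    return GriddedCube(cube.grid, out, years, freq="annual", units=units,
                       mask=cube.mask, name=cube.name)


_CARBON_UNITS = {"g C m-2 yr-1"}
_WATER_UNITS = {"mm yr-1"}


def global_total(
    field_: GridField,
    weights: GridField | None = None,
    earth_area: float = EARTH_LAND_AREA_M2,
    petagrams: bool = False,
) -> float:
    """Area-weighted land integral of a per-area field.

    ``earth_area`` is the total area (m^2) represented by the whole grid;
    each cell contributes ``value * weight * earth_area``. With
    ``petagrams=True`` a g C m-2 yr-1 field is returned in Pg C yr-1.
    """
    canon = canonical_units(field_.units)
    if canon not in _CARBON_UNITS | _WATER_UNITS:
        raise UnitsError(
            f"global_total expects g C m-2 yr-1 or mm yr-1, got {field_.units!r}"
        )
    if petagrams and canon not in _CARBON_UNITS:
        raise UnitsError("petagrams conversion only applies to carbon fluxes")
    if weights is None:
        weights = area_weights(field_.grid)
    m = field_.mask
    total = float(np.sum(field_.values[m] * weights.values[m]) * earth_area)
    return total / GRAMS_PER_PETAGRAM if petagrams else total
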