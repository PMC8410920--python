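"""Gridded processing chain: forcing NetCDF in, daily index NetCDF out.

The six steps, in order: (1) regrid the coarse direct-beam radiation to
the fine grid (nearest neighbour, value-preserving); (2) de-accumulate
the radiation variables to hourly increments; (3) convert to W m-2
fluxes; (4) compute the mean radiant temperature; (5) compute the twelve
thermal indices hourly; (6) reduce to daily mean/max/min and write one
NetCDF file per UTC day, named ``HiTiSEA_YYYY-MM-DD.nc``, 36 variables
(``<Index>_mean/_max/_min``), fill value -32767.

Time dialect: hourly timestamps 00..23 UTC; a value stamped ``t`` refers
to the interval [t, t+1).  Fine-grid radiation follows the since-daily-
reset accumulation convention (``era5land``); the coarse direct beam is a
per-step accumulation (``era5``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from thermidx import indices as idx
from thermidx import meteo
from thermidx.mrt import BodyRadiationConstants, DEFAULT_CONSTANTS, mean_radiant_temperature
from thermidx.radiation import ClipCounter, deaccumulate, decompose_fluxes, to_flux
from thermidx.solar import mean_cos_zenith, projected_area_factor

__all__ = ["GridSpec", "regrid_nearest", "compute_hour", "daily_summary",
           "write_daily_netcdf", "run_pipeline", "FILL_VALUE", "FILE_PREFIX"]

logger = logging.getLogger(__name__)

FILL_VALUE = -32767
FILE_PREFIX = "HiTiSEA"

#: accepted aliases for the nine forcing variables
VARIABLE_ALIASES = {
    "t2m": ("t2m", "Ta", "temperature_2m"),
    "d2m": ("d2m", "Td", "dewpoint_2m"),
    "u10": ("u10", "u"),
    "v10": ("v10", "v"),
    "ssrd": ("ssrd",),
    "ssr": ("ssr",),
    "strd": ("strd",),
    "str": ("str", "str_"),
    "fdir": ("fdir",),
}


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid (cell centers, monotone ascending)."""

    lat: np.ndarray
    lon: np.ndarray

    @classmethod
    def from_bbox(cls, lon_min, lon_max, lat_min, lat_max, resolution):
        lon = np.round(np.arange(lon_min, lon_max + resolution / 2, resolution), 6)
        lat = np.round(np.arange(lat_min, lat_max + resolution / 2, resolution), 6)
        return cls(lat=lat, lon=lon)

    @classmethod
    def from_dataset(cls, ds: xr.Dataset):
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        return cls(lat=lat, lon=lon)

    @property
    def shape(self):
        return (len(self.lat), len(self.lon))

    def meshgrid(self):
        return np.meshgrid(self.lat, self.lon, indexing="ij")


def _nearest_index(centers: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index of the nearest center for each target; ties -> lower index."""
    centers = np.asarray(centers, dtype=float)
    targets = np.asarray(targets, dtype=float)
    pos = np.searchsorted(centers, targets)
    pos = np.clip(pos, 1, len(centers) - 1)
    lo, hi = centers[pos - 1], centers[pos]
    # strictly closer to the upper center -> upper; ties stay at the lower
    choose_hi = (targets - lo) > (hi - targets)
    out = np.where(choose_hi, pos, pos - 1)
    return np.where(targets <= centers[0], 0, out)


def regrid_nearest(coarse_field, coarse_grid: GridSpec, fine_grid: GridSpec):
    """Nearest-neighbour regridding from a coarse to a fine regular grid.

    Each fine cell takes the value of the coarse cell whose center is
    nearest in plain lat/lon coordinates (separable on regular grids);
    equidistant cases resolve toward the lower index.  Values are copied,
    never interpolated, so the output value set is a subset of the input's.
    """
    if (fine_grid.lat[0] < coarse_grid.lat[0] - 1e-9
            or fine_grid.lat[-1] > coarse_grid.lat[-1] + 1e-9
            or fine_grid.lon[0] < coarse_grid.lon[0] - 1e-9
            or fine_grid.lon[-1] > coarse_grid.lon[-1] + 1e-9):
        raise ValueError("fine grid extends outside coarse grid coverage")
    field = np.asarray(coarse_field, dtype=float)
    ilat = _nearest_index(coarse_grid.lat, fine_grid.lat)
    ilon = _nearest_index(coarse_grid.lon, fine_grid.lon)
    return field[..., ilat[:, None], ilon[None, :]]


def nearest_cell_map(coarse_grid: GridSpec, fine_grid: GridSpec):
    """(ilat, ilon) arrays mapping each fine cell to its nearest coarse cell."""
    return (_nearest_index(coarse_grid.lat, fine_grid.lat),
            _nearest_index(coarse_grid.lon, fine_grid.lon))


def compute_hour(forcing: dict, grid: GridSpec, time_utc: datetime, *,
                 const: BodyRadiationConstants = DEFAULT_CONSTANTS,
                 n_substeps: int = 60, clips: ClipCounter | None = None,
                 qc: idx.QCMask | None = None) -> dict:
    """All twelve index fields for one hourly interval [t, t+1).

    ``forcing`` maps canonical names (t2m, d2m, u10, v10 plus the five
    radiation variables as W m-2 fluxes on the fine grid) to 2-D arrays.
    Returns a dict index-name -> 2-D array (degC).
    """
    missing = [k for k in VARIABLE_ALIASES if k not in forcing]
    if missing:
        raise KeyError(f"forcing is missing variables: {missing}")

    lat2d, lon2d = grid.meshgrid()
    mu = mean_cos_zenith(np.deg2rad(lat2d), lon2d, time_utc,
                         time_utc + timedelta(hours=1), n_substeps=n_substeps)
    # f_p from the interval-mean sun position; irrelevant where the beam is 0
    theta_bar = np.arccos(np.clip(mu, 0.0, 1.0))
    f_p = projected_area_factor(theta_bar)

    rad = decompose_fluxes(forcing["ssrd"], forcing["ssr"], forcing["strd"],
                           forcing["str"], forcing["fdir"], mu)
    if clips is not None:
        clips.update(rad.clips)

    Ta_c = meteo.celsius(forcing["t2m"])
    e = meteo.vapor_pressure_from_dewpoint(forcing["d2m"])
    RH = meteo.relative_humidity(forcing["t2m"], forcing["d2m"])
    Va10 = meteo.wind_speed(forcing["u10"], forcing["v10"])
    Va12 = meteo.wind_at_height(Va10, 1.2)
    SR = np.asarray(forcing["ssrd"], dtype=float)

    mrt_field = mean_radiant_temperature(rad, f_p, const)
    return {
        "UTCI": idx.utci(Ta_c, Va10, e, mrt_field, qc=qc),
        "UTCI3": idx.utci_outdoor_shaded(Ta_c, Va10, e, qc=qc),
        "UTCI2": idx.utci_indoor(Ta_c, e, qc=qc),
        "AT": idx.apparent_temperature(Ta_c, e, Va10),
        "ESI": idx.environment_stress_index(Ta_c, RH, SR),
        "HI": idx.heat_index(Ta_c, RH),
        "Humidex": idx.humidex(Ta_c, e),
        "MRT": mrt_field,
        "NET": idx.net_effective_temperature(Ta_c, RH, Va12),
        "WBT": idx.wbt_stull(Ta_c, RH, qc=qc),
        "WBGT": idx.wbgt_simplified(Ta_c, e),
        "WCT": idx.wind_chill_temperature(Ta_c, Va10),
    }


def daily_summary(hours: list[dict], date) -> dict:
    """Cellwise mean/max/min over the 24 hourly index fields of one day.

    A cell missing (NaN) at any hour carries NaN in all three statistics
    (conservative poisoning); NaNs become the fill value at write time.
    Returns ``{"date": date, "<Index>_mean": ..., "_max": ..., "_min": ...}``.
    """
    if len(hours) != 24:
        raise ValueError(f"need exactly 24 hourly field sets, got {len(hours)}")
    out = {"date": date}
    for name in idx.INDEX_NAMES:
        stack = np.stack([h[name] for h in hours])
        out[f"{name}_mean"] = stack.mean(axis=0)
        out[f"{name}_max"] = stack.max(axis=0)
        out[f"{name}_min"] = stack.min(axis=0)
    return out


def write_daily_netcdf(summary: dict, out_dir, grid: GridSpec, *,
                       lossless: bool = False) -> Path:
    """Write one day's summary as ``HiTiSEA_YYYY-MM-DD.nc``.

    Default encoding is int16 with a 0.01 degC scale factor and fill value
    -32767; ``lossless=True`` stores float64 (fill value kept).
    """
    date = summary["date"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{FILE_PREFIX}_{date:%Y-%m-%d}.nc"

    data_vars = {}
    encoding = {}
    for name in idx.INDEX_NAMES:
        for stat in ("mean", "max", "min"):
            var = f"{name}_{stat}"
            data_vars[var] = (("lat", "lon"), np.asarray(summary[var], dtype=float),
                              {"units": "degC", "long_name": f"daily {stat} {name}"})
            if lossless:
                encoding[var] = {"_FillValue": float(FILL_VALUE)}
            else:
                encoding[var] = {"dtype": "int16", "scale_factor": 0.01,
                                 "add_offset": 0.0, "_FillValue": FILL_VALUE}
    ds = xr.Dataset(
        data_vars,
        coords={"lat": ("lat", grid.lat, {"units": "degrees_north"}),
                "lon": ("lon", grid.lon, {"units": "degrees_east"})},
        attrs={"date": f"{date:%Y-%m-%d}"},
    )
    ds.to_netcdf(path, engine="scipy", encoding=encoding)
    return path


def _resolve_variables(ds: xr.Dataset, needed) -> dict:
    found = {}
    for canon in needed:
        for alias in VARIABLE_ALIASES[canon]:
            if alias in ds:
                found[canon] = ds[alias]
                break
        else:
            raise KeyError(f"input dataset is missing required variable {canon!r} "
                           f"(accepted aliases: {VARIABLE_ALIASES[canon]})")
    return found


_FINE_VARS = ("t2m", "d2m", "u10", "v10", "ssrd", "ssr", "strd", "str")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config) -> list[Path]:
    """Execute the whole chain per the configuration; one output file per day.

    ``config`` is a dict (or YAML path) with keys: ``fine_forcing`` and
    ``fdir_forcing`` (NetCDF paths), ``output_dir``, optional ``dates``
    (list/range of YYYY-MM-DD strings; default: all complete days found),
    ``kelvin_offset`` (273.5 default), ``lossless`` (bool), ``n_substeps``.
    A day failing any stage is logged and skipped; other days proceed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    fine = xr.open_dataset(config["fine_forcing"], engine="scipy")
    coarse = xr.open_dataset(config["fdir_forcing"], engine="scipy")
    out_dir = Path(config["output_dir"])
    const = BodyRadiationConstants(kelvin_offset=float(config.get("kelvin_offset", 273.5)))
    n_substeps = int(config.get("n_substeps", 60))
    lossless = bool(config.get("lossless", False))

    fine_vars = _resolve_variables(fine, _FINE_VARS)
    fdir_var = _resolve_variables(coarse, ("fdir",))["fdir"]
    grid = GridSpec.from_dataset(fine)
    coarse_grid = GridSpec.from_dataset(coarse)

    times = pd.to_datetime(fine["time"].values)
    by_day: dict = {}
    for i, t in enumerate(times):
        by_day.setdefault(t.normalize(), []).append(i)
    wanted = config.get("dates")
    if wanted is not None:
        wanted = {pd.Timestamp(d) for d in wanted}

    # step 1: regrid the coarse direct beam; step 2-3: de-accumulate to fluxes
    fdir_fine = regrid_nearest(fdir_var.values, coarse_grid, grid)
    clips = ClipCounter()
    fdir_flux = to_flux(deaccumulate(fdir_fine, "era5", clips=clips))
    rad_flux = {v: to_flux(deaccumulate(fine_vars[v].values, "era5land",
                                        non_negative=(v != "str"), clips=clips))
                for v in ("ssrd", "ssr", "strd", "str")}

    paths = []
    for day, hour_idx in sorted(by_day.items()):
        if wanted is not None and day not in wanted:
            continue
        try:
            if len(hour_idx) != 24:
                raise ValueError(f"day {day.date()} has {len(hour_idx)} hours, need 24")
            qc = idx.QCMask()
            fields = []
            for i in hour_idx:
                forcing = {v: fine_vars[v].values[i] for v in ("t2m", "d2m", "u10", "v10")}
                forcing.update({v: rad_flux[v][i] for v in ("ssrd", "ssr", "strd", "str")})
                forcing["fdir"] = fdir_flux[i]
                fields.append(compute_hour(forcing, grid, times[i].to_pydatetime(),
                                           const=const, n_substeps=n_substeps,
                                           clips=clips, qc=qc))
            summary = daily_summary(fields, day.date())
            paths.append(write_daily_netcdf(summary, out_dir, grid, lossless=lossless))
            logger.info("day %s written (clips so far: %d, UTCI/WBT clamps: %d)",
                        day.date(), clips.total(), qc.n_clamped)
        except Exception:
            logger.exception("day %s failed; continuing with remaining days", day.date())
    fine.close()
    coarse.close()
    run_pipeline.last_clips = clips  # exposed for diagnostics
    return paths
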