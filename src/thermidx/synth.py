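"""Seeded generator of reanalysis-like hourly forcing and station records.

Emulates the structure of an ERA5-Land-style product on a fine regular
grid (plus a coarser grid for the direct solar beam) with physically
consistent fields:

* a diurnal temperature cycle phased to local solar time, with a smooth
  spatial anomaly field;
* dewpoint always at or below air temperature;
* shortwave radiation following the clear-sky diurnal shape driven by the
  solar geometry, attenuated by a smooth cloud-transmittance field, with
  0 <= fdir <= ssrd, surface albedo (=(ssrd-ssr)/ssrd) in [0.12, 0.30];
* longwave from a sky-emissivity closure, upwelling from a
  Stefan-Boltzmann surface term, so strd > 0 and strd - str > 0;
* radiation stored as accumulations: since-daily-reset on the fine grid,
  per-step on the coarse direct-beam grid.

The coarse direct beam is built as the minimum of the fine-cell direct
beam over each coarse cell's nearest-neighbour footprint, so the
regridded beam can never exceed the local global shortwave — generated
forcing passes the flux-decomposition preconditions with zero clips.

Matching station records (3-hourly synoptic CSV with configurable
Gaussian noise and missingness) are drawn from the same fields.  Output
is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from thermidx.mrt import SIGMA
from thermidx.pipeline import GridSpec, nearest_cell_map
from thermidx.solar import mean_cos_zenith

__all__ = ["SynthConfig", "generate_forcing", "generate_stations"]

_SYNOPTIC_HOURS = (0, 3, 6, 9, 12, 15, 18, 21)


@dataclass
class SynthConfig:
    """Synthetic-domain configuration; the seed fully determines output."""

    bbox: tuple = (110.0, 112.0, 29.0, 31.0)  # lon_min, lon_max, lat_min, lat_max
    fine_resolution: float = 0.1
    coarse_resolution: float = 0.25
    start: str = "2018-07-01"
    n_days: int = 2
    seed: int = 0
    mean_temperature: float = 24.0     # degC at the southern edge
    lapse_per_degree_lat: float = 0.25  # degC per degree latitude
    diurnal_amplitude: float = 5.0     # degC
    noise_temperature: float = 0.0     # degC, station obs noise
    noise_wind: float = 0.0            # m/s
    noise_dewpoint: float = 0.0        # degC
    n_stations: int = 10
    station_placement: str = "cell_centers"  # or "random" (jittered positions)
    missing_fraction: float = 0.0
    surface_pressure: float = 1013.25  # hPa, constant filler for station files

    def fine_grid(self) -> GridSpec:
        return GridSpec.from_bbox(*self.bbox, self.fine_resolution)

    def coarse_grid(self) -> GridSpec:
        lon_min, lon_max, lat_min, lat_max = self.bbox
        r = self.coarse_resolution
        # expand by one coarse cell so the fine grid is strictly covered
        return GridSpec.from_bbox(lon_min - r, lon_max + r, lat_min - r, lat_max + r, r)

    def times(self):
        t0 = datetime.fromisoformat(self.start)
        return [t0 + timedelta(hours=h) for h in range(24 * self.n_days)]


def _smooth_field(rng, shape, lo, hi, sigma=3.0):
    """Seeded smooth random field mapped onto [lo, hi]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


def generate_forcing(cfg: SynthConfig, out_dir) -> dict:
    """Write fine-grid forcing and coarse-grid direct beam as NetCDF.

    Returns ``{"fine": path, "fdir": path}``; deterministic for a seed.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.fine_grid()
    cgrid = cfg.coarse_grid()
    lat2d, lon2d = grid.meshgrid()
    nlat, nlon = grid.shape
    times = cfg.times()

    t_anom = _smooth_field(rng, (nlat, nlon), -1.5, 1.5)
    dew_dep = _smooth_field(rng, (nlat, nlon), 2.0, 6.0)      # dewpoint depression
    cloud = _smooth_field(rng, (nlat, nlon), 0.3, 1.0)        # transmittance factor
    diffuse_frac = 0.25 + 0.5 * (1.0 - cloud)                 # in [0.25, 0.60]
    albedo = _smooth_field(rng, (nlat, nlon), 0.12, 0.30)
    u_field = _smooth_field(rng, (nlat, nlon), 0.8, 4.0)
    v_field = _smooth_field(rng, (nlat, nlon), -2.0, 2.0)

    base = (cfg.mean_temperature
            - cfg.lapse_per_degree_lat * (lat2d - cfg.bbox[2]) + t_anom)

    ilat_map, ilon_map = nearest_cell_map(cgrid, grid)

    nt = len(times)
    shape = (nt, nlat, nlon)
    t2m = np.empty(shape)
    flux = {v: np.empty(shape) for v in ("ssrd", "ssr", "strd", "str")}
    fdir_fine = np.empty(shape)

    for i, t in enumerate(times):
        solar_hour = (t.hour + t.minute / 60.0 + lon2d / 15.0) % 24.0
        ta_c = base + cfg.diurnal_amplitude * np.sin(2 * np.pi * (solar_hour - 9.0) / 24.0)
        ta_k = ta_c + 273.15
        t2m[i] = ta_k

        mu = mean_cos_zenith(np.deg2rad(lat2d), lon2d, t, t + timedelta(hours=1))
        ssrd = np.where(mu > 0.015, 950.0 * mu * 0.75 * cloud, 0.0)
        fdir_fine[i] = (1.0 - diffuse_frac) * ssrd
        flux["ssrd"][i] = ssrd
        flux["ssr"][i] = (1.0 - albedo) * ssrd
        eps_sky = 0.95 - 0.25 * cloud
        strd = eps_sky * SIGMA * ta_k ** 4
        u_lw = 0.97 * SIGMA * (ta_k + 1.0) ** 4
        flux["strd"][i] = strd
        flux["str"][i] = strd - u_lw

    d2m = t2m - dew_dep[None, :, :]

    # coarse direct beam: minimum over each coarse cell's fine footprint,
    # grouped by the same nearest-neighbour map the pipeline regrids with
    nclat, nclon = cgrid.shape
    fdir_coarse = np.zeros((nt, nclat, nclon))
    flat_group = ilat_map[:, None] * nclon + ilon_map[None, :]
    order = np.argsort(flat_group.ravel(), kind="stable")
    groups, starts = np.unique(flat_group.ravel()[order], return_index=True)
    for i in range(nt):
        vals = fdir_fine[i].ravel()[order]
        mins = np.minimum.reduceat(vals, starts)
        fdir_coarse[i].ravel()[groups] = mins

    # accumulations: fine radiation since daily reset, coarse beam per step
    acc = {}
    for v in ("ssrd", "ssr", "strd", "str"):
        a = flux[v] * 3600.0
        for d in range(cfg.n_days):
            sl = slice(24 * d, 24 * (d + 1))
            a[sl] = np.cumsum(a[sl], axis=0)
        acc[v] = a
    fdir_acc = fdir_coarse * 3600.0

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    time_coord = np.array(times, dtype="datetime64[s]")

    fine_ds = xr.Dataset(
        {"t2m": (("time", "lat", "lon"), t2m, {"units": "K"}),
         "d2m": (("time", "lat", "lon"), d2m, {"units": "K"}),
         "u10": (("time", "lat", "lon"), np.broadcast_to(u_field, shape).copy(),
                 {"units": "m s-1"}),
         "v10": (("time", "lat", "lon"), np.broadcast_to(v_field, shape).copy(),
                 {"units": "m s-1"}),
         **{v: (("time", "lat", "lon"), acc[v], {"units": "J m-2"})
            for v in ("ssrd", "ssr", "strd", "str")}},
        coords={"time": time_coord, "lat": grid.lat, "lon": grid.lon},
    )
    fdir_ds = xr.Dataset(
        {"fdir": (("time", "lat", "lon"), fdir_acc, {"units": "J m-2"})},
        coords={"time": time_coord, "lat": cgrid.lat, "lon": cgrid.lon},
    )
    fine_path = out_dir / "forcing_fine.nc"
    fdir_path = out_dir / "forcing_fdir.nc"
    fine_ds.to_netcdf(fine_path, engine="scipy")
    fdir_ds.to_netcdf(fdir_path, engine="scipy")
    return {"fine": fine_path, "fdir": fdir_path}


def generate_stations(cfg: SynthConfig, forcing_fine_path, out_csv) -> Path:
    """Sample noisy 3-hourly station observations from the forcing fields.

    Stations sit at fine-grid cell centers (or jittered inside the cell
    with ``station_placement="random"``).  Observations are the collocated
    forcing at synoptic hours plus Gaussian noise; with
    ``missing_fraction > 0`` a random meteorological field is blanked in
    that share of records to exercise the downstream exclusion rule.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ds = xr.open_dataset(forcing_fine_path, engine="scipy")
    grid = GridSpec.from_dataset(ds)
    nlat, nlon = grid.shape

    cells = rng.choice(nlat * nlon, size=cfg.n_stations, replace=False)
    ilat, ilon = np.unravel_index(cells, (nlat, nlon))
    lat = grid.lat[ilat]
    lon = grid.lon[ilon]
    if cfg.station_placement == "random":
        lat = lat + rng.uniform(-0.4, 0.4, cfg.n_stations) * np.diff(grid.lat).mean()
        lon = lon + rng.uniform(-0.4, 0.4, cfg.n_stations) * np.diff(grid.lon).mean()

    times = pd.to_datetime(ds["time"].values)
    synoptic = [i for i, t in enumerate(times) if t.hour in _SYNOPTIC_HOURS]

    rows = []
    for s in range(cfg.n_stations):
        for i in synoptic:
            ta = float(ds["t2m"].values[i, ilat[s], ilon[s]]) - 273.15
            td = float(ds["d2m"].values[i, ilat[s], ilon[s]]) - 273.15
            va = float(np.hypot(ds["u10"].values[i, ilat[s], ilon[s]],
                                ds["v10"].values[i, ilat[s], ilon[s]]))
            ta += rng.normal(0.0, cfg.noise_temperature) if cfg.noise_temperature else 0.0
            td += rng.normal(0.0, cfg.noise_dewpoint) if cfg.noise_dewpoint else 0.0
            td = min(td, ta)
            va = max(va + (rng.normal(0.0, cfg.noise_wind) if cfg.noise_wind else 0.0), 0.0)
            rows.append({"station_id": f"S{s:04d}", "lat": lat[s], "lon": lon[s],
                         "time": times[i].isoformat(), "Ta": ta, "Td": td,
                         "Va10": va, "P": cfg.surface_pressure})
    ds.close()
    df = pd.DataFrame(rows)
    if cfg.missing_fraction > 0:
        hit = rng.random(len(df)) < cfg.missing_fraction
        which = rng.integers(0, 4, len(df))
        for k, col in enumerate(("Ta", "Td", "Va10", "P")):
            df.loc[hit & (which == k), col] = np.nan
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    return out_csv
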