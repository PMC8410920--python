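"""Station-versus-grid validation: RMSE and bias per station and period.

Stations report 3-hourly synoptic observations of air temperature,
dewpoint, 10-m wind and surface pressure.  The nine indices that need no
radiation input (indoor and outdoor-shaded UTCI, HI, Humidex, WBGT, WBT,
WCT, AT, NET) are computed from the observations and compared with the
same indices computed from the gridded forcing at the nearest grid cell
and the same instants.  Scores are

    rmse = sqrt(mean((pred - obs)^2)),   bias = mean(pred - obs)

with pred the grid-derived and obs the station-derived value, summarized
per station and month or year (yearly scores pool all pairs rather than
averaging monthly RMSEs).  Surface pressure is ingested for completeness
of the record-exclusion rule but enters no index formula.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from thermidx import indices as idx
from thermidx import meteo
from thermidx.pipeline import GridSpec, _nearest_index

__all__ = ["NONRADIATION_INDICES", "match_station", "load_stations",
           "station_indices", "grid_indices_at_stations", "pair_max_radiation",
           "score", "build_pairs", "summarize", "export_scores"]

logger = logging.getLogger(__name__)

#: The nine indices computable from (Ta, Td, Va) alone.
NONRADIATION_INDICES = ("UTCI2", "UTCI3", "HI", "Humidex", "WBGT",
                        "WBT", "WCT", "AT", "NET")

_REQUIRED = ("Ta", "Td", "Va10", "P")


def match_station(lat, lon, grid: GridSpec):
    """(ilat, ilon) of the nearest grid-cell center; ties -> lower index.

    Raises for stations outside the grid bounding box (callers exclude
    and log them).
    """
    half_lat = np.diff(grid.lat).mean() / 2 if len(grid.lat) > 1 else 0.5
    half_lon = np.diff(grid.lon).mean() / 2 if len(grid.lon) > 1 else 0.5
    if not (grid.lat[0] - half_lat <= lat <= grid.lat[-1] + half_lat
            and grid.lon[0] - half_lon <= lon <= grid.lon[-1] + half_lon):
        raise ValueError(f"station ({lat}, {lon}) outside grid bbox")
    return (int(_nearest_index(grid.lat, np.array([lat]))[0]),
            int(_nearest_index(grid.lon, np.array([lon]))[0]))


def load_stations(csv_path, column_map: dict | None = None) -> pd.DataFrame:
    """Read station records; exclude rows missing any required variable.

    Expected columns: station_id, lat, lon, time, Ta, Td, Va10, P (rename
    via ``column_map``).  Records missing any of Ta/Td/Va10/P are dropped
    (the exclusion rule), with a log line giving the count.
    """
    df = pd.read_csv(csv_path)
    if column_map:
        df = df.rename(columns=column_map)
    df["time"] = pd.to_datetime(df["time"])
    n0 = len(df)
    df = df.dropna(subset=list(_REQUIRED)).reset_index(drop=True)
    if len(df) < n0:
        logger.info("load_stations: excluded %d incomplete records of %d", n0 - len(df), n0)
    return df


def _indices_from_met(Ta_c, Td_c, Va10):
    """The nine non-radiation indices from degC temperatures and m/s wind."""
    Ta_k = np.asarray(Ta_c, dtype=float) + 273.15
    Td_k = np.asarray(Td_c, dtype=float) + 273.15
    e = meteo.vapor_pressure_from_dewpoint(Td_k)
    RH = meteo.relative_humidity(Ta_k, Td_k)
    Va12 = meteo.wind_at_height(np.asarray(Va10, dtype=float), 1.2)
    Ta_c = np.asarray(Ta_c, dtype=float)
    return {
        "UTCI2": idx.utci_indoor(Ta_c, e),
        "UTCI3": idx.utci_outdoor_shaded(Ta_c, Va10, e),
        "HI": idx.heat_index(Ta_c, RH),
        "Humidex": idx.humidex(Ta_c, e),
        "WBGT": idx.wbgt_simplified(Ta_c, e),
        "WBT": idx.wbt_stull(Ta_c, RH),
        "WCT": idx.wind_chill_temperature(Ta_c, Va10),
        "AT": idx.apparent_temperature(Ta_c, e, Va10),
        "NET": idx.net_effective_temperature(Ta_c, RH, Va12),
    }


def station_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Append the nine observation-derived index columns to station records."""
    vals = _indices_from_met(records["Ta"].values, records["Td"].values,
                             records["Va10"].values)
    out = records.copy()
    for name in NONRADIATION_INDICES:
        out[name] = vals[name]
    return out


def grid_indices_at_stations(forcing_fine_path, stations: pd.DataFrame) -> pd.DataFrame:
    """Grid-derived indices at each station's nearest cell and instants.

    Opens the fine forcing, matches each station to its cell, extracts
    Ta/Td/u/v at the station's observation times, and computes the nine
    non-radiation indices through the same formulas.
    """
    ds = xr.open_dataset(forcing_fine_path, engine="scipy")
    grid = GridSpec.from_dataset(ds)
    times = pd.to_datetime(ds["time"].values)
    time_index = pd.Series(np.arange(len(times)), index=times)

    rows = []
    for (sid, lat, lon), sub in stations.groupby(["station_id", "lat", "lon"], sort=True):
        try:
            ilat, ilon = match_station(lat, lon, grid)
        except ValueError:
            logger.info("grid_indices_at_stations: station %s outside grid, excluded", sid)
            continue
        ti = time_index.reindex(sub["time"]).values
        ok = ~pd.isna(ti)
        if not ok.all():
            logger.info("station %s: %d instants not in forcing, dropped", sid, int((~ok).sum()))
        sub = sub.loc[ok.tolist()]
        ti = ti[ok].astype(int)
        ta = ds["t2m"].values[ti, ilat, ilon] - 273.15
        td = ds["d2m"].values[ti, ilat, ilon] - 273.15
        va = np.hypot(ds["u10"].values[ti, ilat, ilon], ds["v10"].values[ti, ilat, ilon])
        vals = _indices_from_met(ta, td, va)
        frame = pd.DataFrame({"station_id": sid, "lat": lat, "lon": lon,
                              "time": sub["time"].values})
        for name in NONRADIATION_INDICES:
            frame[name] = np.atleast_1d(vals[name])
        rows.append(frame)
    ds.close()
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def pair_max_radiation(daily_rad: pd.DataFrame, synoptic: pd.DataFrame) -> pd.DataFrame:
    """Attach each day's maximum-radiation value to a synoptic record.

    ``daily_rad`` carries one row per station-day with the maximum global
    radiation flux (``SR_max``, W m-2) and the time it occurred
    (``time_of_max``); the time is rounded to the nearest 3-hour synoptic
    instant and joined against the synoptic records.  Days without a
    matching synoptic record (or with missing fields) are dropped and
    counted.
    """
    rad = daily_rad.copy()
    rad["time_of_max"] = pd.to_datetime(rad["time_of_max"])
    rad["synoptic_time"] = rad["time_of_max"].dt.round("3h")
    rad = rad.dropna(subset=["SR_max"])
    merged = rad.merge(synoptic, left_on=["station_id", "synoptic_time"],
                       right_on=["station_id", "time"], how="inner")
    merged = merged.dropna(subset=[c for c in _REQUIRED if c in merged.columns])
    n_dropped = len(rad) - len(merged)
    if n_dropped:
        logger.info("pair_max_radiation: dropped %d of %d daily records without "
                    "a complete synoptic match", n_dropped, len(rad))
    return merged.reset_index(drop=True)


def score(pred, obs):
    """(rmse, bias) of predicted minus observed, both in degC."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size == 0:
        raise ValueError("cannot score an empty pair set")
    d = pred - obs
    return float(np.sqrt(np.mean(d ** 2))), float(np.mean(d))


def build_pairs(forcing_fine_path, stations_csv, column_map=None) -> pd.DataFrame:
    """Aligned (pred, obs) pairs for the nine indices, long format."""
    obs = station_indices(load_stations(stations_csv, column_map))
    pred = grid_indices_at_stations(forcing_fine_path, obs)
    merged = obs.merge(pred, on=["station_id", "lat", "lon", "time"],
                       suffixes=("_obs", "_pred"))
    rows = []
    for name in NONRADIATION_INDICES:
        rows.append(pd.DataFrame({
            "station_id": merged["station_id"], "lat": merged["lat"],
            "lon": merged["lon"], "time": merged["time"], "index": name,
            "obs": merged[f"{name}_obs"], "pred": merged[f"{name}_pred"]}))
    return pd.concat(rows, ignore_index=True)


def summarize(pairs: pd.DataFrame, by: str = "month") -> pd.DataFrame:
    """Per-station, per-period RMSE/bias table (one row per station-period).

    ``by`` is "month" or "year"; yearly statistics are recomputed on the
    pooled pairs of the year, not averaged over months.  Empty periods do
    not appear.
    """
    if by == "month":
        period = pairs["time"].dt.to_period("M").astype(str)
    elif by == "year":
        period = pairs["time"].dt.year.astype(str)
    else:
        raise ValueError("by must be 'month' or 'year'")
    work = pairs.assign(period=period)
    rows = {}
    for (sid, per, name), sub in work.groupby(["station_id", "period", "index"], sort=True):
        rmse, bias = score(sub["pred"], sub["obs"])
        key = (sid, per)
        rows.setdefault(key, {"station_id": sid, "period": per,
                              "lon": sub["lon"].iloc[0], "lat": sub["lat"].iloc[0],
                              "n_pairs": 0})
        rows[key][f"{name}_rmse"] = rmse
        rows[key][f"{name}_bias"] = bias
        rows[key]["n_pairs"] = max(rows[key]["n_pairs"], len(sub))
    return pd.DataFrame(list(rows.values()))


def export_scores(table: pd.DataFrame, out_dir) -> list[Path]:
    """Write one tab-separated file per period (plain-text archive layout)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for per, sub in table.groupby("period", sort=True):
        p = out_dir / f"validation_{per}.tsv"
        sub.drop(columns="period").to_csv(p, sep="\t", index=False, float_format="%.4f")
        paths.append(p)
    return paths
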