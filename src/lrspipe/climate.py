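"""Thermal-discomfort exposure from daily weather-station summaries.

Daily station records (maximum air temperature and dewpoint, both degC)
are converted to a minimum relative humidity via the Magnus formula and
then to a maximum temperature-humidity index (THI_max), the standard
scalar used to quantify heat stress in dairy cattle:

    THI_max = 0.8 * T + RH/100 * (T - 14.4) + 46.4

with T the daily maximum temperature and RH the minimum relative
humidity of the day.  Station-years with more than 10% of calendar days
missing are dropped (or merely flagged, for single-station research-herd
data).  Farms are matched to their nearest station by great-circle
distance and exposures are summarised as arithmetic means of THI_max
over closed date intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rh_from_dewpoint",
    "thi_max",
    "add_thi",
    "station_completeness",
    "qc_stations",
    "haversine_km",
    "match_nearest_station",
    "mean_thi",
]

_EARTH_RADIUS_KM = 6371.0088


def rh_from_dewpoint(dewpoint, t_max):
    """Minimum relative humidity (%) from dewpoint and max temperature.

    Magnus-form ratio RH = 100 * exp(17.625*DP/(243.04+DP))
    / exp(17.625*T/(243.04+T)).  Physically inconsistent records with
    dewpoint above the air temperature are clamped to 100%.
    """
    dp = np.asarray(dewpoint, dtype=float)
    t = np.asarray(t_max, dtype=float)
    rh = 100.0 * np.exp(17.625 * dp / (243.04 + dp)) / np.exp(17.625 * t / (243.04 + t))
    rh = np.minimum(rh, 100.0)
    if rh.ndim == 0:
        return float(rh)
    return rh


def thi_max(t_max, rh_min):
    """Maximum temperature-humidity index (index points)."""
    t = np.asarray(t_max, dtype=float)
    rh = np.asarray(rh_min, dtype=float)
    out = 0.8 * t + rh / 100.0 * (t - 14.4) + 46.4
    if out.ndim == 0:
        return float(out)
    return out


def add_thi(weather: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the daily weather table with rh_min and thi_max columns.

    Expects columns ``t_max`` and ``dewpoint`` (degC).  Rows where the
    dewpoint exceeds t_max are clamped to RH = 100; their count is
    attached as ``df.attrs["n_clamped"]``.
    """
    df = weather.copy()
    df["rh_min"] = rh_from_dewpoint(df["dewpoint"].to_numpy(), df["t_max"].to_numpy())
    df["thi_max"] = thi_max(df["t_max"].to_numpy(), df["rh_min"].to_numpy())
    df.attrs["n_clamped"] = int((df["dewpoint"] > df["t_max"]).sum())
    return df


def _year_length(year: int) -> int:
    return 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365


def station_completeness(weather: pd.DataFrame) -> pd.DataFrame:
    """Fraction of calendar days observed, per station-year.

    Completeness is measured against the true calendar length of the
    year (365 or 366 days), not against the span of observations.
    """
    df = weather.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    counts = (
        df.drop_duplicates(["station_id", "date"])
        .groupby(["station_id", "year"])
        .size()
        .rename("n_days")
        .reset_index()
    )
    counts["completeness"] = counts.apply(
        lambda r: r["n_days"] / _year_length(int(r["year"])), axis=1
    )
    return counts


def qc_stations(weather: pd.DataFrame, mode: str = "multi") -> pd.DataFrame:
    """Apply the >10%-missing station-year rule.

    mode="multi" (multi-herd data): station-years with strictly more than
    10% of daily observations missing are dropped (``retained`` False).
    mode="single" (single-station research-herd data): such years are
    kept but flagged, so analyses can report them.
    """
    if mode not in ("multi", "single"):
        raise ValueError(f"unknown QC mode: {mode!r}")
    comp = station_completeness(weather)
    comp["flagged"] = comp["completeness"] < 0.90
    comp["retained"] = True if mode == "single" else ~comp["flagged"]
    return comp


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a WGS-84 spherical approximation."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    if np.ndim(d) == 0:
        return float(d)
    return d


def match_nearest_station(farms: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Match each farm to its nearest weather station (haversine).

    ``farms`` needs farm_id/latitude/longitude; ``stations`` needs
    station_id/latitude/longitude (pass stations that survived QC in at
    least one year).  Returns farm_id, station_id, distance_km.
    """
    if len(stations) == 0:
        raise ValueError("no weather stations available for matching")
    st = stations.drop_duplicates("station_id").reset_index(drop=True)
    rows = []
    for _, farm in farms.iterrows():
        d = haversine_km(farm["latitude"], farm["longitude"],
                         st["latitude"].to_numpy(), st["longitude"].to_numpy())
        i = int(np.argmin(d))
        rows.append({"farm_id": farm["farm_id"],
                     "station_id": st.loc[i, "station_id"],
                     "distance_km": float(d[i])})
    return pd.DataFrame(rows)


def mean_thi(weather: pd.DataFrame, start, end) -> float:
    """Mean daily THI_max over the closed date interval [start, end].

    ``weather`` is the daily series of a single station and must carry a
    ``thi_max`` column.  Days missing from the record are simply absent
    from the mean; if no day of the interval is observed, NaN.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end < start:
        raise ValueError("empty date interval")
    dates = pd.to_datetime(weather["date"])
    sel = weather.loc[(dates >= start) & (dates <= end), "thi_max"]
    if len(sel) == 0:
        return float("nan")
    return float(sel.mean())
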