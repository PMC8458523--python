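"""Station-level sea-ice concentration series, 15%-threshold crossings,
monthly means, and song/ice timing lags.

A station's daily series is the unweighted mean concentration over grid
cells whose great-circle distance to the station is at most 50 km (cells
treated as points at their centres).  The ice edge is the 15% concentration
contour: a retreat event is the first day strictly below the threshold after
a day at or above it; an advance event is the first day strictly above it
after a day at or below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import Station

__all__ = [
    "EARTH_RADIUS_KM",
    "IceGrid",
    "IceSeries",
    "CrossingEvents",
    "LagResult",
    "haversine_km",
    "station_series",
    "monthly_mean",
    "crossings",
    "song_ice_lags",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (array-friendly)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class IceGrid:
    """Daily gridded sea-ice concentration records.

    ``cells`` columns: date (datetime64), lat, lon, sic (percent, 0-100).
    """

    cells: pd.DataFrame
    resolution_km: Optional[float] = None

    def __post_init__(self) -> None:
        required = {"date", "lat", "lon", "sic"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"ice grid missing columns: {sorted(missing)}")
        sic = self.cells["sic"].to_numpy(float)
        if np.nanmin(sic) < 0 or np.nanmax(sic) > 100:
            raise ValueError("sea-ice concentration must lie in [0, 100]")
        self.cells = self.cells.assign(date=pd.to_datetime(self.cells["date"]))

    @classmethod
    def from_csv(cls, path: str | Path,
                 resolution_km: Optional[float] = None) -> "IceGrid":
        """Long-format CSV with columns date, lat, lon, sic_percent."""
        df = pd.read_csv(path)
        df = df.rename(columns={"sic_percent": "sic"})
        return cls(df[["date", "lat", "lon", "sic"]], resolution_km)

    @classmethod
    def from_netcdf(cls, path: str | Path,
                    resolution_km: Optional[float] = None) -> "IceGrid":
        """NetCDF with variables lat, lon, time and sic."""
        import xarray as xr

        ds = xr.open_dataset(path)
        df = ds["sic"].to_dataframe().reset_index()
        df = df.rename(columns={"time": "date"})
        return cls(df[["date", "lat", "lon", "sic"]].dropna(), resolution_km)

    def to_csv(self, path: str | Path) -> None:
        out = self.cells.rename(columns={"sic": "sic_percent"})
        out.assign(date=out["date"].dt.date).to_csv(path, index=False)


@dataclass
class IceSeries:
    """Daily mean concentration at one station."""

    station: str
    dates: pd.DatetimeIndex
    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if len(self.dates) != len(self.concentration):
            raise ValueError("dates and concentration differ in length")
        valid = self.concentration[np.isfinite(self.concentration)]
        if valid.size and (valid.min() < -1e-9 or valid.max() > 100 + 1e-9):
            raise ValueError("concentration must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"station": self.station, "date": self.dates,
             "sic_percent": self.concentration}
        )


@dataclass
class CrossingEvents:
    """Ice-edge (threshold) crossing events of one station series."""

    station: str
    retreat_dates: list[Date] = field(default_factory=list)
    advance_dates: list[Date] = field(default_factory=list)
    threshold: float = 15.0


@dataclass(frozen=True)
class LagResult:
    retreat_lag_days: Optional[int]
    advance_lag_days: Optional[int]
    retreat_defined: bool
    advance_defined: bool


def station_series(
    grid: IceGrid,
    station: Station,
    radius_km: float = 50.0,
    max_gap_days: int = 5,
) -> IceSeries:
    """Daily unweighted mean concentration over cells within ``radius_km``
    (haversine) of the station.

    Missing days inside the covered span are linearly interpolated when the
    gap is at most ``max_gap_days`` days, otherwise left missing.  Raises if
    no cell lies within the radius.
    """
    cells = grid.cells
    pts = cells[["lat", "lon"]].drop_duplicates()
    dist = haversine_km(
        pts["lat"].to_numpy(), pts["lon"].to_numpy(),
        station.latitude, station.longitude,
    )
    near = pts[dist <= radius_km]
    if near.empty:
        raise ValueError(
            f"no ice grid cell within {radius_km} km of station {station.id}"
        )
    merged = cells.merge(near, on=["lat", "lon"])
    daily = merged.groupby("date")["sic"].mean()
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(full)
    values = _fill_short_gaps(daily.to_numpy(), max_gap_days)
    return IceSeries(station.id, full, values)


def _fill_short_gaps(values: "np.ndarray", max_gap_days: int) -> "np.ndarray":
    """Linearly interpolate interior NaN runs whose whole length is at most
    ``max_gap_days``; longer runs stay missing."""
    out = values.copy()
    n = len(out)
    i = 0
    while i < n:
        if not np.isnan(out[i]):
            i += 1
            continue
        j = i
        while j < n and np.isnan(out[j]):
            j += 1
        interior = i > 0 and j < n
        if interior and (j - i) <= max_gap_days:
            left, right = out[i - 1], out[j]
            for k in range(i, j):
                frac = (k - i + 1) / (j - i + 1)
                out[k] = left + frac * (right - left)
        i = j
    return out


def monthly_mean(series: IceSeries) -> pd.DataFrame:
    """Arithmetic mean concentration per calendar month; months with no
    valid day are omitted (no-data rather than zero)."""
    df = pd.DataFrame({"sic": series.concentration}, index=series.dates)
    df = df.dropna()
    if df.empty:
        return pd.DataFrame(columns=["station", "month", "mean_sic"])
    grouped = df.groupby(df.index.to_period("M"))["sic"].mean()
    return pd.DataFrame(
        {"station": series.station, "month": grouped.index,
         "mean_sic": grouped.to_numpy()}
    ).reset_index(drop=True)


def crossings(series: IceSeries, threshold: float = 15.0) -> CrossingEvents:
    """Threshold-crossing events.

    Retreat: first day strictly below the threshold following a day at or
    above it.  Advance: first day strictly above following a day at or
    below.  Transitions are only evaluated between consecutive valid days,
    so missing spans are skipped.
    """
    events = CrossingEvents(series.station, threshold=threshold)
    conc = series.concentration
    dates = series.dates
    prev_val: Optional[float] = None
    prev_date: Optional[pd.Timestamp] = None
    for d, v in zip(dates, conc):
        if not np.isfinite(v):
            continue
        if (
            prev_val is not None
            and (d - prev_date).days == 1  # type: ignore[operator]
        ):
            if prev_val >= threshold and v < threshold:
                events.retreat_dates.append(d.date())
            elif prev_val <= threshold and v > threshold:
                events.advance_dates.append(d.date())
        prev_val, prev_date = v, d
    return events


def song_ice_lags(
    first_song: Date,
    last_song: Date,
    events: CrossingEvents,
) -> LagResult:
    """Lags between song-season endpoints and ice-edge events.

    ``retreat_lag`` = days from the most recent retreat at or before the
    first song to the first song (undefined if no prior retreat).
    ``advance_lag`` = days from the season's advance to the last song:
    the most recent advance at or before the last song if one exists,
    otherwise the next advance after it (negative lag).
    """
    prior_retreats = [d for d in events.retreat_dates if d <= first_song]
    retreat_lag = (
        (first_song - max(prior_retreats)).days if prior_retreats else None
    )

    prior_advances = [d for d in events.advance_dates if d <= last_song]
    later_advances = [d for d in events.advance_dates if d > last_song]
    if prior_advances:
        advance_lag: Optional[int] = (last_song - max(prior_advances)).days
    elif later_advances:
        advance_lag = (last_song - min(later_advances)).days
    else:
        advance_lag = None

    return LagResult(
        retreat_lag_days=retreat_lag,
        advance_lag_days=advance_lag,
        retreat_defined=retreat_lag is not None,
        advance_defined=advance_lag is not None,
    )
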