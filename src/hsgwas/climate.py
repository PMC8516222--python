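"""Temperature-humidity-index exposures for gestation weeks before birth.

Builds hourly THI from station weather, aggregates to daily and weekly means
anchored at each animal's birth date, assigns herds to their nearest weather
station by great-circle distance, and emits binary heat-stress (HS) flags for
gestation weeks 1..8 (THI >= 60 in the respective week).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, MissingDataError

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius
HS_THI_THRESHOLD = 60.0
DEFAULT_WEEKS = tuple(range(1, 9))
#: minimum number of hourly records for a daily mean to be considered valid
DEFAULT_MIN_HOURS = 18


def thi_hourly(temperature, relative_humidity):
    """THI = (1.8*T + 32) - (0.55 - 0.0055*RH) * (1.8*T - 26).

    ``temperature`` in degrees Celsius, ``relative_humidity`` in percent.
    Vectorized over array inputs.
    """
    t = np.asarray(temperature, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise DomainError("relative humidity must lie in [0, 100] percent")
    thi = (1.8 * t + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t - 26.0)
    if thi.ndim == 0:
        return float(thi)
    return thi


def daily_thi(hourly_values, min_hours: int = DEFAULT_MIN_HOURS) -> float:
    """Mean of one calendar day's hourly THI values.

    Days with fewer than ``min_hours`` non-missing hourly records are treated
    as missing and raise :class:`MissingDataError`.
    """
    vals = np.asarray(list(hourly_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise MissingDataError("no hourly THI values for the day")
    if vals.size < min_hours:
        raise MissingDataError(
            f"only {vals.size} hourly THI values present; {min_hours} required"
        )
    return float(vals.mean())


def daily_thi_series(weather: pd.DataFrame, min_hours: int = DEFAULT_MIN_HOURS) -> pd.Series:
    """Daily THI series for one station's hourly weather table.

    ``weather`` needs columns ``timestamp`` (datetime-like), ``temp_c`` and
    ``rh_pct``. Days failing the ``min_hours`` completeness rule are dropped
    (they surface later as missing-data errors if a week needs them).
    """
    ts = pd.to_datetime(weather["timestamp"])
    thi = thi_hourly(weather["temp_c"].to_numpy(), weather["rh_pct"].to_numpy())
    frame = pd.DataFrame({"date": ts.dt.normalize(), "thi": thi})
    grouped = frame.groupby("date")["thi"]
    counts = grouped.count()
    means = grouped.mean()
    keep = counts >= min_hours
    out = means[keep]
    out.index = pd.DatetimeIndex(out.index)
    return out.sort_index()


def week_day_offsets(week: int, strict_seven: bool = False) -> range:
    """Day offsets before the birth date covered by gestation week ``week``.

    Week 1 is implemented as printed in the source protocol: days 0-7 before
    birth (eight days, including the birth day). ``strict_seven`` switches
    week 1 to days 1-7. Weeks k >= 2 always cover days 7(k-1)+1 .. 7k.
    """
    if not 1 <= week <= 8:
        raise DomainError(f"week must be in 1..8, got {week}")
    if week == 1:
        return range(1, 8) if strict_seven else range(0, 8)
    return range(7 * (week - 1) + 1, 7 * week + 1)


def weekly_thi(daily: pd.Series, birth_date, week: int, strict_seven: bool = False) -> float:
    """Mean daily THI over the gestation-week window before ``birth_date``."""
    birth = pd.Timestamp(birth_date).normalize()
    offsets = week_day_offsets(week, strict_seven=strict_seven)
    days = [birth - pd.Timedelta(days=d) for d in offsets]
    try:
        vals = daily.loc[days]
    except KeyError as exc:
        raise MissingDataError(
            f"daily THI missing for week {week} before {birth.date()}"
        ) from exc
    arr = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise MissingDataError(f"daily THI contains NaN in week {week} before {birth.date()}")
    return float(arr.mean())


def hs_indicator(weekly_thi_value: float, threshold: float = HS_THI_THRESHOLD) -> int:
    """1 if the weekly THI is at or above the heat-stress threshold, else 0."""
    v = float(weekly_thi_value)
    if not np.isfinite(v):
        raise DomainError("weekly THI must be finite")
    return int(v >= threshold)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    coords = np.asarray([lat1, lon1, lat2, lon2], dtype=float)
    if np.any(np.abs(coords[[0, 2]]) > 90.0) or np.any(np.abs(coords[[1, 3]]) > 180.0):
        raise DomainError("coordinates out of range: |lat| <= 90, |lon| <= 180")
    la1, lo1, la2, lo2 = np.radians(coords)
    dlat = la2 - la1
    dlon = lo2 - lo1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _pairwise_haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorized distances between every row of (lat1,lon1) and (lat2,lon2)."""
    la1 = np.radians(np.asarray(lat1, float))[:, None]
    lo1 = np.radians(np.asarray(lon1, float))[:, None]
    la2 = np.radians(np.asarray(lat2, float))[None, :]
    lo2 = np.radians(np.asarray(lon2, float))[None, :]
    a = (np.sin((la2 - la1) / 2.0) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def assign_stations(herds: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Map each herd to its nearest weather station.

    Both tables carry (``herd_id``/``station_id``, ``lat``, ``lon``). Ties in
    distance are broken by the lexicographically smallest station id. Returns
    a frame with ``herd_id``, ``station_id`` and ``distance_km``.
    """
    if len(stations) == 0:
        raise ConfigurationError("station table is empty")
    if len(herds) == 0:
        raise ConfigurationError("herd table is empty")
    st = stations.sort_values("station_id", key=lambda s: s.astype(str)).reset_index(drop=True)
    dist = _pairwise_haversine_km(
        herds["lat"].to_numpy(), herds["lon"].to_numpy(),
        st["lat"].to_numpy(), st["lon"].to_numpy(),
    )
    idx = np.argmin(dist, axis=1)  # argmin takes the first minimum -> smallest id
    return pd.DataFrame({
        "herd_id": herds["herd_id"].to_numpy(),
        "station_id": st["station_id"].to_numpy()[idx],
        "distance_km": dist[np.arange(len(herds)), idx],
    })


@dataclass(frozen=True)
class ExposureTable:
    """Per (animal, gestation week) THI exposure with binary HS flag."""

    table: pd.DataFrame  # columns: animal_id, week, weekly_thi, hs_flag

    def __post_init__(self):
        required = {"animal_id", "week", "weekly_thi", "hs_flag"}
        if not required.issubset(self.table.columns):
            raise ConfigurationError(f"exposure table needs columns {sorted(required)}")

    def exposed_mask(self, animal_ids: Iterable, week: int) -> np.ndarray:
        """Boolean HS mask aligned to ``animal_ids`` for the given week."""
        sub = self.table[self.table["week"] == week]
        flags = dict(zip(sub["animal_id"].astype(str), sub["hs_flag"].astype(int)))
        try:
            return np.array([bool(flags[str(a)]) for a in animal_ids])
        except KeyError as exc:
            raise MissingDataError(f"no exposure record for animal {exc} in week {week}") from exc

    def weekly_values(self, animal_ids: Iterable, week: int) -> np.ndarray:
        sub = self.table[self.table["week"] == week]
        vals = dict(zip(sub["animal_id"].astype(str), sub["weekly_thi"].astype(float)))
        return np.array([vals[str(a)] for a in animal_ids])


def build_exposure(
    animals: pd.DataFrame,
    daily_by_station: Mapping[str, pd.Series],
    assignment: pd.DataFrame,
    weeks: Iterable[int] = DEFAULT_WEEKS,
    threshold: float = HS_THI_THRESHOLD,
    strict_seven: bool = False,
) -> ExposureTable:
    """Compute weekly THI and HS flags for every animal and requested week.

    ``animals`` needs ``animal_id``, ``herd_id`` and ``birth_date``;
    ``daily_by_station`` maps station ids to daily THI series;
    ``assignment`` comes from :func:`assign_stations`.
    """
    herd_to_station = dict(zip(assignment["herd_id"], assignment["station_id"]))
    rows = []
    for _, rec in animals.iterrows():
        herd = rec["herd_id"]
        if herd not in herd_to_station:
            raise MissingDataError(f"herd {herd!r} has no station assignment")
        daily = daily_by_station[herd_to_station[herd]]
        for wk in weeks:
            val = weekly_thi(daily, rec["birth_date"], wk, strict_seven=strict_seven)
            rows.append((rec["animal_id"], wk, val, hs_indicator(val, threshold)))
    table = pd.DataFrame(rows, columns=["animal_id", "week", "weekly_thi", "hs_flag"])
    return ExposureTable(table)
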