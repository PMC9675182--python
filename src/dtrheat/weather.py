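"""Daily district temperature data: containers, CSV I/O, QC, calendar utilities.

The pipeline operates on one daily series per district municipality, each a
contiguous civil-calendar sequence of (tmax, tmin) observations in degrees
Celsius.  Missing observations are retained as explicit NaN days — they are
excluded from every downstream statistic, never interpolated, because an
interpolated day would fabricate heat exposure.

Dates are timezone-free calendar dates; no sub-daily data is supported.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Plausible band for a district minimum-mortality temperature, degrees C.
#: Published district estimates for the study region span 18.5-39 C.
MMT_BOUNDS = (10.0, 45.0)

_DEFAULT_SCHEMA = {
    "district": "district_id",
    "date": "date",
    "tmax": "tmax",
    "tmin": "tmin",
}


def _as_date(value) -> dt.date:
    """Coerce a date-like value (date, datetime, Timestamp, ISO string) to date."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        return dt.date.fromisoformat(value)
    if isinstance(value, pd.Timestamp):
        return value.date()
    raise TypeError(f"cannot interpret {value!r} as a calendar date")


def inclusive_day_count(start, end) -> int:
    """Number of calendar days in [start, end], both endpoints counted.

    Leap-year aware by construction (civil-calendar subtraction).  The full
    2014-01-01..2019-12-31 study window contains 2191 days (five 365-day
    years plus the 366-day year 2016).

    Raises
    ------
    ValueError
        If start is after end.
    """
    start, end = _as_date(start), _as_date(end)
    if start > end:
        raise ValueError(f"start {start} is after end {end}")
    return (end - start).days + 1


@dataclass(frozen=True)
class DistrictMeta:
    """Identity and health-threshold metadata for one district municipality.

    ``mmt`` is the district's minimum mortality temperature: the mean daily
    temperature at which mortality is lowest.  Days with mean temperature
    below it are excluded from heatwave analysis.
    """

    district_id: str
    province: str
    mmt: float
    centroid_lat: float
    centroid_lon: float
    coastal: bool

    def __post_init__(self):
        lo, hi = MMT_BOUNDS
        if not (lo <= self.mmt <= hi):
            raise ValueError(
                f"district {self.district_id}: MMT {self.mmt} outside plausible "
                f"band [{lo}, {hi}] degC"
            )
        if not -90.0 <= self.centroid_lat <= 90.0:
            raise ValueError(f"district {self.district_id}: latitude {self.centroid_lat} out of range")
        if not -180.0 <= self.centroid_lon <= 180.0:
            raise ValueError(f"district {self.district_id}: longitude {self.centroid_lon} out of range")


@dataclass
class DailySeries:
    """One district's contiguous daily (tmax, tmin) record.

    ``frame`` is indexed by a daily DatetimeIndex with float columns
    ``tmax`` and ``tmin``; NaN marks a missing observation.  Every calendar
    day between period_start and period_end is present (missing days are
    explicit NaN rows).  Where both values are present, tmax >= tmin.
    """

    district_id: str
    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            raise ValueError("DailySeries frame must have a DatetimeIndex")
        if len(f) == 0:
            raise ValueError("DailySeries frame is empty")
        for col in ("tmax", "tmin"):
            if col not in f.columns:
                raise ValueError(f"DailySeries frame lacks column {col!r}")
        if not f.index.is_monotonic_increasing or f.index.has_duplicates:
            raise ValueError("DailySeries dates must be strictly increasing")
        deltas = np.diff(f.index.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not (deltas == 1).all():
            raise ValueError(
                f"district {self.district_id}: calendar not contiguous "
                "(gap days must be filled with missing records)"
            )
        both = f["tmax"].notna() & f["tmin"].notna()
        bad = both & (f["tmax"] < f["tmin"])
        if bad.any():
            when = f.index[bad][0].date()
            raise ValueError(
                f"district {self.district_id}: tmax < tmin on {when} "
                "(flag such rows to missing before constructing the series)"
            )

    # -- convenience -------------------------------------------------------

    @property
    def period_start(self) -> dt.date:
        return self.frame.index[0].date()

    @property
    def period_end(self) -> dt.date:
        return self.frame.index[-1].date()

    @property
    def n_days(self) -> int:
        return len(self.frame)

    @property
    def missing_mask(self) -> pd.Series:
        """True on days where either temperature is missing."""
        return self.frame["tmax"].isna() | self.frame["tmin"].isna()

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())

    @classmethod
    def from_arrays(cls, district_id: str, start, tmax, tmin) -> "DailySeries":
        """Build a series from parallel tmax/tmin arrays starting at ``start``."""
        tmax = np.asarray(tmax, dtype=float)
        tmin = np.asarray(tmin, dtype=float)
        if tmax.shape != tmin.shape:
            raise ValueError("tmax and tmin must have equal length")
        idx = pd.date_range(pd.Timestamp(_as_date(start)), periods=len(tmax), freq="D")
        return cls(district_id, pd.DataFrame({"tmax": tmax, "tmin": tmin}, index=idx))


@dataclass
class LoadResult:
    """Outcome of reading a daily-temperature CSV: series plus QC evidence."""

    series: dict[str, DailySeries]
    #: per-district QC report: n_days, n_missing, missing_fraction, n_flagged
    qc: pd.DataFrame
    #: rows whose tmax < tmin, set to missing (district, date, tmax, tmin)
    flagged: pd.DataFrame


def read_daily_csv(
    path,
    schema: Mapping[str, str] | None = None,
    meta: Mapping[str, DistrictMeta] | None = None,
    period: tuple | None = None,
) -> LoadResult:
    """Read a long-format daily temperature CSV into per-district series.

    Parameters
    ----------
    path
        CSV with one row per (district, day).  Default column names are
        ``district_id, date, tmax, tmin``; pass ``schema`` mapping the
        logical names ``district/date/tmax/tmin`` to the file's headers to
        load differently headed exports without editing them.
    meta
        Optional district metadata; if given, any district in the file that
        is absent from the metadata is a hard error.
    period
        Optional (start, end) dates to which every series is reindexed;
        defaults to each district's own observed span.

    Rows with tmax < tmin are treated as sensor error: both values are set
    missing and the row is recorded in ``flagged``.  Gap days are filled
    with missing records so each series covers a contiguous calendar.
    Duplicate (district, date) rows and unparseable dates are hard errors.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if len(raw) == 0:
        raise ValueError(f"{path}: no data rows")

    colmap = dict(_DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    missing_cols = [c for c in colmap.values() if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")

    df = pd.DataFrame(
        {
            "district_id": raw[colmap["district"]].astype(str),
            "date_raw": raw[colmap["date"]],
            "tmax": pd.to_numeric(raw[colmap["tmax"]], errors="coerce"),
            "tmin": pd.to_numeric(raw[colmap["tmin"]], errors="coerce"),
        }
    )
    dates = pd.to_datetime(df["date_raw"], errors="coerce", format="mixed")
    bad = dates.isna() & df["date_raw"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise ValueError(
            f"{path}: unparseable date {df['date_raw'].iloc[row]!r} in data row {row}"
        )
    df["date"] = dates.dt.normalize()

    dup = df.duplicated(subset=["district_id", "date"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for district {row['district_id']} on "
            f"{row['date'].date()}"
        )

    if meta is not None:
        unknown = sorted(set(df["district_id"]) - set(meta))
        if unknown:
            raise ValueError(f"{path}: unknown districts {unknown} not in metadata")

    # sensor-error rows: tmax < tmin -> both missing, flagged
    both = df["tmax"].notna() & df["tmin"].notna()
    bad_rows = both & (df["tmax"] < df["tmin"])
    flagged = df.loc[bad_rows, ["district_id", "date", "tmax", "tmin"]].copy()
    if bad_rows.any():
        logger.warning(
            "%s: %d rows with tmax < tmin set to missing", path, int(bad_rows.sum())
        )
        df.loc[bad_rows, ["tmax", "tmin"]] = np.nan

    series: dict[str, DailySeries] = {}
    qc_rows = []
    for district_id, grp in df.groupby("district_id", sort=True):
        grp = grp.set_index("date").sort_index()
        if period is not None:
            start, end = (pd.Timestamp(_as_date(p)) for p in period)
        else:
            start, end = grp.index[0], grp.index[-1]
        full = pd.date_range(start, end, freq="D")
        frame = grp[["tmax", "tmin"]].reindex(full).astype(float)
        s = DailySeries(district_id, frame)
        series[district_id] = s
        qc_rows.append(
            {
                "district_id": district_id,
                "n_days": s.n_days,
                "n_missing": int(s.missing_mask.sum()),
                "missing_fraction": s.missing_fraction,
                "n_flagged": int((flagged["district_id"] == district_id).sum()),
            }
        )
    qc = pd.DataFrame(qc_rows).set_index("district_id")
    return LoadResult(series=series, qc=qc, flagged=flagged.reset_index(drop=True))


def write_daily_csv(series: Iterable[DailySeries] | Mapping[str, DailySeries], path) -> None:
    """Write series to the same long CSV dialect ``read_daily_csv`` accepts.

    Missing values are written as empty fields, so a write/read round trip
    reproduces values and missingness pattern exactly.
    """
    if isinstance(series, Mapping):
        series = series.values()
    parts = []
    for s in series:
        part = s.frame.reset_index(names="date")
        part.insert(0, "district_id", s.district_id)
        part["date"] = part["date"].dt.strftime("%Y-%m-%d")
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_district_meta(path) -> dict[str, DistrictMeta]:
    """Read district metadata CSV (district_id, province, mmt, lat, lon, coastal).

    Every invariant violation (MMT outside the plausible band, coordinates
    out of range, duplicate district ids) is a hard error: metadata defects
    silently corrupt the MMT masking downstream.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    required = ["district_id", "province", "mmt", "lat", "lon", "coastal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["district_id"].duplicated().any():
        dups = sorted(df.loc[df["district_id"].duplicated(), "district_id"])
        raise ValueError(f"{path}: duplicate district ids {dups}")
    out: dict[str, DistrictMeta] = {}
    for _, row in df.iterrows():
        coastal = row["coastal"]
        if isinstance(coastal, str):
            coastal = coastal.strip().lower() in {"true", "1", "yes", "t"}
        out[str(row["district_id"])] = DistrictMeta(
            district_id=str(row["district_id"]),
            province=str(row["province"]),
            mmt=float(row["mmt"]),
            centroid_lat=float(row["lat"]),
            centroid_lon=float(row["lon"]),
            coastal=bool(coastal),
        )
    return out


def write_district_meta(meta: Mapping[str, DistrictMeta], path) -> None:
    rows = [
        {
            "district_id": m.district_id,
            "province": m.province,
            "mmt": m.mmt,
            "lat": m.centroid_lat,
            "lon": m.centroid_lon,
            "coastal": m.coastal,
        }
        for m in meta.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
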