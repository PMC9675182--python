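"""Per-day derived quantities and district descriptive statistics.

The exposure metric throughout is the diurnal temperature range
DTR = tmax - tmin; a "hot day" is a day whose DTR exceeds the national
health-based threshold (12.8 degC by default).  Mean daily temperature is
the midrange (tmax + tmin)/2 — the only mean computable from daily
max/min records — and is compared against the district MMT.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .weather import DailySeries, DistrictMeta, _as_date

#: National mortality-derived DTR alert threshold, degrees C.
DTR_THRESHOLD_DEFAULT = 12.8

_SEASON_OF_MONTH = {
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
    9: "spring", 10: "spring", 11: "spring",
}

SEASON_ORDER = ("summer", "autumn", "winter", "spring")


def season_of(date) -> str:
    """Austral season of a calendar date: DJF summer, MAM autumn, JJA winter, SON spring."""
    return _SEASON_OF_MONTH[_as_date(date).month]


def derive_daily(
    series: DailySeries,
    threshold: float | None = None,
    mmt: float | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-day derived frame: dtr, tmean, and optional qualification flags.

    Returns a DataFrame on the series' daily index with float columns
    ``dtr`` (tmax - tmin) and ``tmean`` ((tmax + tmin)/2); both are NaN
    whenever either input temperature is missing.  If ``threshold`` is
    given, a nullable-boolean ``is_hot_day`` column marks DTR exceedance
    (strict ``>`` by default, ``>=`` with strict=False); if ``mmt`` is
    given, ``above_mmt`` marks tmean >= mmt.  Flags are <NA> on missing
    days.  The operation is pointwise — each output day depends only on
    that day's inputs.
    """
    tmax, tmin = series.frame["tmax"], series.frame["tmin"]
    out = pd.DataFrame(index=series.frame.index)
    out["tmax"] = tmax
    out["tmin"] = tmin
    out["dtr"] = tmax - tmin
    out["tmean"] = (tmax + tmin) / 2.0
    if threshold is not None:
        hot = out["dtr"] > threshold if strict else out["dtr"] >= threshold
        out["is_hot_day"] = hot.astype("boolean").mask(out["dtr"].isna())
    if mmt is not None:
        above = out["tmean"] >= mmt
        out["above_mmt"] = above.astype("boolean").mask(out["tmean"].isna())
    return out


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary of one temperature variable over a district's non-missing days."""

    variable: str
    mean: float
    sd: float
    p95: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("standard deviation cannot be negative")
        if self.p95 < self.mean - 5 * self.sd:
            raise ValueError("p95 implausibly far below the mean")


def descriptive_stats(series: DailySeries, variable: str) -> DescriptiveStats:
    """Mean, sample SD (n-1), and 95th percentile of tmax, tmin or dtr.

    Statistics are computed over non-missing days only; the 95th percentile
    interpolates linearly between the closest order statistics (other
    percentile conventions exist; this one is the numpy default and is the
    package's documented choice).  Requires at least two non-missing days.
    """
    if variable in ("tmax", "tmin"):
        values = series.frame[variable]
    elif variable == "dtr":
        values = series.frame["tmax"] - series.frame["tmin"]
    else:
        raise ValueError(f"unknown variable {variable!r}; expected tmax, tmin or dtr")
    x = values.dropna().to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError(
            f"district {series.district_id}: need >= 2 non-missing {variable} values, "
            f"have {len(x)}"
        )
    return DescriptiveStats(
        variable=variable,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        p95=float(np.percentile(x, 95, method="linear")),
        n=int(len(x)),
    )


def count_hot_days(derived: pd.DataFrame | pd.Series, threshold: float, strict: bool = True) -> int:
    """Count days whose DTR exceeds the threshold; missing days never count.

    Monotone non-increasing in the threshold.  Under the default strict
    convention a day with DTR exactly at the threshold does not count.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    dtr = derived["dtr"] if isinstance(derived, pd.DataFrame) else derived
    dtr = pd.Series(dtr).astype(float)
    hot = dtr > threshold if strict else dtr >= threshold
    return int(hot.fillna(False).sum())


def descriptive_table(
    series: Mapping[str, DailySeries],
    meta: Mapping[str, DistrictMeta] | None = None,
    date_range: tuple | None = None,
) -> pd.DataFrame:
    """Per-district descriptive statistics for tmax, tmin and DTR (long format).

    ``date_range`` optionally restricts to a (start, end) date window, for
    example to compute summer-only statistics.
    """
    rows = []
    for district_id, s in series.items():
        if date_range is not None:
            start, end = (pd.Timestamp(_as_date(d)) for d in date_range)
            s = DailySeries(district_id, s.frame.loc[start:end])
        for variable in ("tmax", "tmin", "dtr"):
            st = descriptive_stats(s, variable)
            rows.append(
                {
                    "district_id": district_id,
                    "province": meta[district_id].province if meta else "",
                    "variable": variable,
                    "mean": st.mean,
                    "sd": st.sd,
                    "p95": st.p95,
                    "n": st.n,
                }
            )
    return pd.DataFrame(rows)


def hot_day_table(
    series: Mapping[str, DailySeries],
    threshold: float = DTR_THRESHOLD_DEFAULT,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-district hot-day counts and the share of the period they represent."""
    rows = []
    for district_id, s in series.items():
        derived = derive_daily(s)
        n_hot = count_hot_days(derived, threshold, strict=strict)
        rows.append(
            {
                "district_id": district_id,
                "n_hot_days": n_hot,
                "n_days": s.n_days,
                "pct_of_period": 100.0 * n_hot / s.n_days,
            }
        )
    return pd.DataFrame(rows)
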