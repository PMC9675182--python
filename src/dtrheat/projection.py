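"""Delta-change climate projection and observed-vs-scenario comparison.

Future daily series are built by adding scenario anomaly deltas (e.g.
RCP 4.5 / RCP 8.5 future-minus-baseline differences for daily tmax and
tmin) to the observed series: future = observed + delta.  The observed
base calendar is cycled to cover the projection period, aligning by month
and day.  District MMTs are held fixed in future scenarios (no
acclimatisation adjustment), which may overestimate future events — a
known limitation of stationary health thresholds.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .detection import HeatwaveEvent, summarise_events
from .weather import DailySeries, DistrictMeta, _as_date

_VARIABLES = ("tmax", "tmin")


@dataclass
class AnomalyField:
    """Scenario temperature deltas for one variable, gridded or per-district.

    Gridded fields carry ``values`` shaped (ntime, nlat, nlon) on regular
    1-degree-style ``grid_lats`` x ``grid_lons`` axes; per-district fields
    carry ``district_values`` (index = time, columns = district ids).  The
    time axis is either the integers 1..12 (``time_resolution='monthly'``,
    a month-of-year climatology broadcast to every day of that month in the
    projection period) or a daily DatetimeIndex covering it.
    """

    scenario: str
    variable: str
    time_resolution: str  # 'monthly' | 'daily'
    time_index: pd.Index
    grid_lats: np.ndarray | None = None
    grid_lons: np.ndarray | None = None
    values: np.ndarray | None = None
    district_values: pd.DataFrame | None = None

    def __post_init__(self):
        if self.variable not in _VARIABLES:
            raise ValueError(f"variable must be one of {_VARIABLES}")
        if self.time_resolution not in ("monthly", "daily"):
            raise ValueError("time_resolution must be 'monthly' or 'daily'")
        if self.is_gridded:
            lats, lons = np.asarray(self.grid_lats, float), np.asarray(self.grid_lons, float)
            vals = np.asarray(self.values, float)
            if vals.shape != (len(self.time_index), len(lats), len(lons)):
                raise ValueError("gridded values must be shaped (ntime, nlat, nlon)")
            for ax, name in ((lats, "grid_lats"), (lons, "grid_lons")):
                if len(ax) < 2 or not np.allclose(np.diff(ax), ax[1] - ax[0]):
                    raise ValueError(f"{name} must be a regular axis with >= 2 nodes")
            if not np.isfinite(vals).all():
                raise ValueError("anomaly deltas must be finite")
            self.grid_lats, self.grid_lons, self.values = lats, lons, vals
        elif self.district_values is not None:
            if not np.isfinite(self.district_values.to_numpy(float)).all():
                raise ValueError("anomaly deltas must be finite")
        else:
            raise ValueError("field must be gridded or carry district_values")

    @property
    def is_gridded(self) -> bool:
        return self.values is not None

    @classmethod
    def gridded(cls, scenario, variable, grid_lats, grid_lons, values,
                time_index=None, time_resolution="monthly") -> "AnomalyField":
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:  # single time slice
            values = values[None, :, :]
        if time_index is None:
            time_index = pd.RangeIndex(values.shape[0])
        return cls(scenario, variable, time_resolution, pd.Index(time_index),
                   grid_lats=np.asarray(grid_lats, float),
                   grid_lons=np.asarray(grid_lons, float), values=values)

    @classmethod
    def per_district(cls, scenario, variable, district_values: pd.DataFrame,
                     time_resolution="monthly") -> "AnomalyField":
        return cls(scenario, variable, time_resolution,
                   pd.Index(district_values.index), district_values=district_values)

    def deltas_for_district(self, meta: DistrictMeta) -> pd.Series:
        """Delta series over the field's time axis at one district.

        Gridded fields are bilinearly interpolated to the district centroid;
        per-district fields return the district's column.
        """
        if self.is_gridded:
            vals = bilinear_interpolate(self, meta.centroid_lat, meta.centroid_lon)
            return pd.Series(vals, index=self.time_index)
        if meta.district_id not in self.district_values.columns:
            raise ValueError(
                f"scenario {self.scenario}: no {self.variable} deltas for "
                f"district {meta.district_id}"
            )
        return self.district_values[meta.district_id]


def bilinear_interpolate(field: AnomalyField, lat: float, lon: float) -> np.ndarray:
    """Bilinear interpolation of a gridded field at one point, per time step.

    Standard weighting of the four surrounding nodes; points on a node
    reproduce that node's value exactly, and the result is linear in the
    field values.  Points outside the grid's bounding box are an error —
    no extrapolation.
    """
    if not field.is_gridded:
        raise ValueError("field is not gridded")
    lats, lons = field.grid_lats, field.grid_lons
    if not (min(lats) <= lat <= max(lats) and min(lons) <= lon <= max(lons)):
        raise ValueError(
            f"point ({lat}, {lon}) outside grid bounding box "
            f"[{min(lats)}, {max(lats)}] x [{min(lons)}, {max(lons)}]"
        )
    # trailing time axis lets one interpolator serve every time step
    interp = RegularGridInterpolator(
        (lats, lons), np.moveaxis(field.values, 0, -1),
        method="linear", bounds_error=True,
    )
    return np.asarray(interp((lat, lon)), dtype=float).reshape(-1)


def _source_date(target: dt.date, base_years: Sequence[int], target_start_year: int) -> dt.date:
    """Base-period calendar analogue of a future date (month/day aligned).

    Base years are cycled in order across the projection period.  Feb 29 in
    a future leap year maps from Feb 28 when the source year lacks it.
    """
    source_year = base_years[(target.year - target_start_year) % len(base_years)]
    try:
        return dt.date(source_year, target.month, target.day)
    except ValueError:  # Feb 29 -> Feb 28
        return dt.date(source_year, target.month, target.day - 1)


def apply_anomaly(
    series: DailySeries,
    fields: AnomalyField | Iterable[AnomalyField],
    meta: DistrictMeta,
    target_period: tuple,
) -> DailySeries:
    """Delta-change projection of one observed series onto a future period.

    ``fields`` supplies the tmax and/or tmin deltas for one scenario (a
    variable without a field gets delta 0).  Each future day takes the
    observed value of its base-calendar analogue plus that day's delta;
    observed-missing days stay missing.  Monthly deltas broadcast to all
    days of the month.  If a projected day ends with tmax < tmin it is set
    fully missing, with a warning.
    """
    if isinstance(fields, AnomalyField):
        fields = [fields]
    by_var: dict[str, AnomalyField] = {}
    scenarios = set()
    for f in fields:
        if f.variable in by_var:
            raise ValueError(f"duplicate anomaly field for variable {f.variable}")
        by_var[f.variable] = f
        scenarios.add(f.scenario)
    if len(scenarios) > 1:
        raise ValueError(f"fields mix scenarios {sorted(scenarios)}")

    start, end = _as_date(target_period[0]), _as_date(target_period[1])
    if start > end:
        raise ValueError("target period start after end")
    base_start, base_end = series.period_start, series.period_end
    if not (base_start.month == 1 and base_start.day == 1
            and base_end.month == 12 and base_end.day == 31):
        raise ValueError(
            "base series must cover whole calendar years for month/day-aligned "
            f"cycling; got {base_start}..{base_end}"
        )
    base_years = list(range(base_start.year, base_end.year + 1))

    deltas: dict[str, pd.Series] = {}
    for var, f in by_var.items():
        s = f.deltas_for_district(meta)
        if f.time_resolution == "monthly":
            if not set(range(1, 13)) <= set(int(t) for t in s.index):
                raise ValueError(
                    f"monthly anomaly field for {var} must cover months 1..12"
                )
        deltas[var] = s

    target_idx = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    obs = series.frame
    out = {}
    for var in _VARIABLES:
        src_vals = np.empty(len(target_idx))
        for k, ts in enumerate(target_idx):
            d = _source_date(ts.date(), base_years, start.year)
            src_vals[k] = obs.at[pd.Timestamp(d), var]
        if var in deltas:
            f, s = by_var[var], deltas[var]
            if f.time_resolution == "monthly":
                dvals = s.reindex(target_idx.month).to_numpy(dtype=float)
            else:
                aligned = s.reindex(target_idx)
                if aligned.isna().any():
                    raise ValueError(
                        f"daily anomaly field for {var} does not cover the target period"
                    )
                dvals = aligned.to_numpy(dtype=float)
            src_vals = src_vals + dvals
        out[var] = src_vals

    tmax, tmin = out["tmax"], out["tmin"]
    inverted = ~np.isnan(tmax) & ~np.isnan(tmin) & (tmax < tmin)
    if inverted.any():
        warnings.warn(
            f"district {meta.district_id}: {int(inverted.sum())} projected days "
            "with tmax < tmin set to missing",
            stacklevel=2,
        )
        tmax[inverted] = np.nan
        tmin[inverted] = np.nan
    frame = pd.DataFrame({"tmax": tmax, "tmin": tmin}, index=target_idx)
    return DailySeries(series.district_id, frame)


@dataclass(frozen=True)
class PctChange:
    """Percent change of a future count over an observed count.

    ``rounded`` is the whole-percent presentation value (None when the
    observed count is zero, where the change is undefined); ``raw`` keeps
    full precision (NaN when undefined).
    """

    raw: float
    rounded: int | None

    @property
    def defined(self) -> bool:
        return self.rounded is not None


def pct_change(observed: float, future: float) -> PctChange:
    """100 * (future - observed) / observed; undefined (not infinite) at observed = 0.

    A 150 -> 270 increase is +80%; 150 -> 281 is +87% rounded (87.33 raw).
    """
    if observed == 0:
        return PctChange(raw=math.nan, rounded=None)
    raw = 100.0 * (future - observed) / observed
    return PctChange(raw=raw, rounded=int(round(raw)))


def compare_scenarios(
    observed_events: Sequence[HeatwaveEvent],
    future_events: Sequence[HeatwaveEvent],
    group_by: str,
    scenario: str = "",
    groups: Sequence | None = None,
    province_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Observed-vs-scenario per-group comparison of event counts and event-days.

    Both event sets must come from the same detection configuration.  Event
    counts and event-days are reported separately, each with raw and
    whole-percent change columns (percent change is empty where the
    observed count is zero).
    """
    if groups is None:
        obs_sum = summarise_events(observed_events, group_by, province_of=province_of)
        fut_sum = summarise_events(future_events, group_by, province_of=province_of)
        groups = sorted(
            set(obs_sum[group_by]) | set(fut_sum[group_by]),
            key=lambda g: str(g),
        )
        if group_by == "season":
            groups = [s for s in ("summer", "autumn", "winter", "spring") if s in groups]
    obs_sum = summarise_events(observed_events, group_by, groups=groups,
                               province_of=province_of).set_index(group_by)
    fut_sum = summarise_events(future_events, group_by, groups=groups,
                               province_of=province_of).set_index(group_by)
    rows = []
    for g in groups:
        row = {"scenario": scenario, group_by: g}
        for kind in ("n_events", "event_days"):
            o, f = int(obs_sum.at[g, kind]), int(fut_sum.at[g, kind])
            pc = pct_change(o, f)
            label = "events" if kind == "n_events" else "event_days"
            row[f"observed_{label}"] = o
            row[f"future_{label}"] = f
            row[f"pct_change_{label}"] = pc.rounded
            row[f"pct_change_{label}_raw"] = pc.raw
        rows.append(row)
    return pd.DataFrame(rows)


def read_anomaly_csv(path) -> list[AnomalyField]:
    """Read anomaly fields from a long CSV.

    Columns: scenario, variable, time (month number 1-12 or ISO date),
    delta, and either district (per-district fields) or lat+lon (gridded).
    Returns one AnomalyField per (scenario, variable) pair found.
    """
    df = pd.read_csv(path)
    required = {"scenario", "variable", "time", "delta"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: anomaly CSV needs columns {sorted(required)}")
    gridded = {"lat", "lon"} <= set(df.columns)
    if not gridded and "district" not in df.columns:
        raise ValueError(f"{path}: anomaly CSV needs 'district' or 'lat'+'lon' columns")

    def _time_axis(values):
        try:
            ints = values.astype(int)
            if set(ints) <= set(range(1, 13)):
                return pd.Index(ints), "monthly"
        except (ValueError, TypeError):
            pass
        return pd.DatetimeIndex(pd.to_datetime(values)), "daily"

    fields = []
    for (scenario, variable), grp in df.groupby(["scenario", "variable"]):
        if gridded:
            lats = np.sort(grp["lat"].unique())
            lons = np.sort(grp["lon"].unique())
            times, resolution = _time_axis(grp["time"].unique())
            cube = (
                grp.pivot_table(index="time", columns=["lat", "lon"], values="delta")
                .reindex(index=sorted(grp["time"].unique()))
                .to_numpy()
                .reshape(len(times), len(lats), len(lons))
            )
            fields.append(AnomalyField.gridded(scenario, variable, lats, lons, cube,
                                               time_index=times, time_resolution=resolution))
        else:
            wide = grp.pivot(index="time", columns="district", values="delta")
            times, resolution = _time_axis(pd.Series(wide.index))
            wide.index = times
            fields.append(AnomalyField.per_district(scenario, variable, wide,
                                                    time_resolution=resolution))
    return fields
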