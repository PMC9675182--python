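"""Heatwave event detection and characterisation.

A heatwave is a run of at least ``min_duration`` consecutive qualifying
days, where a day qualifies when its DTR exceeds the national threshold
AND its mean temperature is at or above the district's minimum mortality
temperature (MMT).  MMT masking is applied per day before run detection:
a below-MMT day breaks a run, exactly as a sub-threshold day does.  There
is no gap-joining by default — a single non-qualifying (or missing) day
terminates an event — because the definition is a plain consecutive-day
exceedance, unlike climatological marine-heatwave conventions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import DTR_THRESHOLD_DEFAULT, SEASON_ORDER, season_of
from .weather import DistrictMeta, _as_date, inclusive_day_count


@dataclass(frozen=True)
class ThresholdConfig:
    """Detection parameters.

    dtr_threshold : national health-based DTR alert threshold, degC.
    min_duration  : minimum consecutive qualifying days for an event.
    strict_exceedance : DTR must be strictly above the threshold (default);
        set False for a >= convention.
    max_gap : maximum run-interrupting gap (days) bridged when joining runs;
        0 (default) means any non-qualifying day terminates an event.
    """

    dtr_threshold: float = DTR_THRESHOLD_DEFAULT
    min_duration: int = 2
    strict_exceedance: bool = True
    max_gap: int = 0

    def __post_init__(self):
        if not self.dtr_threshold > 0:
            raise ValueError("dtr_threshold must be positive")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap cannot be negative")


@dataclass(frozen=True)
class HeatwaveEvent:
    """One detected event with its run-length and intensity metrics.

    ``peak_date`` is the event day of maximum DTR (the detection metric);
    ties resolve to the earliest such day.  ``peak_tmax_date`` reports the
    day of maximum tmax as an auxiliary view of the peak.
    ``cumulative_exceedance`` sums (dtr - threshold) over qualifying event
    days, in degC-days.  Events are attributed to the season and year of
    their start date.
    """

    district_id: str
    start: dt.date
    end: dt.date
    peak_date: dt.date
    duration: int
    peak_dtr: float
    mean_dtr: float
    cumulative_exceedance: float
    season_of_start: str
    year_of_start: int
    peak_tmax_date: dt.date | None = None

    def __post_init__(self):
        if not (self.start <= self.peak_date <= self.end):
            raise ValueError("peak_date must lie within [start, end]")
        if self.duration != inclusive_day_count(self.start, self.end):
            raise ValueError("duration inconsistent with start/end dates")


def event_duration(start, end) -> int:
    """Inclusive day count of an event (the 29 Oct 2015 - 13 Jan 2016 event spans 77 days)."""
    return inclusive_day_count(start, end)


def qualify_days(
    derived: pd.DataFrame,
    mmt: float,
    config: ThresholdConfig = ThresholdConfig(),
) -> np.ndarray:
    """Boolean per-day qualification: DTR exceeds threshold and tmean >= mmt.

    Days with a missing DTR or tmean never qualify.  ``mmt=-inf`` disables
    the MMT mask (useful for consistency checks against hot-day counts).
    """
    _require_contiguous(derived.index)
    dtr = derived["dtr"].to_numpy(dtype=float)
    tmean = derived["tmean"].to_numpy(dtype=float)
    if config.strict_exceedance:
        hot = dtr > config.dtr_threshold
    else:
        hot = dtr >= config.dtr_threshold
    mask = hot & (tmean >= mmt)
    mask &= ~np.isnan(dtr) & ~np.isnan(tmean)
    return mask


def _require_contiguous(index: pd.Index) -> None:
    if not isinstance(index, pd.DatetimeIndex):
        raise ValueError("derived frame must be indexed by calendar dates")
    if len(index) > 1:
        deltas = np.diff(index.values).astype("timedelta64[D]").astype(int)
        if not (deltas == 1).all():
            raise ValueError("derived frame calendar is not contiguous daily")


def _maximal_runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Half-open [i, j) index spans of maximal True runs, gap-joined if max_gap > 0."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, ends)]


def detect_events(
    derived: pd.DataFrame,
    meta: DistrictMeta,
    config: ThresholdConfig = ThresholdConfig(),
    apply_mmt: bool = True,
) -> list[HeatwaveEvent]:
    """Detect all heatwave events in one district's derived daily frame.

    Events are exactly the maximal runs of qualifying days of length at
    least ``config.min_duration``; shorter runs produce no event.  The
    returned events are sorted by start date and non-overlapping.  Raises
    if the frame's calendar is not contiguous daily.
    """
    _require_contiguous(derived.index)
    mmt = meta.mmt if apply_mmt else -np.inf
    mask = qualify_days(derived, mmt, config)
    dtr = derived["dtr"].to_numpy(dtype=float)
    tmax = derived["tmax"].to_numpy(dtype=float) if "tmax" in derived.columns else None
    dates = derived.index

    events: list[HeatwaveEvent] = []
    for i, j in _maximal_runs(mask, config.max_gap):
        duration = j - i
        if duration < config.min_duration:
            continue
        span = slice(i, j)
        qual = mask[span]
        q_dtr = dtr[span][qual]
        rel = np.flatnonzero(qual)
        peak_rel = rel[int(np.argmax(q_dtr))]  # argmax -> earliest on ties
        start = dates[i].date()
        peak_tmax_date = None
        if tmax is not None:
            q_tmax = tmax[span][qual]
            if np.isfinite(q_tmax).any():
                peak_tmax_rel = rel[int(np.nanargmax(q_tmax))]
                peak_tmax_date = dates[i + peak_tmax_rel].date()
        events.append(
            HeatwaveEvent(
                district_id=meta.district_id,
                start=start,
                end=dates[j - 1].date(),
                peak_date=dates[i + peak_rel].date(),
                duration=duration,
                peak_dtr=float(np.max(q_dtr)),
                mean_dtr=float(np.mean(q_dtr)),
                cumulative_exceedance=float(np.sum(q_dtr - config.dtr_threshold)),
                season_of_start=season_of(start),
                year_of_start=start.year,
                peak_tmax_date=peak_tmax_date,
            )
        )
    return events


def events_to_frame(events: Iterable[HeatwaveEvent]) -> pd.DataFrame:
    """Events as a flat table (one row per event), ready for CSV export."""
    cols = [
        "district_id", "start", "end", "peak_date", "duration", "peak_dtr",
        "mean_dtr", "cumulative_exceedance", "season_of_start",
        "year_of_start", "peak_tmax_date",
    ]
    rows = [{c: getattr(e, c) for c in cols} for e in events]
    return pd.DataFrame(rows, columns=cols)


_GROUP_KEYS = ("district", "province", "year", "season")


def summarise_events(
    events: Sequence[HeatwaveEvent],
    group_by: str,
    groups: Sequence | None = None,
    province_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group event count, total event-days, max duration and max peak DTR.

    ``group_by`` is one of district, province, year or season.  Groups with
    zero events appear with zeros; the group universe is ``groups`` when
    given, else the four austral seasons for ``season``, the spanned years
    for ``year``, and the observed set otherwise.  Grouping by province
    requires a ``province_of`` district->province mapping.
    """
    if group_by not in _GROUP_KEYS:
        raise ValueError(f"unknown group key {group_by!r}; expected one of {_GROUP_KEYS}")

    def key(e: HeatwaveEvent):
        if group_by == "district":
            return e.district_id
        if group_by == "province":
            if province_of is None:
                raise ValueError("grouping by province requires a province_of mapping")
            return province_of[e.district_id]
        if group_by == "year":
            return e.year_of_start
        return e.season_of_start

    keys = [key(e) for e in events]
    if groups is None:
        if group_by == "season":
            groups = list(SEASON_ORDER)
        elif group_by == "year" and keys:
            groups = list(range(min(keys), max(keys) + 1))
        else:
            groups = sorted(set(keys))
    rows = []
    for g in groups:
        sub = [e for e, k in zip(events, keys) if k == g]
        rows.append(
            {
                group_by: g,
                "n_events": len(sub),
                "event_days": sum(e.duration for e in sub),
                "max_duration": max((e.duration for e in sub), default=0),
                "max_peak_dtr": max((e.peak_dtr for e in sub), default=0.0),
            }
        )
    return pd.DataFrame(rows, columns=[group_by, "n_events", "event_days", "max_duration", "max_peak_dtr"])
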