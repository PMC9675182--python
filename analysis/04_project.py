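#!/usr/bin/env python
"""Project heatwave events under two warming scenarios, 2020-2039.

Applies delta-change anomalies to the simulated observed series — a
moderate scenario (+1.2 degC tmax / +1.0 degC tmin, RCP 4.5-like) and a
high scenario (+1.8 / +1.6, RCP 8.5-like) for the near-term 20-year
horizon — re-runs detection with unchanged thresholds and MMTs, and
compares event counts by season and district.  Observed counts cover the
6-year base window, scenario counts the 20 projected years; the tables
report both raw counts and percent changes.
"""

import sys
from pathlib import Path

from dtrheat import (
    ThresholdConfig,
    apply_anomaly,
    compare_scenarios,
    derive_daily,
    detect_events,
    events_to_frame,
    read_daily_csv,
    read_district_meta,
)
from dtrheat.synthetic import generate_anomaly

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
TARGET = ("2020-01-01", "2039-12-31")
SCENARIOS = {"RCP4.5-like": (1.2, 1.0), "RCP8.5-like": (1.8, 1.6)}


def main() -> None:
    meta = read_district_meta(DATA / "meta.csv")
    loaded = read_daily_csv(DATA / "weather.csv", meta=meta)
    config = ThresholdConfig()
    province_of = {d: m.province for d, m in meta.items()}

    observed = []
    for district_id, series in sorted(loaded.series.items()):
        observed.extend(detect_events(derive_daily(series), meta[district_id], config))
    print(f"observed: {len(observed)} events "
          f"({sum(e.duration for e in observed)} event-days)")

    for name, (d_tmax, d_tmin) in SCENARIOS.items():
        fields = list(generate_anomaly(name, d_tmax, d_tmin,
                                       district_ids=sorted(loaded.series)))
        future = []
        for district_id, series in sorted(loaded.series.items()):
            fut = apply_anomaly(series, fields, meta[district_id], TARGET)
            future.extend(detect_events(derive_daily(fut), meta[district_id], config))
        tag = name.replace(".", "").replace("-", "_")
        # full future event tables are bulky and regenerable -> scratch/
        events_to_frame(future).to_csv(DATA / f"future_events_{tag}.csv", index=False)
        for key in ("season", "district"):
            comp = compare_scenarios(observed, future, key, scenario=name,
                                     province_of=province_of)
            comp.to_csv(RESULTS / f"comparison_{key}_{tag}.csv", index=False)
        summer = compare_scenarios(observed, future, "season",
                                   scenario=name).set_index("season").loc["summer"]
        print(f"{name}: {len(future)} events over 20 years "
              f"(+{d_tmax}/{d_tmin} degC); summer events "
              f"{summer['observed_events']} -> {summer['future_events']} "
              f"({summer['pct_change_events']:+.0f}%)")


if __name__ == "__main__":
    sys.exit(main())
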