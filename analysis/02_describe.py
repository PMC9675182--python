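#!/usr/bin/env python
"""Descriptive climatology of the simulated districts.

Computes per-district mean/SD/95th-percentile of tmax, tmin and DTR and
the per-district hot-day counts (days with DTR above the 12.8 degC
national threshold), then summarises the coastal vs inland DTR contrast
the detection step exploits.  Requires 01_simulate.py to have run.
"""

import sys
from pathlib import Path

import pandas as pd

from dtrheat import descriptive_table, hot_day_table, read_daily_csv, read_district_meta

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    meta = read_district_meta(DATA / "meta.csv")
    loaded = read_daily_csv(DATA / "weather.csv", meta=meta)
    loaded.qc.to_csv(RESULTS / "qc.csv")

    stats = descriptive_table(loaded.series, meta=meta)
    stats.to_csv(RESULTS / "descriptive_stats.csv", index=False)

    hot = hot_day_table(loaded.series)
    hot["coastal"] = hot["district_id"].map(lambda d: meta[d].coastal)
    hot.to_csv(RESULTS / "hot_days.csv", index=False)

    dtr = stats[stats["variable"] == "dtr"].set_index("district_id")
    coastal_mean = dtr.loc[[d for d in dtr.index if meta[d].coastal], "mean"].mean()
    inland_mean = dtr.loc[[d for d in dtr.index if not meta[d].coastal], "mean"].mean()
    print(f"mean DTR: coastal {coastal_mean:.1f} degC vs inland {inland_mean:.1f} degC")
    print(f"hot days per district: coastal median "
          f"{hot.loc[hot['coastal'], 'n_hot_days'].median():.0f}, "
          f"inland median {hot.loc[~hot['coastal'], 'n_hot_days'].median():.0f} "
          f"of {hot['n_days'].iloc[0]}")


if __name__ == "__main__":
    sys.exit(main())
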