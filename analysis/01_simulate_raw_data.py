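#!/usr/bin/env python
"""Simulate the raw longitudinal records the panel builder consumes.

Writes the four raw CSV tables (daily rainfall, monthly ranks, reproductive
event records, group census) to ``scratch/data/`` and a one-row summary of
their sizes to ``results/raw_data_summary.csv``.  The simulated world is a
null world: neither rainfall nor rank influences fertility, so downstream
derivative tests should find nothing.
"""

from pathlib import Path

import pandas as pd

from dcar import io as dio
from dcar.raw_records import RawDataConfig, simulate_raw_records

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SEED = 20240901


def generate(seed: int = SEED) -> dict:
    tables = simulate_raw_records(RawDataConfig(seed=seed))
    paths = dio.write_raw_tables(tables, DATA_DIR)
    summary = {
        "n_rain_days": len(tables.rain),
        "n_rank_entries": len(tables.ranks),
        "n_females": len(tables.females),
        "n_state_months": len(tables.states),
        "n_pregnancies": len(tables.pregnancies),
        "n_infants": len(tables.infants),
        "seed": seed,
    }
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame([summary]).to_csv(RESULTS / "raw_data_summary.csv", index=False)
    return {"paths": paths, "summary": summary}


if __name__ == "__main__":
    out = generate()
    print("raw tables written to", DATA_DIR)
    for k, v in out["summary"].items():
        print(f"  {k}: {v}")
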