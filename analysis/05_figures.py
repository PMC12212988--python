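#!/usr/bin/env python
"""Figure-style artifacts: delta histograms and binned-scatter plots.

For each built panel, writes the signed-delta histogram table and the
50-bin equal-count binned scatter (with its unadjusted quadratic overlay) as
CSV under ``results/figures/``, plus PNG renderings.
"""

import importlib.util
from pathlib import Path

from dcar import io as dio
from dcar.reporting import (
    binned_scatter,
    delta_histogram,
    plot_binned_scatter,
    plot_delta_histogram,
)

ROOT = Path(__file__).resolve().parents[1]
PANEL_DIR = ROOT / "scratch" / "panels"
OUT = ROOT / "results" / "figures"


def _ensure_panels():
    if not any(PANEL_DIR.glob("table_*.csv")):
        spec = importlib.util.spec_from_file_location(
            "build_panels", Path(__file__).parent / "02_build_panels.py"
        )
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        mod.build()


def run() -> list[str]:
    _ensure_panels()
    OUT.mkdir(parents=True, exist_ok=True)
    written = []
    for path in sorted(PANEL_DIR.glob("table_*.csv")):
        table = dio.read_analysis_table(path)
        key = path.stem.removeprefix("table_")
        bins, coefs = binned_scatter(table, x="delta")
        bins.to_csv(OUT / f"binned_{key}.csv", index=False)
        delta_histogram(table).to_csv(OUT / f"delta_hist_{key}.csv", index=False)
        plot_binned_scatter(table, OUT / f"binned_{key}.png", x="delta")
        plot_delta_histogram(table, OUT / f"delta_hist_{key}.png")
        written.append(key)
    return written


if __name__ == "__main__":
    keys = run()
    print(f"wrote histogram + binned-scatter artifacts for {len(keys)} panels:")
    for k in keys:
        print(" ", k)
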