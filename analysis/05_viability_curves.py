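#!/usr/bin/env python
"""Percent-viable curves per intervention time.

Strictly post hoc: reads the per-run trajectory tables written by
02_clearance_timing_sweep.py (no re-simulation), draws one apoptosis
threshold per cell from Normal(600, variance 50), finds each cell's first
grid time with total p53 above its threshold, and tabulates the
percentage of cells still alive over time per condition.  Writes
results/viability/viable_curves.csv and death_times.csv.
"""

import argparse
from pathlib import Path

import pandas as pd
import yaml

from adcycle.ssa import TrajectoryRecord
from adcycle.viability import ThresholdModel, viability_analysis


def load_condition(path: Path):
    df = pd.read_csv(path / "trajectories.csv")
    label = yaml.safe_load((path / "manifest.yaml").read_text())["experiment"]
    records = []
    for (run_id, seed), sub in df.groupby(["run_id", "seed"]):
        piv = sub.pivot_table(index="time", columns="observable",
                              values="count").sort_index()
        records.append(TrajectoryRecord(
            model_name=label, seed=int(seed), grid=piv.index.to_numpy(),
            series={c: piv[c].to_numpy() for c in piv.columns},
            first_passage={}))
    return label, records


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sweep-dir", default="results/clearance_sweep")
    ap.add_argument("--mean", type=float, default=600.0)
    ap.add_argument("--variance", type=float, default=50.0)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/viability")
    args = ap.parse_args()

    sweep = Path(args.sweep_dir)
    condition_dirs = sorted(sweep.glob("day_*"))
    if not condition_dirs:
        raise SystemExit(f"no conditions under {sweep}; "
                         "run 02_clearance_timing_sweep.py first")

    conditions = dict(load_condition(d) for d in condition_dirs)
    results = viability_analysis(
        conditions, ThresholdModel(mean=args.mean, variance=args.variance),
        seed=args.seed)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    curve_rows, death_rows = [], []
    for label, res in results.items():
        for t, v in zip(res.grid, res.viable_curve):
            curve_rows.append({"time": t, "percent_viable": v,
                               "condition": label})
        for seed, thr, dt in res.per_run:
            death_rows.append({"condition": label, "seed": seed,
                               "threshold": thr, "death_time": dt})
    pd.DataFrame(curve_rows).to_csv(out / "viable_curves.csv", index=False)
    pd.DataFrame(death_rows).to_csv(out / "death_times.csv", index=False)

    print(f"viability (threshold ~ N({args.mean:.0f}, var {args.variance:.0f})):")
    for label in sorted(results, key=lambda s: (len(s), s)):
        res = results[label]
        deaths = sum(dt is not None for _, _, dt in res.per_run)
        print(f"  {label:>20}: {res.viable_curve[-1]:5.1f}% viable at day 12 "
              f"({deaths} deaths / {len(res.per_run)})")


if __name__ == "__main__":
    main()
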