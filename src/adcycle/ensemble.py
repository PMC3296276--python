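"""Ensemble orchestration, summary statistics and artifact serialisation.

An ensemble is n independent trajectories of one model, with run seeds
derived as ``base_seed + run_index`` so that any single run can be
regenerated in isolation.  Summaries hold the per-grid-time mean and
standard deviation (sample sd, n-1 denominator; reported as 0 for n=1) of
every recorded observable, the fraction of runs that formed at least one
plaque / tangle, and the ensemble medians of the first-passage times
(censored runs enter the median as +infinity; a censored median is
reported as None).

All headline artifacts are tidy, comma-separated text with a header row;
the manifest is YAML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelDefinition
from .ssa import CompiledModel, DEFAULT_GRID_STEP, TrajectoryRecord, simulate

__all__ = ["RunManifest", "EnsembleSummary", "run_ensemble", "summarize",
           "median_first_aggregate", "write_outputs", "read_summary"]

SOFTWARE_VERSION = "0.1.0"


@dataclass
class RunManifest:
    experiment: str
    model_hash: str
    parameters: dict
    n_runs: int
    base_seed: int
    seeds: list
    grid_step: float
    created: str = ""
    software_version: str = SOFTWARE_VERSION


@dataclass
class EnsembleSummary:
    plan_name: str
    grid: np.ndarray
    mean_series: dict
    sd_series: dict
    n_runs: int
    fraction_with_plaque_by_end: float
    fraction_with_tangle_by_end: float
    median_first_plaque: float | None
    median_first_tangle: float | None


def run_ensemble(model: ModelDefinition, n_runs: int, base_seed: int,
                 grid_step: float = DEFAULT_GRID_STEP):
    """Simulate ``n_runs`` independent trajectories (seeds base_seed+i).

    Returns ``(records, manifest)``.  Any failing run aborts the ensemble
    with its seed named.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cm = CompiledModel(model)
    seeds = [int(base_seed) + i for i in range(n_runs)]
    records = []
    for s in seeds:
        try:
            records.append(simulate(cm, s, grid_step))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"simulation failed for seed {s}: {exc}") from exc
    manifest = RunManifest(
        experiment=model.name,
        model_hash=model.model_hash(),
        parameters=model.parameter_map(),
        n_runs=n_runs,
        base_seed=int(base_seed),
        seeds=seeds,
        grid_step=float(grid_step),
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    return records, manifest


def _median_or_censored(times):
    arr = np.array([math.inf if t is None else t for t in times], dtype=float)
    med = float(np.median(arr))
    return None if math.isinf(med) else med


def summarize(trajectories, plan_name: str = "") -> EnsembleSummary:
    """Per-time mean and sd over runs plus aggregate-formation statistics."""
    if not trajectories:
        raise ValueError("cannot summarize an empty trajectory list")
    grid = trajectories[0].grid
    for tr in trajectories[1:]:
        if len(tr.grid) != len(grid) or not np.array_equal(tr.grid, grid):
            raise ValueError("trajectories do not share a common recording grid")
    n = len(trajectories)
    names = sorted(trajectories[0].series)
    mean_series, sd_series = {}, {}
    for name in names:
        stack = np.stack([tr.series[name] for tr in trajectories]).astype(float)
        mean_series[name] = stack.mean(axis=0)
        sd_series[name] = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(len(grid))

    fp = [tr.first_passage.get("first_plaque") for tr in trajectories]
    ft = [tr.first_passage.get("first_tangle") for tr in trajectories]
    return EnsembleSummary(
        plan_name=plan_name or trajectories[0].model_name,
        grid=grid,
        mean_series=mean_series,
        sd_series=sd_series,
        n_runs=n,
        fraction_with_plaque_by_end=sum(t is not None for t in fp) / n,
        fraction_with_tangle_by_end=sum(t is not None for t in ft) / n,
        median_first_plaque=_median_or_censored(fp),
        median_first_tangle=_median_or_censored(ft),
    )


def median_first_aggregate(trajectories) -> float | None:
    """Ensemble median of each run's earliest aggregate (plaque or tangle)
    appearance time; None if the median run never formed either."""
    times = []
    for tr in trajectories:
        per_run = [t for t in (tr.first_passage.get("first_plaque"),
                               tr.first_passage.get("first_tangle")) if t is not None]
        times.append(min(per_run) if per_run else None)
    return _median_or_censored(times)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def summary_frame(summary: EnsembleSummary) -> pd.DataFrame:
    frames = []
    for name in sorted(summary.mean_series):
        frames.append(pd.DataFrame({
            "time": summary.grid,
            "observable": name,
            "mean": summary.mean_series[name],
            "sd": summary.sd_series[name],
        }))
    return pd.concat(frames, ignore_index=True)


def trajectory_frame(trajectories) -> pd.DataFrame:
    frames = []
    for run_id, tr in enumerate(trajectories):
        for name in sorted(tr.series):
            frames.append(pd.DataFrame({
                "time": tr.grid,
                "observable": name,
                "count": tr.series[name],
                "run_id": run_id,
                "seed": tr.seed,
            }))
    return pd.concat(frames, ignore_index=True)


def write_outputs(summary: EnsembleSummary, trajectories, manifest: RunManifest,
                  out_dir, overwrite: bool = False):
    """Write summary.csv, trajectories.csv, ensemble_stats.csv, manifest.yaml.

    Refuses a non-empty ``out_dir`` unless ``overwrite`` is set. Returns the
    list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = list(out.iterdir())
    if existing and not overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty; pass overwrite=True to replace")

    paths = []

    p = out / "summary.csv"
    summary_frame(summary).to_csv(p, index=False)
    paths.append(p)

    p = out / "trajectories.csv"
    trajectory_frame(trajectories).to_csv(p, index=False)
    paths.append(p)

    p = out / "ensemble_stats.csv"
    pd.DataFrame([{
        "plan": summary.plan_name,
        "n_runs": summary.n_runs,
        "fraction_with_plaque_by_end": summary.fraction_with_plaque_by_end,
        "fraction_with_tangle_by_end": summary.fraction_with_tangle_by_end,
        "median_first_plaque": summary.median_first_plaque,
        "median_first_tangle": summary.median_first_tangle,
    }]).to_csv(p, index=False)
    paths.append(p)

    p = out / "first_passage.csv"
    pd.DataFrame([{
        "run_id": i,
        "seed": tr.seed,
        "first_plaque": tr.first_passage.get("first_plaque"),
        "first_tangle": tr.first_passage.get("first_tangle"),
    } for i, tr in enumerate(trajectories)]).to_csv(p, index=False)
    paths.append(p)

    p = out / "manifest.yaml"
    p.write_text(yaml.safe_dump(vars(manifest), sort_keys=False))
    paths.append(p)

    return paths


def read_summary(out_dir) -> EnsembleSummary:
    """Reconstruct an EnsembleSummary from a written output directory."""
    out = Path(out_dir)
    df = pd.read_csv(out / "summary.csv")
    stats = pd.read_csv(out / "ensemble_stats.csv").iloc[0]
    grid = np.array(sorted(df["time"].unique()))
    mean_series, sd_series = {}, {}
    for name, sub in df.groupby("observable"):
        sub = sub.sort_values("time")
        mean_series[name] = sub["mean"].to_numpy()
        sd_series[name] = sub["sd"].to_numpy()

    def opt(v):
        return None if pd.isna(v) else float(v)

    return EnsembleSummary(
        plan_name=str(stats["plan"]),
        grid=grid,
        mean_series=mean_series,
        sd_series=sd_series,
        n_runs=int(stats["n_runs"]),
        fraction_with_plaque_by_end=float(stats["fraction_with_plaque_by_end"]),
        fraction_with_tangle_by_end=float(stats["fraction_with_tangle_by_end"]),
        median_first_plaque=opt(stats["median_first_plaque"]),
        median_first_tangle=opt(stats["median_first_tangle"]),
    )
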