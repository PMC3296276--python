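"""Scripted in-silico experiments on the default AD network.

Four protocols are reproduced:

* **baseline** — the unmodified network, 100 cells, 12 days;
* **clearance timing sweep** — soluble-Abeta clearance multiplied by 100 at
  day 0, 2, 4, 6 or 8 (plus a labelled no-intervention condition);
* **ROS blockade** — Abeta-mediated ROS production zeroed from t=0, with a
  day-8 clearance boost layered on top;
* **binding blockade** — GSK3beta/p53 binding zeroed from t=0, likewise
  with the day-8 clearance boost.

Per-condition run seeds are derived from the experiment base seed and the
condition label (CRC32 offset), so conditions are independent of the order
in which they are executed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

from .model import (
    InterventionSpec,
    ModelDefinition,
    apply_intervention,
    build_default_network,
)
from .ensemble import EnsembleSummary, run_ensemble, summarize
from .ssa import DEFAULT_GRID_STEP

__all__ = ["NO_INTERVENTION", "ExperimentPlan", "CalibrationError",
           "condition_seed", "run_condition", "run_baseline",
           "run_clearance_sweep", "run_ros_block", "run_binding_block",
           "close_to_zero"]

#: explicit sentinel for the unmodified-clearance condition
NO_INTERVENTION = "none"

#: minimum ensemble size at which the built-in calibration checks engage
CALIBRATION_N = 100


class CalibrationError(AssertionError):
    """The default parameter set failed one of its contracted ensemble
    behaviours."""


@dataclass
class ExperimentPlan:
    name: str
    base_model: ModelDefinition
    intervention: InterventionSpec
    n_runs: int = 100
    base_seed: int = 0
    grid_step: float = DEFAULT_GRID_STEP

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def condition_seed(base_seed: int, label: str) -> int:
    """Deterministic per-condition seed offset (order-independent)."""
    return (int(base_seed) + zlib.crc32(str(label).encode())) % (2**31)


def run_condition(plan: ExperimentPlan):
    """Execute one plan; returns ``(records, summary, manifest)``."""
    model = apply_intervention(plan.base_model, plan.intervention)
    model.name = plan.name
    records, manifest = run_ensemble(model, plan.n_runs,
                                     condition_seed(plan.base_seed, plan.name),
                                     plan.grid_step)
    return records, summarize(records, plan.name), manifest


def _end(summary: EnsembleSummary, observable: str) -> float:
    return float(summary.mean_series[observable][-1])


def close_to_zero(value: float, reference: float | None = None) -> bool:
    """The working definition of a "close to zero" ensemble mean: below one
    copy absolutely and, when a no-intervention reference is given, below
    2% of it."""
    if value >= 1.0:
        return False
    return reference is None or value < 0.02 * max(reference, 1e-12)


def run_baseline(n_runs: int = 100, base_seed: int = 0, *,
                 params: dict | None = None,
                 grid_step: float = DEFAULT_GRID_STEP,
                 check_calibration: bool | None = None) -> EnsembleSummary:
    """Ensemble of the unmodified model.

    For ensembles of >= 100 runs (or with ``check_calibration=True``) the
    contracted baseline phenotypes are asserted: a majority of cells form
    both plaques and tangles by day 12, a nonzero minority form neither,
    and tangles precede plaques in the ensemble median.
    """
    plan = ExperimentPlan("baseline", build_default_network(params),
                          InterventionSpec("none"), n_runs, base_seed, grid_step)
    records, summary, _ = run_condition(plan)

    if check_calibration is None:
        check_calibration = n_runs >= CALIBRATION_N
    if check_calibration:
        if not (summary.fraction_with_plaque_by_end > 0.5
                and summary.fraction_with_tangle_by_end > 0.5):
            raise CalibrationError(
                "baseline: a majority of runs must form both plaques and tangles "
                f"(got plaque {summary.fraction_with_plaque_by_end:.2f}, "
                f"tangle {summary.fraction_with_tangle_by_end:.2f})")
        none_frac = sum(
            tr.first_passage["first_plaque"] is None
            and tr.first_passage["first_tangle"] is None
            for tr in records) / len(records)
        if none_frac <= 0:
            raise CalibrationError(
                "baseline: a nonzero minority of runs must form no aggregates")
        mfp, mft = summary.median_first_plaque, summary.median_first_tangle
        if mft is not None and mfp is not None and not mft < mfp:
            raise CalibrationError(
                f"baseline: median first tangle ({mft:.2f} d) must precede "
                f"median first plaque ({mfp:.2f} d)")
    return summary


def run_clearance_sweep(days=(0, 2, 4, 6, 8, NO_INTERVENTION),
                        n_runs: int = 100, base_seed: int = 0, *,
                        params: dict | None = None,
                        grid_step: float = DEFAULT_GRID_STEP) -> dict:
    """One ensemble per clearance-boost start day.

    ``days`` may mix numbers in [0, horizon] with the NO_INTERVENTION
    sentinel; returns a mapping from each entry to its summary.
    """
    base = build_default_network(params)
    out = {}
    for day in days:
        if day == NO_INTERVENTION:
            spec = InterventionSpec("none")
            label = NO_INTERVENTION
        else:
            day = float(day)
            if not (0 <= day <= base.horizon):
                raise ValueError(f"intervention day {day} outside [0, {base.horizon}]")
            spec = InterventionSpec("clearance_boost", start_day=day)
            label = day
        plan = ExperimentPlan(f"clearance_day_{label}", base, spec,
                              n_runs, base_seed, grid_step)
        _, summary, _ = run_condition(plan)
        out[label] = summary
    return out


def _run_blockade(kind: str, n_runs: int, base_seed: int, params, grid_step,
                  check, zero_observables):
    plan = ExperimentPlan(kind, build_default_network(params),
                          InterventionSpec(kind), n_runs, base_seed, grid_step)
    _, summary, _ = run_condition(plan)
    if check is None:
        check = n_runs >= CALIBRATION_N
    if check:
        for obs in zero_observables:
            if not close_to_zero(_end(summary, obs)):
                raise CalibrationError(
                    f"{kind}: end-of-run mean {obs} = {_end(summary, obs):.3f} "
                    "is not close to zero")
    return summary


def run_ros_block(n_runs: int = 100, base_seed: int = 0, *,
                  params: dict | None = None,
                  grid_step: float = DEFAULT_GRID_STEP,
                  check_calibration: bool | None = None) -> EnsembleSummary:
    """Abeta-mediated ROS production zeroed from t=0 plus a day-8 clearance
    boost; plaques, tangles, damaged DNA and GSK3b_p53 all end close to
    zero (checked for ensembles of >= 100 runs)."""
    return _run_blockade("ros_block", n_runs, base_seed, params, grid_step,
                         check_calibration,
                         ("abeta_plaque", "tau_tangles", "damDNA", "GSK3b_p53"))


def run_binding_block(n_runs: int = 100, base_seed: int = 0, *,
                      params: dict | None = None,
                      grid_step: float = DEFAULT_GRID_STEP,
                      check_calibration: bool | None = None) -> EnsembleSummary:
    """GSK3beta/p53 binding zeroed from t=0 plus a day-8 clearance boost;
    plaques and tangles end close to zero while total p53 still rises
    (checked for ensembles of >= 100 runs)."""
    summary = _run_blockade("binding_block", n_runs, base_seed, params,
                            grid_step, check_calibration,
                            ("abeta_plaque", "tau_tangles"))
    check = check_calibration if check_calibration is not None else n_runs >= CALIBRATION_N
    if check:
        p53 = summary.mean_series["total_p53"]
        if not p53[-1] > p53[0]:
            raise CalibrationError(
                "binding_block: mean total p53 should rise over the run "
                f"(start {p53[0]:.1f}, end {p53[-1]:.1f})")
    return summary
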