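"""Post-hoc neuronal-viability analysis.

Cell death is not a reaction in the network; instead each simulated cell
is assigned an apoptosis threshold on total p53 drawn from a normal
distribution (mean 600 copies, variance 50 — i.e. sd ~7.07, taken as
printed), clipped below at a floor of 1.  A cell dies at the first
recording-grid time at which its total p53 pool strictly exceeds its
threshold; cells that never cross are censored at the horizon.  The
percent-viable curve of a condition is the fraction of its runs still
alive at each grid time.

Thresholds are drawn from a stream independent of the trajectory RNG, so
re-analysis with a different threshold seed needs no re-simulation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThresholdModel", "ViabilityResult", "sample_threshold",
           "first_passage_time", "viability_analysis"]


@dataclass(frozen=True)
class ThresholdModel:
    """Distribution of the per-cell apoptotic p53 threshold."""

    mean: float = 600.0
    variance: float = 50.0
    floor: float = 1.0

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("threshold mean must be positive")
        if self.variance < 0:
            raise ValueError("threshold variance must be >= 0")


@dataclass
class ViabilityResult:
    condition: str
    per_run: list  # (seed, threshold, death_time or None)
    grid: np.ndarray
    viable_curve: np.ndarray = field(default=None)  # percent alive per grid time


def sample_threshold(model: ThresholdModel, rng: np.random.Generator) -> float:
    """One draw from Normal(mean, sd=sqrt(variance)), clipped at the floor."""
    draw = rng.normal(model.mean, math.sqrt(model.variance))
    return max(float(draw), float(model.floor))


def first_passage_time(trajectory, threshold: float):
    """Earliest grid time with total_p53 strictly above ``threshold``;
    None (censored) if the trajectory never crosses."""
    series = trajectory.observable("total_p53")
    above = np.nonzero(series > threshold)[0]
    if len(above) == 0:
        return None
    return float(trajectory.grid[above[0]])


def _viable_curve(death_times, grid) -> np.ndarray:
    n = len(death_times)
    deaths = np.array([t for t in death_times if t is not None], dtype=float)
    dead_by = (deaths[None, :] <= grid[:, None]).sum(axis=1) if len(deaths) else \
        np.zeros(len(grid), dtype=int)
    return 100.0 * (1.0 - dead_by / n)


def viability_analysis(condition_trajectories: dict,
                       threshold_model: ThresholdModel = ThresholdModel(),
                       seed: int = 0) -> dict:
    """Per-condition death times and percent-viable curves.

    ``condition_trajectories`` maps condition labels to lists of
    TrajectoryRecords sharing one grid.  Each run receives a fresh
    threshold; the per-condition threshold streams are derived from
    ``seed`` and the condition label, so results do not depend on the
    order (or subset) of conditions analysed.  Never re-simulates.
    """
    if not condition_trajectories:
        raise ValueError("no conditions supplied")
    grids = [trs[0].grid for trs in condition_trajectories.values() if trs]
    if len(grids) != len(condition_trajectories):
        raise ValueError("every condition needs at least one trajectory")
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.array_equal(g, grids[0]):
            raise ValueError("conditions must share a common recording grid")

    out = {}
    for label, trajectories in condition_trajectories.items():
        sub_seed = (int(seed) + zlib.crc32(str(label).encode())) % (2**31)
        rng = np.random.Generator(np.random.PCG64(sub_seed))
        per_run = []
        deaths = []
        for tr in trajectories:
            thr = sample_threshold(threshold_model, rng)
            dt = first_passage_time(tr, thr)
            per_run.append((tr.seed, thr, dt))
            deaths.append(dt)
        out[label] = ViabilityResult(
            condition=str(label),
            per_run=per_run,
            grid=grids[0],
            viable_curve=_viable_curve(deaths, grids[0]),
        )
    return out
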