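"""Shared fixtures.

The expensive ensembles are session-scoped and reused across test modules:
the 100-run protected (day-0 clearance boost) and elevated-production
ensembles back the headline zero-aggregate / early-onset checks, the
100-run baseline backs the calibration phenotypes, and the 60-run sweep
conditions back the intervention-timing comparisons.

All conditions share one base seed (common random numbers): paired runs
have identical histories up to the intervention time, so between-condition
comparisons isolate the intervention effect rather than between-stream
Monte-Carlo variation.
"""

import numpy as np
import pytest

import adcycle as a

SEED = 0
GRID = 0.05


@pytest.fixture(scope="session")
def default_model():
    return a.build_default_network()


@pytest.fixture(scope="session")
def baseline_records(default_model):
    records, _ = a.run_ensemble(default_model, 100, SEED, GRID)
    return records


@pytest.fixture(scope="session")
def baseline_summary(baseline_records):
    return a.summarize(baseline_records, "baseline")


@pytest.fixture(scope="session")
def day0_records(default_model):
    protected = a.apply_intervention(
        default_model, a.InterventionSpec("clearance_boost", start_day=0))
    records, _ = a.run_ensemble(protected, 100, SEED, GRID)
    return records


@pytest.fixture(scope="session")
def elevated_records():
    model = a.build_default_network(a.elevated_abeta_production())
    records, _ = a.run_ensemble(model, 100, SEED, GRID)
    return records


def _sweep_condition(day, n_runs=60):
    base = a.build_default_network()
    model = a.apply_intervention(
        base, a.InterventionSpec("clearance_boost", start_day=day))
    records, _ = a.run_ensemble(model, n_runs, SEED, GRID)
    return records


@pytest.fixture(scope="session")
def day2_records():
    return _sweep_condition(2)


@pytest.fixture(scope="session")
def day4_records():
    return _sweep_condition(4)


@pytest.fixture(scope="session")
def day6_records():
    return _sweep_condition(6)


@pytest.fixture(scope="session")
def day8_records():
    return _sweep_condition(8)


def end_mean(records, observable):
    return float(np.mean([r.series[observable][-1] for r in records]))


def end_se(records, observable):
    vals = [r.series[observable][-1] for r in records]
    return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))


def ci_overlap(records_a, records_b, observable):
    """95% Monte-Carlo confidence intervals of the end-of-run means overlap."""
    gap = abs(end_mean(records_a, observable) - end_mean(records_b, observable))
    return gap <= 1.96 * (end_se(records_a, observable)
                          + end_se(records_b, observable))
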