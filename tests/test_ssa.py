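"""Exactness, determinism and event semantics of the Gillespie engine."""

import itertools
from math import comb, exp

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adcycle as a
from adcycle.model import ModelDefinition, Parameter, Reaction, Species, TimedEvent
from adcycle.ssa import CompiledModel, SimState, advance, propensity, simulate


def tiny_model(reactions, species, params, events=(), horizon=12.0):
    return ModelDefinition(
        name="tiny",
        species=[Species(id=s, initial_count=n) for s, n in species],
        parameters=[Parameter(id=k, value=v) for k, v in params],
        reactions=reactions,
        events=list(events),
        horizon=horizon,
    )


def birth_death(k=5.0, gamma=1.0, x0=0, horizon=12.0, events=()):
    return tiny_model(
        reactions=[
            Reaction("birth", (), (("X", 1),), rate_parameter="k"),
            Reaction("death", (("X", 1),), (), rate_parameter="gamma"),
        ],
        species=[("X", x0)],
        params=[("k", k), ("gamma", gamma)],
        events=events,
        horizon=horizon,
    )


class TestPropensity:
    def _state(self, counts, params):
        return SimState(0.0, counts, params, [])

    def test_constant_source(self):
        r = Reaction("src", (), (("X", 1),), rate_parameter="k")
        assert propensity(r, self._state({"X": 0}, {"k": 4.0})) == 4.0

    def test_empty_reactant_pool(self):
        r = Reaction("deg", (("X", 1),), (), rate_parameter="k")
        assert propensity(r, self._state({"X": 0}, {"k": 2.0})) == 0.0

    def test_homodimerisation_matches_pair_enumeration(self):
        r = Reaction("dim", (("X", 2),), (("Y", 1),), rate_parameter="k")
        n = 5
        n_pairs = len(list(itertools.combinations(range(n), 2)))
        assert n_pairs == 10
        assert propensity(r, self._state({"X": n}, {"k": 1.0})) == n_pairs

    def test_trimolecular_uses_triple_combinations(self):
        r = Reaction("tri", (("X", 3),), (("Y", 1),), rate_parameter="k")
        for n in (0, 1, 2, 3, 7):
            got = propensity(r, self._state({"X": n}, {"k": 2.0}))
            assert got == 2.0 * comb(n, 3)

    def test_modifier_scales_and_zero_modifier_silences(self):
        r = Reaction("mod", (), (("X", 1),), modifiers=("M",),
                     rate_parameter="k", kinetics="modifier_mass_action")
        assert propensity(r, self._state({"M": 3}, {"k": 2.0})) == 6.0
        assert propensity(r, self._state({"M": 0}, {"k": 2.0})) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40))
    def test_vectorised_engine_agrees_with_scalar_definition(self, n_m, n_o):
        model = a.build_default_network()
        cm = CompiledModel(model)
        state = cm.initial_state()
        state.counts["AbetaM"] = n_m
        state.counts["AbetaO"] = n_o
        counts_ext = np.append(
            [state.counts[s] for s in cm.species_ids], 1).astype(np.int64)
        vec = cm.propensities(counts_ext, cm.init_params)
        for j, r in enumerate(model.reactions):
            assert vec[j] == pytest.approx(propensity(r, state))


class TestAdvance:
    def test_forced_event_when_nothing_can_fire(self):
        model = birth_death(k=0.0, gamma=1.0, x0=0,
                            events=[TimedEvent(8.0, "k", "set_value", 5.0)])
        cm = CompiledModel(model)
        state, fired = advance(cm, cm.initial_state(),
                               np.random.default_rng(0))
        assert state.time == 8.0
        assert fired == "event:k"
        assert state.param_values["k"] == 5.0
        assert state.counts == {"X": 0}

    def test_waiting_time_has_exponential_mean(self):
        model = birth_death(k=1.0, gamma=0.0, x0=0, horizon=1e6)
        cm = CompiledModel(model)
        rng = np.random.default_rng(42)
        n = 4000
        taus = []
        state = cm.initial_state()
        for _ in range(n):
            new, fired = advance(cm, state, rng)
            taus.append(new.time - state.time)
            state = new
        # tau ~ Exp(1): mean 1, sd 1; allow 3 standard errors
        assert abs(np.mean(taus) - 1.0) < 3 / np.sqrt(n)

    def test_multiply_event_scales_parameter_exactly_100x(self):
        model = birth_death(k=0.0, gamma=0.3, x0=0,
                            events=[TimedEvent(8.0, "gamma", "multiply", 100.0)])
        cm = CompiledModel(model)
        state, fired = advance(cm, cm.initial_state(), np.random.default_rng(1))
        assert fired == "event:gamma"
        assert state.param_values["gamma"] == pytest.approx(0.3 * 100.0, rel=0, abs=0)


class TestSimulate:
    def test_no_reactions_gives_constant_series(self):
        model = tiny_model(reactions=[], species=[("X", 7)], params=[])
        tr = simulate(model, seed=3)
        assert np.all(tr.series["X"] == 7)
        assert len(tr.grid) == 241

    def test_same_seed_bit_identical_across_events(self):
        model = birth_death(k=5.0, gamma=1.0,
                            events=[TimedEvent(6.0, "k", "multiply", 10.0)])
        a_, b_ = simulate(model, 11), simulate(model, 11)
        assert np.array_equal(a_.grid, b_.grid)
        for key in a_.series:
            assert np.array_equal(a_.series[key], b_.series[key])
        assert a_.first_passage == b_.first_passage

    def test_different_seeds_differ(self):
        model = birth_death()
        assert not np.array_equal(simulate(model, 1).series["X"],
                                  simulate(model, 2).series["X"])

    def test_birth_death_time_average_matches_stationary_mean(self):
        # X* ~ Poisson(k/gamma); long-run time average within 3 MC standard
        # errors of 8.0 (correlation time 1/gamma ~ 1 day)
        k, gamma, horizon = 8.0, 1.0, 400.0
        model = birth_death(k=k, gamma=gamma, horizon=horizon)
        tr = simulate(model, seed=5, grid_step=0.5)
        x = tr.series["X"][40:]  # discard burn-in
        n_eff = len(x) / (2 / 0.5)  # ~one independent sample per 2/gamma days
        se = np.sqrt(k / gamma / n_eff)
        assert abs(x.mean() - k / gamma) < 3 * se

    def test_linear_cascade_matches_master_equation_moments(self):
        # production -> A -> B -> 0: the stationary law is product Poisson
        # with E[A]=k/c, E[B]=k/d; means and variances checked at t=8
        # against the closed form over 1500 replicate runs.
        k, c, d = 8.0, 2.0, 1.0
        model = tiny_model(
            reactions=[
                Reaction("prod", (), (("A", 1),), rate_parameter="k"),
                Reaction("conv", (("A", 1),), (("B", 1),), rate_parameter="c"),
                Reaction("deg", (("B", 1),), (), rate_parameter="d"),
            ],
            species=[("A", 0), ("B", 0)],
            params=[("k", k), ("c", c), ("d", d)],
            horizon=8.0,
        )
        cm = CompiledModel(model)
        n = 1500
        finals = np.array([[simulate(cm, s, grid_step=8.0).series[sp][-1]
                            for sp in ("A", "B")] for s in range(n)])
        t = 8.0
        lam_a = k / c * (1 - exp(-c * t))
        lam_b = k * ((1 - exp(-d * t)) / d
                     - (exp(-c * t) - exp(-d * t)) / (d - c))
        for idx, lam in ((0, lam_a), (1, lam_b)):
            mean_se = np.sqrt(lam / n)
            assert abs(finals[:, idx].mean() - lam) < 3 * mean_se
            var_se = np.sqrt((2 * lam**2 + lam) / n)
            assert abs(finals[:, idx].var(ddof=1) - lam) < 3 * var_se

    def test_event_bracketing_on_grid(self):
        # source switched on at t=8 exactly; sampling with a binary-exact
        # step: counts are zero strictly before 8 and grow after
        model = birth_death(k=0.0, gamma=0.0,
                            events=[TimedEvent(8.0, "k", "set_value", 50.0)])
        tr = simulate(model, seed=9, grid_step=0.25)
        x = tr.series["X"]
        before = tr.grid < 8.0
        assert np.all(x[before] == 0)
        assert x[-1] > 0

    def test_counts_never_negative(self, baseline_records):
        tr = baseline_records[0]
        for series in tr.series.values():
            assert series.min() >= 0

    def test_first_passage_times_recorded_or_censored(self, baseline_records):
        for tr in baseline_records[:20]:
            fp = tr.first_passage["first_plaque"]
            if fp is None:
                assert tr.series["abeta_plaque"][-1] == 0
            else:
                assert 0 <= fp <= 12
                # plaque count is zero strictly before the recorded time
                assert np.all(tr.series["abeta_plaque"][tr.grid < fp] == 0)

    def test_invalid_model_rejected_before_stepping(self):
        model = birth_death()
        model.parameters[0] = Parameter("k", -2.0)
        with pytest.raises(a.InvalidModelError):
            simulate(model, 1)
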