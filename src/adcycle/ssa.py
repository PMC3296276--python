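"""Exact stochastic simulation (Gillespie direct method) with timed events.

Propensities follow the discrete mass-action convention: a reaction with
stoichiometry *s* in a reactant with copy number *n* contributes the
combinatoric factor C(n, s) (so n(n-1)/2 for a homodimerisation), and each
modifier multiplies the propensity by its current copy number.  Timed
events interrupt the exponential waiting time: if the drawn jump would
pass the next event's fire time, no reaction fires — the clock moves to
the event, the parameter change is applied, and a fresh waiting time is
drawn (justified by the memorylessness of the exponential).

Trajectories are recorded piecewise-constant on a fixed grid: the value at
grid time t is the state after the last reaction or event at or before t;
when an event coincides with a grid point the post-event state is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, inf

import numpy as np

from .model import (
    ModelDefinition,
    OBSERVABLES,
    P53_POOL,
    Reaction,
    TOTAL_P53_TAG,
    assert_valid,
)

__all__ = ["SimState", "TrajectoryRecord", "CompiledModel", "propensity",
           "advance", "simulate"]

DEFAULT_GRID_STEP = 0.05  # days (~240 samples over the 12-day horizon)


@dataclass
class SimState:
    """Instantaneous simulator state: clock, copy numbers, live parameter
    values and the events still to fire (ordered by fire_time)."""

    time: float
    counts: dict
    param_values: dict
    pending_events: list = field(default_factory=list)


@dataclass
class TrajectoryRecord:
    """One simulated cell.

    ``series`` maps every species id plus each registered observable to a
    per-grid-point count vector. ``first_passage`` holds the exact times at
    which the plaque and tangle counts first reached 1 (None = censored:
    never within the horizon).
    """

    model_name: str
    seed: int
    grid: np.ndarray
    series: dict
    first_passage: dict

    def observable(self, name: str) -> np.ndarray:
        if name not in self.series:
            raise KeyError(
                f"observable {name!r} not recorded; available: {sorted(self.series)}")
        return self.series[name]


def propensity(reaction: Reaction, state: SimState) -> float:
    """Mass-action propensity of one reaction in the given state.

    Reference (scalar) implementation; the simulation loop uses the
    vectorised equivalent in :class:`CompiledModel`.
    """
    k = state.param_values[reaction.rate_parameter]
    a = float(k)
    for sid, s in reaction.reactants:
        n = state.counts.get(sid, 0)
        if n < s:
            return 0.0
        a *= comb(n, s)
    if reaction.kinetics == "modifier_mass_action":
        for sid in reaction.modifiers:
            a *= state.counts.get(sid, 0)
    return a


class CompiledModel:
    """Array representation of a ModelDefinition for the inner SSA loop."""

    def __init__(self, model: ModelDefinition):
        assert_valid(model)
        self.model = model
        self.species_ids = model.species_ids()
        self.s_index = {sid: i for i, sid in enumerate(self.species_ids)}
        self.n_species = len(self.species_ids)
        self.param_ids = [p.id for p in model.parameters]
        self.p_index = {pid: i for i, pid in enumerate(self.param_ids)}
        self.init_params = np.array([p.value for p in model.parameters], dtype=float)
        self.init_counts = np.array(
            [s.initial_count for s in model.species], dtype=np.int64)
        self.horizon = float(model.horizon)

        R = len(model.reactions)
        self.n_reactions = R
        self.reaction_ids = [r.id for r in model.reactions]
        self.k_idx = np.array(
            [self.p_index[r.rate_parameter] for r in model.reactions], dtype=np.intp)

        # multiplicative slots: (species index, stoichiometry); stoich 0 = unused
        slots = []
        for r in model.reactions:
            terms = [(self.s_index[sid], s) for sid, s in r.reactants]
            if r.kinetics == "modifier_mass_action":
                terms += [(self.s_index[sid], 1) for sid in r.modifiers]
            slots.append(terms)
        self.max_slots = max((len(t) for t in slots), default=0)
        # dummy species index with constant count 1 backs unused slots
        dummy = self.n_species
        self.slot_idx = np.full((self.max_slots, R), dummy, dtype=np.intp)
        self.slot_sto = np.zeros((self.max_slots, R), dtype=np.int64)
        for j, terms in enumerate(slots):
            for k, (si, st) in enumerate(terms):
                self.slot_idx[k, j] = si
                self.slot_sto[k, j] = st
        self.general_slots = bool((self.slot_sto > 2).any())

        # net state changes per reaction
        self.chg_idx, self.chg_delta = [], []
        for r in model.reactions:
            delta = {}
            for sid, s in r.reactants:
                delta[sid] = delta.get(sid, 0) - s
            for sid, s in r.products:
                delta[sid] = delta.get(sid, 0) + s
            items = [(self.s_index[sid], d) for sid, d in delta.items() if d != 0]
            self.chg_idx.append(np.array([i for i, _ in items], dtype=np.intp))
            self.chg_delta.append(np.array([d for _, d in items], dtype=np.int64))

        self.events = model.sorted_events()
        self.event_p_idx = [self.p_index[e.parameter_id] for e in self.events]

        # observables resolvable in this model
        self.obs_columns = {}
        pool = [self.s_index[s.id] for s in model.species if TOTAL_P53_TAG in s.tags]
        if pool:
            self.obs_columns["total_p53"] = np.array(pool, dtype=np.intp)
        for name, sid in OBSERVABLES.items():
            if sid is not None and sid in self.s_index:
                self.obs_columns[name] = np.array([self.s_index[sid]], dtype=np.intp)
        self.plaque_i = self.s_index.get("AbetaP")
        self.tangle_i = self.s_index.get("TauTangle")

    # -- propensities ----------------------------------------------------
    def propensities(self, counts_ext: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Vector of reaction propensities; ``counts_ext`` carries a trailing
        dummy entry fixed at 1."""
        a = params[self.k_idx].astype(float, copy=True)
        for k in range(self.max_slots):
            c = counts_ext[self.slot_idx[k]]
            st = self.slot_sto[k]
            f = np.where(st == 0, 1.0,
                         np.where(st == 1, c, 0.5 * c * (c - 1)))
            if self.general_slots:
                hi = st > 2
                if hi.any():
                    f[hi] = [comb(int(n), int(s)) for n, s in zip(c[hi], st[hi])]
            a *= f
        np.maximum(a, 0.0, out=a)
        return a

    def initial_state(self) -> SimState:
        return SimState(
            time=0.0,
            counts=dict(zip(self.species_ids, self.init_counts.tolist())),
            param_values=dict(zip(self.param_ids, self.init_params.tolist())),
            pending_events=list(self.events),
        )


def _apply_event(ev, params, p_idx):
    if ev.action == "set_value":
        params[p_idx] = ev.operand
    else:  # multiply
        params[p_idx] *= ev.operand


def advance(compiled: CompiledModel | ModelDefinition, state: SimState,
            rng: np.random.Generator):
    """One step of the direct method; returns ``(new_state, fired)``.

    ``fired`` is the reaction id, the string ``"event:<param>"`` when a
    timed event interrupted the waiting time, or None when the clock ran
    to the horizon with nothing left to fire.
    """
    cm = compiled if isinstance(compiled, CompiledModel) else CompiledModel(compiled)
    counts_ext = np.empty(cm.n_species + 1, dtype=np.int64)
    counts_ext[:-1] = [state.counts[s] for s in cm.species_ids]
    counts_ext[-1] = 1
    params = np.array([state.param_values[p] for p in cm.param_ids], dtype=float)
    pending = list(state.pending_events)
    t = state.time

    a = cm.propensities(counts_ext, params)
    a0 = float(a.sum())
    next_ev_t = pending[0].fire_time if pending else inf

    if a0 <= 0.0:
        if next_ev_t <= cm.horizon:
            ev = pending.pop(0)
            _apply_event(ev, params, cm.p_index[ev.parameter_id])
            t, fired = ev.fire_time, f"event:{ev.parameter_id}"
        else:
            t, fired = cm.horizon, None
    else:
        tau = rng.exponential(1.0 / a0)
        if t + tau >= next_ev_t and next_ev_t <= cm.horizon:
            ev = pending.pop(0)
            _apply_event(ev, params, cm.p_index[ev.parameter_id])
            t, fired = ev.fire_time, f"event:{ev.parameter_id}"
        elif t + tau > cm.horizon:
            t, fired = cm.horizon, None
        else:
            t = t + tau
            j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
            j = min(j, cm.n_reactions - 1)
            counts_ext[cm.chg_idx[j]] += cm.chg_delta[j]
            fired = cm.reaction_ids[j]

    new_state = SimState(
        time=t,
        counts=dict(zip(cm.species_ids, counts_ext[:-1].tolist())),
        param_values=dict(zip(cm.param_ids, params.tolist())),
        pending_events=pending,
    )
    return new_state, fired


def simulate(model: ModelDefinition | CompiledModel, seed: int,
             grid_step: float = DEFAULT_GRID_STEP) -> TrajectoryRecord:
    """Run one trajectory from t=0 to the horizon.

    Identical ``(model, seed, grid_step)`` give a bit-identical record.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    rng = np.random.Generator(np.random.PCG64(seed))

    horizon = cm.horizon
    n_grid = int(np.floor(horizon / grid_step + 1e-9)) + 1
    grid = np.arange(n_grid) * grid_step

    counts_ext = np.empty(cm.n_species + 1, dtype=np.int64)
    counts_ext[:-1] = cm.init_counts
    counts_ext[-1] = 1
    params = cm.init_params.copy()
    rows = np.empty((n_grid, cm.n_species), dtype=np.int64)
    gi = 0  # next grid row to fill

    events = [e for e in cm.events if e.fire_time <= horizon]
    ev_ptr = 0
    t = 0.0
    first_plaque = None
    first_tangle = None
    pi, ti = cm.plaque_i, cm.tangle_i
    if pi is not None and counts_ext[pi] >= 1:
        first_plaque = 0.0
    if ti is not None and counts_ext[ti] >= 1:
        first_tangle = 0.0

    exp_draw = rng.exponential
    uni = rng.random
    while True:
        a = cm.propensities(counts_ext, params)
        a0 = float(a.sum())
        next_ev_t = events[ev_ptr].fire_time if ev_ptr < len(events) else inf

        if a0 <= 0.0:
            if ev_ptr >= len(events):
                break  # constant to the horizon
            t_new, is_event = next_ev_t, True
        else:
            t_new = t + exp_draw(1.0 / a0)
            if t_new >= next_ev_t:
                # waiting time interrupted: the event fires, tau is discarded
                t_new, is_event = next_ev_t, True
            elif t_new > horizon:
                break  # drawn reaction falls beyond the horizon: nothing fires
            else:
                is_event = False

        # grid points strictly before the change keep the current state
        while gi < n_grid and grid[gi] < t_new:
            rows[gi] = counts_ext[:-1]
            gi += 1

        if is_event:
            ev = events[ev_ptr]
            _apply_event(ev, params, cm.event_p_idx[ev_ptr])
            ev_ptr += 1
        else:
            j = int(np.searchsorted(np.cumsum(a), uni() * a0, side="right"))
            j = min(j, cm.n_reactions - 1)
            counts_ext[cm.chg_idx[j]] += cm.chg_delta[j]
            if first_plaque is None and pi is not None and counts_ext[pi] >= 1:
                first_plaque = t_new
            if first_tangle is None and ti is not None and counts_ext[ti] >= 1:
                first_tangle = t_new
        t = t_new

    rows[gi:] = counts_ext[:-1]  # trailing grid points sample the final state

    series = {sid: rows[:, i].copy() for i, sid in enumerate(cm.species_ids)}
    for name, cols in cm.obs_columns.items():
        series[name] = rows[:, cols].sum(axis=1)

    return TrajectoryRecord(
        model_name=cm.model.name,
        seed=int(seed),
        grid=grid,
        series=series,
        first_passage={"first_plaque": first_plaque, "first_tangle": first_tangle},
    )
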