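"""Reaction-network definition for the GSK3beta/p53/ROS pathology cycle.

The model is a discrete, well-mixed mass-action network of the molecular
species implicated in the joint appearance of amyloid-beta (Abeta) plaques
and tau tangles in a single simulated neuron:

* a p53/Mdm2 turnover module (synthesis, Mdm2 binding, ubiquitination,
  proteasomal degradation) that keeps p53 at a low basal level in
  unstressed cells;
* a DNA-damage-response module: reactive oxygen species (ROS) generate
  DNA lesions (``damDNA``) which drive p53 phosphorylation; phospho-p53
  escapes Mdm2-mediated degradation, so damage stabilises and activates
  p53;
* GSK3beta binding of activated p53 — the resulting ``GSK3b_p53`` complex
  is the activity-carrying species that drives both tau phosphorylation
  and amplified Abeta production;
* an Abeta chain (production, clearance of the soluble monomer,
  monomer -> oligomer -> plaque aggregation) whose soluble forms feed back
  on ROS production and p53 transcription;
* a tau chain (GSK3b_p53-driven phosphorylation, dephosphorylation,
  irreversible tangle formation from phospho-tau).

The closed loop Abeta -> ROS -> damDNA -> p53 -> GSK3b_p53 -> Abeta is a
positive feedback cycle with multiple points of entry; an unstressed cell
sits below its ignition threshold and enters it only through a stochastic
nucleation event (in this parameterisation, the chance encounter of two
soluble monomers forming a persistent oligomer).

Rate constants are expressed per day (first order) or per molecule per day
(second order).  The defaults are a calibration to the reported ensemble
phenotypes rather than measured constants; see ``docs/methods.md``.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "Species",
    "Reaction",
    "Parameter",
    "TimedEvent",
    "ModelDefinition",
    "InterventionSpec",
    "Diagnostic",
    "InvalidModelError",
    "OBSERVABLES",
    "TOTAL_P53_TAG",
    "CLEARANCE_PARAM",
    "OLIGOMER_CLEARANCE_PARAM",
    "ROS_PRODUCTION_PARAM",
    "ROS_PRODUCTION_PARAMS",
    "MONOMER_ROS_PARAM",
    "BINDING_PARAM",
    "build_default_network",
    "elevated_abeta_production",
    "elevated_tau_phosphorylation",
    "validate_network",
    "apply_intervention",
    "observable_total",
]

TOTAL_P53_TAG = "p53_pool_member"

#: Parameter ids with a designated experimental role.
CLEARANCE_PARAM = "k_abeta_clear"
OLIGOMER_CLEARANCE_PARAM = "k_oligo_clear"
ROS_PRODUCTION_PARAM = "k_abeta_ros"
MONOMER_ROS_PARAM = "k_abeta_ros_monomer"
#: parameters jointly zeroed by the ros_block intervention
ROS_PRODUCTION_PARAMS = (ROS_PRODUCTION_PARAM, MONOMER_ROS_PARAM)
BINDING_PARAM = "k_gsk_p53_bind"

VALID_KINETICS = ("mass_action", "modifier_mass_action")
VALID_EVENT_ACTIONS = ("set_value", "multiply")
VALID_TAGS = {"p53_pool_member", "abeta_soluble", "aggregate", "damage", "signalling"}


@dataclass(frozen=True)
class Species:
    """A molecular species tracked as an integer copy number."""

    id: str
    display_name: str = ""
    initial_count: int = 0
    tags: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel.

    ``reactants``/``products`` are tuples of ``(species_id, stoichiometry)``.
    ``modifiers`` scale the propensity linearly but are not consumed
    (``modifier_mass_action``).
    """

    id: str
    reactants: tuple = ()
    products: tuple = ()
    modifiers: tuple = ()
    rate_parameter: str = ""
    kinetics: str = "mass_action"

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple((str(s), int(n)) for s, n in self.reactants))
        object.__setattr__(self, "products", tuple((str(s), int(n)) for s, n in self.products))
        object.__setattr__(self, "modifiers", tuple(self.modifiers))


@dataclass(frozen=True)
class Parameter:
    """A non-negative rate constant (per day, or per molecule per day)."""

    id: str
    value: float
    description: str = ""


@dataclass(frozen=True)
class TimedEvent:
    """A scheduled, instantaneous change to one parameter value."""

    fire_time: float
    parameter_id: str
    action: str = "multiply"
    operand: float = 1.0


@dataclass
class ModelDefinition:
    species: list
    reactions: list
    parameters: list
    events: list = field(default_factory=list)
    horizon: float = 12.0
    name: str = "model"

    # -- lookups ---------------------------------------------------------
    def species_ids(self):
        return [s.id for s in self.species]

    def parameter_map(self):
        return {p.id: p.value for p in self.parameters}

    def species_map(self):
        return {s.id: s for s in self.species}

    def initial_counts(self):
        return {s.id: s.initial_count for s in self.species}

    # -- manipulation ----------------------------------------------------
    def copy(self) -> "ModelDefinition":
        return copy.deepcopy(self)

    def with_parameter(self, pid: str, value: float) -> "ModelDefinition":
        """Return a copy with one parameter set to ``value``."""
        m = self.copy()
        found = False
        for i, p in enumerate(m.parameters):
            if p.id == pid:
                m.parameters[i] = replace(p, value=float(value))
                found = True
        if not found:
            raise ValueError(f"unknown parameter id: {pid!r}")
        return m

    def sorted_events(self):
        return sorted(self.events, key=lambda e: e.fire_time)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "horizon": float(self.horizon),
            "species": [
                {
                    "id": s.id,
                    "display_name": s.display_name,
                    "initial_count": int(s.initial_count),
                    "tags": sorted(s.tags),
                }
                for s in self.species
            ],
            "parameters": [
                {"id": p.id, "value": float(p.value), "description": p.description}
                for p in self.parameters
            ],
            "reactions": [
                {
                    "id": r.id,
                    "reactants": [[s, n] for s, n in r.reactants],
                    "products": [[s, n] for s, n in r.products],
                    "modifiers": list(r.modifiers),
                    "rate_parameter": r.rate_parameter,
                    "kinetics": r.kinetics,
                }
                for r in self.reactions
            ],
            "events": [
                {
                    "fire_time": float(e.fire_time),
                    "parameter_id": e.parameter_id,
                    "action": e.action,
                    "operand": float(e.operand),
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDefinition":
        return cls(
            name=d.get("name", "model"),
            horizon=float(d.get("horizon", 12.0)),
            species=[
                Species(
                    id=s["id"],
                    display_name=s.get("display_name", ""),
                    initial_count=int(s.get("initial_count", 0)),
                    tags=frozenset(s.get("tags", ())),
                )
                for s in d.get("species", ())
            ],
            parameters=[
                Parameter(id=p["id"], value=float(p["value"]), description=p.get("description", ""))
                for p in d.get("parameters", ())
            ],
            reactions=[
                Reaction(
                    id=r["id"],
                    reactants=tuple((s, int(n)) for s, n in r.get("reactants", ())),
                    products=tuple((s, int(n)) for s, n in r.get("products", ())),
                    modifiers=tuple(r.get("modifiers", ())),
                    rate_parameter=r["rate_parameter"],
                    kinetics=r.get("kinetics", "mass_action"),
                )
                for r in d.get("reactions", ())
            ],
            events=[
                TimedEvent(
                    fire_time=float(e["fire_time"]),
                    parameter_id=e["parameter_id"],
                    action=e.get("action", "multiply"),
                    operand=float(e.get("operand", 1.0)),
                )
                for e in d.get("events", ())
            ],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelDefinition":
        return cls.from_dict(yaml.safe_load(text))

    def model_hash(self) -> str:
        """Stable content hash of the full network definition."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    message: str


class InvalidModelError(ValueError):
    """Raised when a ModelDefinition fails validation."""


@dataclass(frozen=True)
class InterventionSpec:
    """A named experimental manipulation of the default network.

    kind:
        ``clearance_boost``  multiply soluble-Abeta clearance by
        ``fold_change`` (default 100, i.e. two orders of magnitude) at
        ``start_day``;
        ``ros_block``        zero Abeta-mediated ROS production from t=0 and
        additionally boost clearance at day 8;
        ``binding_block``    zero GSK3beta/p53 binding from t=0 and
        additionally boost clearance at day 8;
        ``none``             identity.
    """

    kind: str = "none"
    start_day: float | None = None
    fold_change: float = 100.0
    include_oligomers: bool = False


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

#: observable name -> species id (None marks the tag-summed p53 pool)
OBSERVABLES = {
    "total_p53": None,
    "GSK3b_p53": "GSK3b_p53",
    "damDNA": "damDNA",
    "ROS": "ROS",
    "abeta_monomer": "AbetaM",
    "abeta_oligomer": "AbetaO",
    "abeta_plaque": "AbetaP",
    "tau_tangles": "TauTangle",
}

#: species that make up the total p53 pool in the default network
P53_POOL = ("p53", "p53_P", "Mdm2_p53", "p53_Ub", "GSK3b_p53")


def observable_total(state, observable: str) -> int:
    """Total copy number of a registered observable in a state-count map.

    ``total_p53`` sums the free, phosphorylated, Mdm2-bound, ubiquitinated
    and GSK3beta-bound forms; every other observable maps to one species.
    """
    if observable not in OBSERVABLES:
        raise KeyError(
            f"unknown observable {observable!r}; valid names: {sorted(OBSERVABLES)}"
        )
    target = OBSERVABLES[observable]
    if target is None:
        return int(sum(state.get(s, 0) for s in P53_POOL))
    return int(state.get(target, 0))


# ---------------------------------------------------------------------------
# default network
# ---------------------------------------------------------------------------

_DEFAULT_PARAMS = [
    # p53 / Mdm2 turnover
    ("k_syn_p53", 20.0, "basal p53 synthesis (molecules/day)"),
    ("k_mdm2_p53_bind", 0.10, "p53 + Mdm2 association (/molecule/day)"),
    ("k_mdm2_p53_unbind", 1.0, "Mdm2_p53 dissociation (/day)"),
    ("k_p53_ub", 10.0, "ubiquitination of Mdm2-bound p53 (/day)"),
    ("k_p53_deg", 10.0, "26S proteasomal degradation of p53_Ub (/day)"),
    ("k_syn_mdm2", 10.0, "Mdm2 synthesis (molecules/day)"),
    ("k_deg_mdm2", 1.0, "Mdm2 degradation (/day)"),
    # ROS / DNA damage response
    ("k_ros_basal", 1e-5, "basal ROS generation (molecules/day)"),
    (ROS_PRODUCTION_PARAM, 2.0, "Abeta-oligomer-mediated ROS generation (/oligomer/day)"),
    (MONOMER_ROS_PARAM, 0.003, "Abeta-monomer-mediated ROS generation (/monomer/day)"),
    ("k_ros_removal", 2.0, "antioxidant ROS removal (/day)"),
    ("k_damage", 2.0, "DNA lesion generation (/ROS/day)"),
    ("k_repair", 2.0, "DNA lesion repair (/day)"),
    ("k_p53_phos", 0.5, "damage-dependent p53 phosphorylation (/damDNA/p53/day)"),
    ("k_p53_dephos", 0.12, "p53_P dephosphorylation (/day)"),
    # GSK3beta binding of activated p53
    (BINDING_PARAM, 0.03, "phospho-p53 + GSK3beta association (/molecule/day)"),
    ("k_gsk_p53_unbind", 2.0, "GSK3b_p53 dissociation (/day)"),
    # Abeta production, clearance, aggregation
    ("k_abeta_prod", 1.2, "basal Abeta monomer production (molecules/day)"),
    ("k_abeta_prod_gsk", 20.0, "GSK3b_p53-driven Abeta production (/complex/day)"),
    ("k_abeta_prod_p53", 0.1, "phospho-p53-driven Abeta production (/p53_P/day)"),
    (CLEARANCE_PARAM, 2.0, "soluble Abeta monomer clearance (/day); intervention target"),
    (OLIGOMER_CLEARANCE_PARAM, 0.3, "Abeta oligomer clearance (/day)"),
    ("k_oligomer", 5.2, "monomer pair -> oligomer nucleation (/pair/day)"),
    ("k_plaque", 0.0015, "oligomer pair -> plaque deposition (/pair/day)"),
    ("k_abeta_p53syn", 1.0, "Abeta-driven p53 transcription (/soluble Abeta/day)"),
    ("k_p53syn_gsk", 15.0, "GSK3b_p53-driven p53 stabilisation/synthesis (/complex/day)"),
    # tau phosphorylation and aggregation
    ("k_tau_phos", 0.04, "GSK3b_p53-driven tau phosphorylation (/complex/tau/day)"),
    ("k_tau_dephos", 1.0, "phospho-tau dephosphorylation (/day)"),
    ("k_tangle", 6e-3, "phospho-tau triple -> tangle nucleation (/triple/day)"),
]

_DEFAULT_SPECIES = [
    ("p53", "free p53", 5, {TOTAL_P53_TAG}),
    ("Mdm2", "Mdm2", 10, set()),
    ("Mdm2_p53", "p53/Mdm2 complex", 0, {TOTAL_P53_TAG}),
    ("p53_Ub", "ubiquitinated p53", 0, {TOTAL_P53_TAG}),
    ("p53_P", "phosphorylated p53", 0, {TOTAL_P53_TAG, "signalling"}),
    ("GSK3b", "GSK3beta", 20, {"signalling"}),
    ("GSK3b_p53", "GSK3beta/p53 complex", 0, {TOTAL_P53_TAG, "signalling"}),
    ("ROS", "reactive oxygen species", 0, {"damage"}),
    ("damDNA", "unrepaired DNA lesions", 0, {"damage"}),
    ("AbetaM", "Abeta monomer", 0, {"abeta_soluble"}),
    ("AbetaO", "Abeta oligomer", 0, {"abeta_soluble"}),
    ("AbetaP", "Abeta plaque", 0, {"aggregate"}),
    ("Tau", "tau", 300, set()),
    ("TauP", "phospho-tau", 0, set()),
    ("TauTangle", "tau tangle", 0, {"aggregate"}),
]

_DEFAULT_REACTIONS = [
    # (id, reactants, products, modifiers, rate parameter)
    # -- p53 / Mdm2 turnover
    ("p53_synthesis", (), (("p53", 1),), (), "k_syn_p53"),
    ("mdm2_p53_binding", (("p53", 1), ("Mdm2", 1)), (("Mdm2_p53", 1),), (), "k_mdm2_p53_bind"),
    ("mdm2_p53_release", (("Mdm2_p53", 1),), (("p53", 1), ("Mdm2", 1)), (), "k_mdm2_p53_unbind"),
    ("p53_ubiquitination", (("Mdm2_p53", 1),), (("p53_Ub", 1), ("Mdm2", 1)), (), "k_p53_ub"),
    ("p53_degradation", (("p53_Ub", 1),), (), (), "k_p53_deg"),
    ("mdm2_synthesis", (), (("Mdm2", 1),), (), "k_syn_mdm2"),
    ("mdm2_degradation", (("Mdm2", 1),), (), (), "k_deg_mdm2"),
    # -- ROS and the DNA damage response
    ("ros_basal", (), (("ROS", 1),), (), "k_ros_basal"),
    ("ros_from_abeta_monomer", (), (("ROS", 1),), ("AbetaM",), MONOMER_ROS_PARAM),
    ("ros_from_abeta_oligomer", (), (("ROS", 1),), ("AbetaO",), ROS_PRODUCTION_PARAM),
    ("ros_removal", (("ROS", 1),), (), (), "k_ros_removal"),
    ("dna_damage", (), (("damDNA", 1),), ("ROS",), "k_damage"),
    ("dna_repair", (("damDNA", 1),), (), (), "k_repair"),
    ("p53_phosphorylation", (("p53", 1),), (("p53_P", 1),), ("damDNA",), "k_p53_phos"),
    ("p53_dephosphorylation", (("p53_P", 1),), (("p53", 1),), (), "k_p53_dephos"),
    # -- GSK3beta binding of activated p53
    ("gsk3_p53_binding", (("p53_P", 1), ("GSK3b", 1)), (("GSK3b_p53", 1),), (), BINDING_PARAM),
    ("gsk3_p53_release", (("GSK3b_p53", 1),), (("p53_P", 1), ("GSK3b", 1)), (), "k_gsk_p53_unbind"),
    # -- Abeta production, clearance and aggregation
    ("abeta_production", (), (("AbetaM", 1),), (), "k_abeta_prod"),
    ("abeta_production_gsk", (), (("AbetaM", 1),), ("GSK3b_p53",), "k_abeta_prod_gsk"),
    ("abeta_production_p53", (), (("AbetaM", 1),), ("p53_P",), "k_abeta_prod_p53"),
    ("abeta_clearance", (("AbetaM", 1),), (), (), CLEARANCE_PARAM),
    ("oligomer_clearance", (("AbetaO", 1),), (), (), OLIGOMER_CLEARANCE_PARAM),
    ("oligomerisation", (("AbetaM", 2),), (("AbetaO", 1),), (), "k_oligomer"),
    ("plaque_formation", (("AbetaO", 2),), (("AbetaP", 1),), (), "k_plaque"),
    ("p53_synthesis_abeta_monomer", (), (("p53", 1),), ("AbetaM",), "k_abeta_p53syn"),
    ("p53_synthesis_abeta_oligomer", (), (("p53", 1),), ("AbetaO",), "k_abeta_p53syn"),
    ("p53_synthesis_gsk", (), (("p53", 1),), ("GSK3b_p53",), "k_p53syn_gsk"),
    # -- tau phosphorylation and aggregation
    ("tau_phosphorylation", (("Tau", 1),), (("TauP", 1),), ("GSK3b_p53",), "k_tau_phos"),
    ("tau_dephosphorylation", (("TauP", 1),), (("Tau", 1),), (), "k_tau_dephos"),
    ("tangle_formation", (("TauP", 3),), (("TauTangle", 1),), (), "k_tangle"),
]


def build_default_network(overrides: dict | None = None) -> ModelDefinition:
    """Build the default AD network with a 12-day horizon.

    ``overrides`` maps parameter ids to replacement values; an unknown id
    raises ``ValueError`` naming it.
    """
    params = {pid: val for pid, val, _ in _DEFAULT_PARAMS}
    if overrides:
        unknown = sorted(set(overrides) - set(params))
        if unknown:
            raise ValueError(f"unknown parameter id(s) in overrides: {unknown}")
        params.update({k: float(v) for k, v in overrides.items()})

    model = ModelDefinition(
        name="ad_gsk3_p53_cycle",
        horizon=12.0,
        species=[
            Species(id=sid, display_name=dn, initial_count=n0, tags=frozenset(tags))
            for sid, dn, n0, tags in _DEFAULT_SPECIES
        ],
        parameters=[
            Parameter(id=pid, value=params[pid], description=desc)
            for pid, _, desc in _DEFAULT_PARAMS
        ],
        reactions=[
            Reaction(
                id=rid,
                reactants=reac,
                products=prod,
                modifiers=mods,
                rate_parameter=rp,
                kinetics="modifier_mass_action" if mods else "mass_action",
            )
            for rid, reac, prod, mods, rp in _DEFAULT_REACTIONS
        ],
        events=[],
    )
    diags = [d for d in validate_network(model) if d.severity == "error"]
    if diags:  # pragma: no cover - defensive; default must validate
        raise InvalidModelError("; ".join(d.message for d in diags))
    return model


def elevated_abeta_production(fold: float = 15.0) -> dict:
    """Overrides raising basal Abeta production to its elevated calibration
    value (aggregates then nucleate within the first days of a run)."""
    base = dict((pid, val) for pid, val, _ in _DEFAULT_PARAMS)
    return {"k_abeta_prod": base["k_abeta_prod"] * fold}


def elevated_tau_phosphorylation(fold: float = 10.0) -> dict:
    """Overrides raising the tau-phosphorylation rate to its elevated
    calibration value."""
    base = dict((pid, val) for pid, val, _ in _DEFAULT_PARAMS)
    return {"k_tau_phos": base["k_tau_phos"] * fold}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(model: ModelDefinition) -> list:
    """Check all structural invariants; returns a list of Diagnostics.

    An empty list means the model is valid. Cross-reference failures,
    negative counts/rates and malformed stoichiometries are errors;
    suspicious but simulatable constructs are warnings.
    """
    diags = []
    err = lambda m: diags.append(Diagnostic("error", m))
    warn = lambda m: diags.append(Diagnostic("warning", m))

    sids = [s.id for s in model.species]
    if len(set(sids)) != len(sids):
        err("duplicate species ids")
    pids = [p.id for p in model.parameters]
    if len(set(pids)) != len(pids):
        err("duplicate parameter ids")
    rids = [r.id for r in model.reactions]
    if len(set(rids)) != len(rids):
        err("duplicate reaction ids")

    for s in model.species:
        if not isinstance(s.initial_count, int) or s.initial_count < 0:
            err(f"species {s.id!r}: initial_count must be a non-negative integer")
        bad_tags = set(s.tags) - VALID_TAGS
        if bad_tags:
            warn(f"species {s.id!r}: unknown tags {sorted(bad_tags)}")

    for p in model.parameters:
        if not math.isfinite(p.value) or p.value < 0:
            err(f"parameter {p.id!r}: value must be finite and >= 0 (zero encodes a blockade)")

    sset, pset = set(sids), set(pids)
    for r in model.reactions:
        if r.kinetics not in VALID_KINETICS:
            err(f"reaction {r.id!r}: unknown kinetics {r.kinetics!r}")
        if r.rate_parameter not in pset:
            err(f"reaction {r.id!r}: rate_parameter {r.rate_parameter!r} not defined")
        for sid, n in list(r.reactants) + list(r.products):
            if sid not in sset:
                err(f"reaction {r.id!r}: references missing species {sid!r}")
            if not isinstance(n, int) or n < 1:
                err(f"reaction {r.id!r}: stoichiometry for {sid!r} must be a positive integer")
        for sid in r.modifiers:
            if sid not in sset:
                err(f"reaction {r.id!r}: modifier references missing species {sid!r}")
        if r.modifiers and r.kinetics != "modifier_mass_action":
            warn(f"reaction {r.id!r}: has modifiers but kinetics is {r.kinetics!r}")
        seen = [sid for sid, _ in r.reactants]
        if len(seen) != len(set(seen)):
            err(f"reaction {r.id!r}: repeat a reactant by raising its stoichiometry, "
                "not by listing it twice (combinatoric n(n-1)/2 convention)")

    for e in model.events:
        if e.fire_time < 0:
            err(f"event on {e.parameter_id!r}: fire_time must be >= 0")
        if e.parameter_id not in pset:
            err(f"event references missing parameter {e.parameter_id!r}")
        if e.action not in VALID_EVENT_ACTIONS:
            err(f"event on {e.parameter_id!r}: unknown action {e.action!r}")
        if not math.isfinite(e.operand):
            err(f"event on {e.parameter_id!r}: operand must be finite")
        if e.fire_time > model.horizon:
            warn(f"event on {e.parameter_id!r} at t={e.fire_time} is beyond the horizon "
                 f"({model.horizon}) and will never fire")

    if not (math.isfinite(model.horizon) and model.horizon > 0):
        err("horizon must be a positive, finite number of days")

    return diags


def assert_valid(model: ModelDefinition) -> None:
    errors = [d for d in validate_network(model) if d.severity == "error"]
    if errors:
        raise InvalidModelError("invalid model: " + "; ".join(d.message for d in errors))


# ---------------------------------------------------------------------------
# interventions
# ---------------------------------------------------------------------------

def apply_intervention(model: ModelDefinition, spec: InterventionSpec) -> ModelDefinition:
    """Return a new model with the intervention applied; the input is untouched.

    A ``clearance_boost`` at day 0 edits the clearance constant directly;
    later start days append a multiply-by-``fold_change`` timed event.  The
    two mechanistic blockades zero their target parameter from t=0 and layer
    a day-8 clearance boost on top, matching the published protocol.
    """
    assert_valid(model)
    out = model.copy()

    def boost_clearance(day: float, fold: float, include_oligomers: bool):
        if not (0 <= day <= out.horizon):
            raise ValueError(
                f"clearance_boost start_day {day} outside [0, {out.horizon}]")
        targets = [CLEARANCE_PARAM]
        if include_oligomers:
            targets.append(OLIGOMER_CLEARANCE_PARAM)
        for pid in targets:
            if day == 0:
                for i, p in enumerate(out.parameters):
                    if p.id == pid:
                        out.parameters[i] = replace(p, value=p.value * fold)
            else:
                out.events.append(TimedEvent(fire_time=float(day), parameter_id=pid,
                                             action="multiply", operand=float(fold)))

    def zero_param(pid: str):
        for i, p in enumerate(out.parameters):
            if p.id == pid:
                out.parameters[i] = replace(p, value=0.0)

    if spec.kind == "none":
        pass
    elif spec.kind == "clearance_boost":
        day = 0.0 if spec.start_day is None else float(spec.start_day)
        boost_clearance(day, spec.fold_change, spec.include_oligomers)
    elif spec.kind == "ros_block":
        for pid in ROS_PRODUCTION_PARAMS:
            zero_param(pid)
        boost_clearance(8.0, spec.fold_change, spec.include_oligomers)
    elif spec.kind == "binding_block":
        zero_param(BINDING_PARAM)
        boost_clearance(8.0, spec.fold_change, spec.include_oligomers)
    else:
        raise ValueError(f"unknown intervention kind: {spec.kind!r}")

    out.events = out.sorted_events()
    return out
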