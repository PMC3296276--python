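"""Optional SBML Level-3 subset reader/writer.

The network format used here is deliberately narrow: discrete species with
integer initial amounts, global parameters, mass-action kinetic laws of the
form ``k * reactant-and-modifier product``, and time-triggered events that
assign (or scale) one parameter.  That is exactly the vocabulary of this
package's models, and it round-trips losslessly.  Anything outside that
subset — rules, function definitions, compartmentally scaled units,
non-mass-action kinetic laws — is rejected with a named diagnostic rather
than silently dropped.

This module is a convenience for interoperating with SBML tooling; nothing
else in the package depends on it.
"""

from __future__ import annotations

from lxml import etree

from .model import (
    ModelDefinition,
    Parameter,
    Reaction,
    Species,
    TimedEvent,
    assert_valid,
)

__all__ = ["SbmlError", "write_sbml", "read_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATH_NS = "http://www.w3.org/1998/Math/MathML"
_TAG_HINT = "adcycle:tags"


class SbmlError(ValueError):
    """An SBML document uses constructs outside the supported subset."""


def _e(tag, ns=SBML_NS, **attrs):
    el = etree.Element(f"{{{ns}}}{tag}")
    for k, v in attrs.items():
        el.set(k, str(v))
    return el


def _math_product(factors):
    """<math><apply><times/><ci>f1</ci>...</apply></math> (or a lone <ci>)."""
    math = _e("math", ns=MATH_NS)
    if len(factors) == 1:
        ci = _e("ci", ns=MATH_NS)
        ci.text = f" {factors[0]} "
        math.append(ci)
        return math
    apply_ = _e("apply", ns=MATH_NS)
    apply_.append(_e("times", ns=MATH_NS))
    for f in factors:
        ci = _e("ci", ns=MATH_NS)
        ci.text = f" {f} "
        apply_.append(ci)
    math.append(apply_)
    return math


def write_sbml(model: ModelDefinition) -> str:
    """Serialise a model to an SBML Level 3 Version 2 document string."""
    assert_valid(model)
    root = _e("sbml", level="3", version="2")
    m = _e("model", id=model.name or "model", name=model.name or "model")
    root.append(m)

    lc = _e("listOfCompartments")
    lc.append(_e("compartment", id="cell", constant="true", size="1"))
    m.append(lc)

    ls = _e("listOfSpecies")
    for s in model.species:
        el = _e(
            "species",
            id=s.id,
            name=s.display_name or s.id,
            compartment="cell",
            initialAmount=s.initial_count,
            hasOnlySubstanceUnits="true",
            boundaryCondition="false",
            constant="false",
        )
        if s.tags:
            notes = _e("notes")
            body = etree.SubElement(notes, "{http://www.w3.org/1999/xhtml}p")
            body.text = f"{_TAG_HINT}={','.join(sorted(s.tags))}"
            el.append(notes)
        ls.append(el)
    m.append(ls)

    lp = _e("listOfParameters")
    for p in model.parameters:
        lp.append(_e("parameter", id=p.id, name=p.description or p.id,
                     value=repr(float(p.value)), constant="false"))
    m.append(lp)

    lr = _e("listOfReactions")
    for r in model.reactions:
        el = _e("reaction", id=r.id, reversible="false")
        if r.reactants:
            lref = _e("listOfReactants")
            for sid, n in r.reactants:
                lref.append(_e("speciesReference", species=sid,
                               stoichiometry=n, constant="true"))
            el.append(lref)
        if r.products:
            lprod = _e("listOfProducts")
            for sid, n in r.products:
                lprod.append(_e("speciesReference", species=sid,
                                stoichiometry=n, constant="true"))
            el.append(lprod)
        if r.modifiers:
            lmod = _e("listOfModifiers")
            for sid in r.modifiers:
                lmod.append(_e("modifierSpeciesReference", species=sid))
            el.append(lmod)
        kl = _e("kineticLaw")
        factors = [r.rate_parameter]
        for sid, n in r.reactants:
            factors.extend([sid] * n)
        factors.extend(r.modifiers)
        kl.append(_math_product(factors))
        el.append(kl)
        lr.append(el)
    m.append(lr)

    if model.events:
        le = _e("listOfEvents")
        for i, ev in enumerate(model.sorted_events()):
            el = _e("event", id=f"event_{i}", useValuesFromTriggerTime="true")
            trig = _e("trigger", initialValue="false", persistent="true")
            math = _e("math", ns=MATH_NS)
            apply_ = _e("apply", ns=MATH_NS)
            apply_.append(_e("geq", ns=MATH_NS))
            ci = _e("ci", ns=MATH_NS)
            ci.text = " time "
            cn = _e("cn", ns=MATH_NS)
            cn.text = f" {repr(float(ev.fire_time))} "
            apply_.extend([ci, cn])
            math.append(apply_)
            trig.append(math)
            el.append(trig)
            lea = _e("listOfEventAssignments")
            ea = _e("eventAssignment", variable=ev.parameter_id)
            if ev.action == "set_value":
                math = _e("math", ns=MATH_NS)
                cn = _e("cn", ns=MATH_NS)
                cn.text = f" {repr(float(ev.operand))} "
                math.append(cn)
            else:  # multiply: parameter := parameter * operand
                math = _e("math", ns=MATH_NS)
                apply_ = _e("apply", ns=MATH_NS)
                apply_.append(_e("times", ns=MATH_NS))
                ci = _e("ci", ns=MATH_NS)
                ci.text = f" {ev.parameter_id} "
                cn = _e("cn", ns=MATH_NS)
                cn.text = f" {repr(float(ev.operand))} "
                apply_.extend([ci, cn])
                math.append(apply_)
            ea.append(math)
            lea.append(ea)
            el.append(lea)
            le.append(el)
        m.append(le)

    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _q(tag, ns=SBML_NS):
    return f"{{{ns}}}{tag}"


def _math_factors(math_el, where: str):
    """Flatten a supported kinetic-law <math> into its <ci> factor list."""
    children = [c for c in math_el if not isinstance(c, etree._Comment)]
    if len(children) != 1:
        raise SbmlError(f"{where}: unsupported math structure")
    node = children[0]
    if node.tag == _q("ci", MATH_NS):
        return [node.text.strip()]
    if node.tag != _q("apply", MATH_NS):
        raise SbmlError(f"{where}: unsupported math node {node.tag!r}")
    ops = list(node)
    if not ops or ops[0].tag != _q("times", MATH_NS):
        raise SbmlError(f"{where}: only pure products are supported")
    factors = []
    for c in ops[1:]:
        if c.tag != _q("ci", MATH_NS):
            raise SbmlError(f"{where}: non-identifier factor in kinetic law")
        factors.append(c.text.strip())
    return factors


def read_sbml(text: str | bytes) -> ModelDefinition:
    """Parse an SBML document restricted to the supported subset.

    Unsupported constructs raise :class:`SbmlError` naming the offending
    element; they are never silently ignored.
    """
    if isinstance(text, str):
        text = text.encode()
    root = etree.fromstring(text)
    model_el = root.find(_q("model"))
    if model_el is None:
        raise SbmlError("document has no <model> element")

    for banned, label in [
        ("listOfRules", "rules"),
        ("listOfFunctionDefinitions", "function definitions"),
        ("listOfConstraints", "constraints"),
        ("listOfInitialAssignments", "initial assignments"),
    ]:
        if model_el.find(_q(banned)) is not None:
            raise SbmlError(f"unsupported SBML construct: {label}")

    species = []
    for el in model_el.iterfind(f"{_q('listOfSpecies')}/{_q('species')}"):
        amount = el.get("initialAmount")
        if amount is None:
            raise SbmlError(f"species {el.get('id')!r}: initialAmount required "
                            "(concentrations are not supported)")
        amt = float(amount)
        if amt != int(amt):
            raise SbmlError(f"species {el.get('id')!r}: non-integer initialAmount")
        tags = ()
        for p in el.iter():
            if p.text and _TAG_HINT in (p.text or ""):
                tags = tuple(p.text.split("=", 1)[1].split(","))
        species.append(Species(id=el.get("id"), display_name=el.get("name", ""),
                               initial_count=int(amt), tags=frozenset(tags)))

    parameters = [
        Parameter(id=el.get("id"), value=float(el.get("value", "0")),
                  description=el.get("name", ""))
        for el in model_el.iterfind(f"{_q('listOfParameters')}/{_q('parameter')}")
    ]
    pids = {p.id for p in parameters}

    reactions = []
    for el in model_el.iterfind(f"{_q('listOfReactions')}/{_q('reaction')}"):
        rid = el.get("id")
        if el.get("reversible") == "true":
            raise SbmlError(f"reaction {rid!r}: reversible reactions are not "
                            "supported (split into two irreversible steps)")

        def refs(kind):
            return [(sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
                    for sr in el.iterfind(f"{_q(kind)}/{_q('speciesReference')}")]

        reactants = refs("listOfReactants")
        products = refs("listOfProducts")
        modifiers = tuple(
            sr.get("species") for sr in
            el.iterfind(f"{_q('listOfModifiers')}/{_q('modifierSpeciesReference')}"))

        kl = el.find(_q("kineticLaw"))
        if kl is None:
            raise SbmlError(f"reaction {rid!r}: kineticLaw required")
        math = kl.find(_q("math", MATH_NS))
        if math is None:
            raise SbmlError(f"reaction {rid!r}: kineticLaw has no math")
        factors = _math_factors(math, f"reaction {rid!r}")
        k_factors = [f for f in factors if f in pids]
        if len(k_factors) != 1:
            raise SbmlError(f"reaction {rid!r}: kinetic law must reference "
                            "exactly one rate parameter")
        expected = sorted(sum(([s] * n for s, n in reactants), []) + list(modifiers))
        got = sorted(f for f in factors if f not in pids)
        if got != expected:
            raise SbmlError(f"reaction {rid!r}: kinetic law is not mass action "
                            f"over its reactants/modifiers (factors {got})")
        reactions.append(Reaction(
            id=rid, reactants=tuple(reactants), products=tuple(products),
            modifiers=modifiers, rate_parameter=k_factors[0],
            kinetics="modifier_mass_action" if modifiers else "mass_action"))

    events = []
    for el in model_el.iterfind(f"{_q('listOfEvents')}/{_q('event')}"):
        eid = el.get("id")
        trig = el.find(_q("trigger"))
        math = None if trig is None else trig.find(_q("math", MATH_NS))
        if math is None:
            raise SbmlError(f"event {eid!r}: time trigger required")
        apply_ = math.find(_q("apply", MATH_NS))
        kids = [] if apply_ is None else list(apply_)
        if (len(kids) != 3 or kids[0].tag != _q("geq", MATH_NS)
                or kids[1].tag != _q("ci", MATH_NS)
                or kids[1].text.strip() not in ("time", "t")
                or kids[2].tag != _q("cn", MATH_NS)):
            raise SbmlError(f"event {eid!r}: only 'time >= T' triggers are supported")
        fire_time = float(kids[2].text)
        eas = el.iterfind(f"{_q('listOfEventAssignments')}/{_q('eventAssignment')}")
        eas = list(eas)
        if len(eas) != 1:
            raise SbmlError(f"event {eid!r}: exactly one event assignment supported")
        ea = eas[0]
        var = ea.get("variable")
        if var not in pids:
            raise SbmlError(f"event {eid!r}: assignment target {var!r} is not a "
                            "parameter")
        math = ea.find(_q("math", MATH_NS))
        node = [c for c in math if not isinstance(c, etree._Comment)][0]
        if node.tag == _q("cn", MATH_NS):
            events.append(TimedEvent(fire_time, var, "set_value", float(node.text)))
        elif node.tag == _q("apply", MATH_NS):
            kids = list(node)
            if (len(kids) == 3 and kids[0].tag == _q("times", MATH_NS)
                    and kids[1].tag == _q("ci", MATH_NS)
                    and kids[1].text.strip() == var
                    and kids[2].tag == _q("cn", MATH_NS)):
                events.append(TimedEvent(fire_time, var, "multiply", float(kids[2].text)))
            else:
                raise SbmlError(f"event {eid!r}: only 'param := value' or "
                                "'param := param * value' assignments supported")
        else:
            raise SbmlError(f"event {eid!r}: unsupported assignment math")

    model = ModelDefinition(
        name=model_el.get("id", "model"),
        species=species, parameters=parameters, reactions=reactions,
        events=events,
    )
    assert_valid(model)
    return model
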