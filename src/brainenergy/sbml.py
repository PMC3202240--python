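"""SBML Level 3 export/import of the compartmental models.

The writer emits a self-contained SBML L3v2 core document: compartments
(relative volumes as sizes), species (initial concentrations, clamped
species as boundary conditions), and reactions whose kinetic laws are
written as MathML in substance-extent units (concentration rate times
source-compartment volume, so a standard SBML simulator reproduces the
package's volume bookkeeping).  A small annotation namespace
(``https://brainenergy.dev/sbml``) carries the declarative law
descriptors and the gene-regulation block, which makes the round trip
exact: re-importing a document and re-assembling the ODE system yields
identical derivatives, and a second export is byte-identical.

Only the constructs this package emits are supported on import; this is
a deliberate subset of SBML, not a general-purpose reader.
"""

from __future__ import annotations

import json

from lxml import etree

from .kinetics import LAW_PARAMS
from .model_core import (
    Compartment,
    CompartmentalModel,
    KineticLaw,
    Reaction,
    Species,
    validate_model,
)

__all__ = ["export_sbml", "import_sbml", "validate_sbml", "SBMLError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
BE_NS = "https://brainenergy.dev/sbml"

_NSMAP = {None: SBML_NS}


class SBMLError(ValueError):
    pass


def _num(x: float) -> str:
    # repr round-trips doubles exactly -> byte-identical re-export
    return repr(float(x))


def _sid(species: str, comp: str) -> str:
    return f"{species}_{comp}"


# ------------------------------------------------------------------ MathML
def _ci(parent, name):
    e = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
    e.text = f" {name} "
    return e


def _cn(parent, value):
    e = etree.SubElement(parent, f"{{{MATHML_NS}}}cn")
    e.text = f" {_num(value)} "
    return e


def _apply(parent, op):
    a = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(a, f"{{{MATHML_NS}}}{op}")
    return a


def _law_math(r: Reaction) -> etree._Element:
    """<math> for rate J (mM/min) x V_src (extent units, mmol/min)."""
    math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
    mult = _apply(math, "times")
    _ci(mult, r.source_compartment)
    p = r.law.params
    form = r.law.form
    rs = [_sid(sp, comp) for sp, comp in r.rate_species]
    if form == "passive_diffusion":
        # gamma * (x - sigma*y)
        t = _apply(mult, "times")
        _cn(t, p["gamma"])
        minus = _apply(t, "minus")
        _ci(minus, rs[0])
        inner = _apply(minus, "times")
        _cn(inner, p["sigma"])
        _ci(inner, rs[1])
    elif form in ("facilitated_transport", "michaelis_menten"):
        cap = p["v"] if form == "facilitated_transport" else p["v_max"]
        km = p["km"]
        frac = _apply(mult, "divide")
        num = _apply(frac, "times")
        _cn(num, cap)
        _ci(num, rs[0])
        den = _apply(frac, "plus")
        _cn(den, km)
        _ci(den, rs[0])
    elif form == "bimolecular_mm":
        frac = _apply(mult, "divide")
        num = _apply(frac, "times")
        _cn(num, p["j_max"])
        _ci(num, rs[0])
        _ci(num, rs[1])
        den = _apply(frac, "plus")
        _cn(den, p["k"])
        prod = _apply(den, "times")
        _ci(prod, rs[0])
        _ci(prod, rs[1])
    elif form == "mass_action":
        t = _apply(mult, "times")
        _cn(t, p["k"])
        for name in rs:
            _ci(t, name)
    elif form == "uncompetitive_inhibition":
        frac = _apply(mult, "divide")
        num = _apply(frac, "times")
        _cn(num, p["v_max"])
        _ci(num, rs[0])
        den = _apply(frac, "plus")
        _cn(den, p["km"])
        t = _apply(den, "times")
        _ci(t, rs[0])
        plus = _apply(t, "plus")
        _cn(plus, 1.0)
        ratio = _apply(plus, "divide")
        _ci(ratio, _sid(*r.inhibitor))
        _cn(ratio, p["ki"])
    else:  # pragma: no cover
        raise SBMLError(f"unsupported law form {form}")
    return math


# ------------------------------------------------------------------ writer
def export_sbml(model: CompartmentalModel) -> str:
    """Serialise a validated model as SBML Level 3 text."""
    report = validate_model(model)
    if not report.ok:
        raise SBMLError("cannot export an invalid model:\n" + str(report))

    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=_NSMAP)
    root.set("level", "3")
    root.set("version", "2")
    m = etree.SubElement(root, f"{{{SBML_NS}}}model")
    m.set("id", f"brainenergy_{model.variant}")
    m.set("substanceUnits", "mmole")
    m.set("timeUnits", "minute")
    m.set("volumeUnits", "litre")
    m.set("extentUnits", "mmole")

    ann = etree.SubElement(m, f"{{{SBML_NS}}}annotation")
    be = etree.SubElement(ann, f"{{{BE_NS}}}model", nsmap={"be": BE_NS})
    be.set("variant", model.variant)
    be.set("genes", ",".join(model.genes))
    be.set("options", json.dumps(model.options, sort_keys=True))
    reg = etree.SubElement(be, f"{{{BE_NS}}}regulation")
    reg.text = json.dumps(model.regulation, sort_keys=True)

    # units
    luds = etree.SubElement(m, f"{{{SBML_NS}}}listOfUnitDefinitions")
    for uid, (kind, exp, scale, mult) in (
        ("minute", ("second", 1, 0, 60.0)),
        ("mmole", ("mole", 1, -3, 1.0)),
        ("mM", ("mole", 1, -3, 1.0)),  # per-litre handled by spatial size
    ):
        ud = etree.SubElement(luds, f"{{{SBML_NS}}}unitDefinition")
        ud.set("id", uid)
        lus = etree.SubElement(ud, f"{{{SBML_NS}}}listOfUnits")
        u = etree.SubElement(lus, f"{{{SBML_NS}}}unit")
        u.set("kind", kind)
        u.set("exponent", _num(exp))
        u.set("scale", str(scale))
        u.set("multiplier", _num(mult))

    lc = etree.SubElement(m, f"{{{SBML_NS}}}listOfCompartments")
    for cid in sorted(model.compartments):
        c = model.compartments[cid]
        e = etree.SubElement(lc, f"{{{SBML_NS}}}compartment")
        e.set("id", cid)
        e.set("name", c.description)
        e.set("size", _num(c.volume))
        e.set("spatialDimensions", "3")
        e.set("constant", "true")

    ls = etree.SubElement(m, f"{{{SBML_NS}}}listOfSpecies")
    for key in sorted(model.species, key=lambda k: (k[1], k[0])):
        s = model.species[key]
        e = etree.SubElement(ls, f"{{{SBML_NS}}}species")
        e.set("id", _sid(s.id, s.compartment))
        e.set("name", s.id)
        e.set("compartment", s.compartment)
        e.set("initialConcentration", _num(s.initial_concentration))
        e.set("hasOnlySubstanceUnits", "false")
        e.set("boundaryCondition", "true" if s.clamped else "false")
        e.set("constant", "false")
        e.set(f"{{{BE_NS}}}carbon", str(s.carbon))

    lr = etree.SubElement(m, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        e = etree.SubElement(lr, f"{{{SBML_NS}}}reaction")
        e.set("id", f"R{r.number}")
        e.set("name", r.name)
        e.set("reversible", "false")

        rann = etree.SubElement(e, f"{{{SBML_NS}}}annotation")
        bl = etree.SubElement(rann, f"{{{BE_NS}}}law", nsmap={"be": BE_NS})
        bl.set("form", r.law.form)
        bl.set("source", r.source_compartment)
        if r.target_compartment:
            bl.set("target", r.target_compartment)
        bl.set("rateSpecies", ";".join(f"{sp}@{c}" for sp, c in r.rate_species))
        if r.inhibitor:
            bl.set("inhibitor", "@".join(r.inhibitor))
        if r.regulated_by:
            bl.set("regulatedBy", r.regulated_by)

        if r.substrates:
            lre = etree.SubElement(e, f"{{{SBML_NS}}}listOfReactants")
            for sp, comp, st in r.substrates:
                sr = etree.SubElement(lre, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", _sid(sp, comp))
                sr.set("stoichiometry", _num(st))
                sr.set("constant", "true")
        if r.products:
            lpr = etree.SubElement(e, f"{{{SBML_NS}}}listOfProducts")
            for sp, comp, st in r.products:
                sr = etree.SubElement(lpr, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", _sid(sp, comp))
                sr.set("stoichiometry", _num(st))
                sr.set("constant", "true")
        mods = r.modifiers
        if mods:
            lmo = etree.SubElement(e, f"{{{SBML_NS}}}listOfModifiers")
            for sp, comp in mods:
                mr = etree.SubElement(lmo, f"{{{SBML_NS}}}modifierSpeciesReference")
                mr.set("species", _sid(sp, comp))

        kl = etree.SubElement(e, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_law_math(r))
        llp = etree.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for pname in LAW_PARAMS[r.law.form]:
            lp = etree.SubElement(llp, f"{{{SBML_NS}}}localParameter")
            lp.set("id", pname)
            lp.set("value", _num(r.law.params[pname]))

    etree.indent(root, space="  ")
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=False
    ).decode()


# ------------------------------------------------------------------ reader
def import_sbml(text: str) -> CompartmentalModel:
    """Rebuild a :class:`CompartmentalModel` from a document written by
    :func:`export_sbml`."""
    issues = validate_sbml(text)
    if issues:
        raise SBMLError("invalid SBML document:\n" + "\n".join(issues))
    root = etree.fromstring(text.encode())
    m = root.find(f"{{{SBML_NS}}}model")

    be = m.find(f"{{{SBML_NS}}}annotation/{{{BE_NS}}}model")
    variant = be.get("variant")
    genes = tuple(be.get("genes").split(","))
    options = json.loads(be.get("options"))
    regulation = json.loads(be.find(f"{{{BE_NS}}}regulation").text)

    compartments = {}
    for c in m.findall(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment"):
        compartments[c.get("id")] = Compartment(
            c.get("id"), c.get("name"), float(c.get("size"))
        )

    species = {}
    for s in m.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        sp = Species(
            id=s.get("name"),
            compartment=s.get("compartment"),
            initial_concentration=float(s.get("initialConcentration")),
            clamped=s.get("boundaryCondition") == "true",
            carbon=int(s.get(f"{{{BE_NS}}}carbon", "0")),
        )
        species[(sp.id, sp.compartment)] = sp
    by_sid = {_sid(sp.id, sp.compartment): sp for sp in species.values()}

    reactions = []
    for e in m.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        bl = e.find(f"{{{SBML_NS}}}annotation/{{{BE_NS}}}law")
        form = bl.get("form")
        params = {}
        for lp in e.findall(
            f"{{{SBML_NS}}}kineticLaw/{{{SBML_NS}}}listOfLocalParameters/"
            f"{{{SBML_NS}}}localParameter"
        ):
            params[lp.get("id")] = float(lp.get("value"))

        def side(tag):
            out = []
            for sr in e.findall(f"{{{SBML_NS}}}{tag}/{{{SBML_NS}}}speciesReference"):
                sp = by_sid[sr.get("species")]
                out.append((sp.id, sp.compartment, float(sr.get("stoichiometry"))))
            return tuple(out)

        rate_species = tuple(
            tuple(item.split("@", 1)) for item in bl.get("rateSpecies").split(";")
        )
        inhibitor = None
        if bl.get("inhibitor"):
            inhibitor = tuple(bl.get("inhibitor").split("@", 1))
        reactions.append(
            Reaction(
                number=int(e.get("id")[1:]),
                name=e.get("name"),
                substrates=side("listOfReactants"),
                products=side("listOfProducts"),
                law=KineticLaw(form, params),
                source_compartment=bl.get("source"),
                target_compartment=bl.get("target"),
                rate_species=rate_species,
                inhibitor=inhibitor,
                regulated_by=bl.get("regulatedBy"),
            )
        )
    reactions.sort(key=lambda r: r.number)
    return CompartmentalModel(
        variant=variant,
        compartments=compartments,
        species=species,
        reactions=reactions,
        genes=genes,
        regulation=regulation,
        options=options,
    )


def validate_sbml(text: str) -> list[str]:
    """Structural validation; returns a list of issues with element paths."""
    issues = []
    try:
        root = etree.fromstring(text.encode() if isinstance(text, str) else text)
    except etree.XMLSyntaxError as exc:
        return [f"/: not well-formed XML ({exc})"]
    if root.tag != f"{{{SBML_NS}}}sbml":
        return [f"/{etree.QName(root).localname}: root element is not sbml"]
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        return ["/sbml: missing model element"]

    comp_ids = set()
    for c in model.findall(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment"):
        cid = c.get("id")
        path = f"/sbml/model/listOfCompartments/compartment[@id='{cid}']"
        if cid in comp_ids:
            issues.append(f"{path}: duplicate compartment id")
        comp_ids.add(cid)
        if float(c.get("size", "0")) <= 0:
            issues.append(f"{path}: size must be positive")

    sp_ids = set()
    for s in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        sid = s.get("id")
        path = f"/sbml/model/listOfSpecies/species[@id='{sid}']"
        if sid in sp_ids:
            issues.append(f"{path}: duplicate species id")
        sp_ids.add(sid)
        if s.get("compartment") not in comp_ids:
            issues.append(f"{path}: unknown compartment {s.get('compartment')!r}")
        if float(s.get("initialConcentration", "0")) < 0:
            issues.append(f"{path}: negative initial concentration")

    for e in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = e.get("id")
        path = f"/sbml/model/listOfReactions/reaction[@id='{rid}']"
        for sr in e.iter(f"{{{SBML_NS}}}speciesReference",
                         f"{{{SBML_NS}}}modifierSpeciesReference"):
            if sr.get("species") not in sp_ids:
                issues.append(
                    f"{path}: reference to unknown species {sr.get('species')!r}"
                )
        if e.find(f"{{{SBML_NS}}}kineticLaw") is None:
            issues.append(f"{path}: missing kineticLaw")
    return issues
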