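"""Read and write models as SBML Level 3 documents.

This is a self-contained SBML subset built on lxml: compartments, species,
reactions with stoichiometry, modifiers, and kinetic laws with local
parameters written as content MathML.  On reading, kinetic-law math is
converted to a sympy expression and pattern-matched against the canonical
mass-action and Michaelis-Menten forms (with optional non-competitive
inhibition factors); math that matches neither is retained verbatim as an
opaque rate expression, so GUI-authored files still load and simulate.

Scope: no events, rules, constraints or unit compliance (units produce
warnings at most).  Species marked ``constant`` that act only as reaction
modifiers are read back as enzymes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import sympy as sp
from lxml import etree

from .network import (
    Compartment,
    KineticLaw,
    LawForm,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
)

__all__ = ["SbmlDocumentSummary", "SbmlError", "read_sbml", "write_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://sphingoflux.invalid/sbml-annotations"


class SbmlError(NetworkError):
    pass


@dataclass
class SbmlDocumentSummary:
    level: int
    version: int
    n_compartments: int
    n_species: int
    n_reactions: int
    n_parameters: int
    unsupported: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"SBML Level {self.level} Version {self.version}",
            f"compartments: {self.n_compartments}",
            f"species: {self.n_species}",
            f"reactions: {self.n_reactions}",
            f"parameters: {self.n_parameters}",
        ]
        if self.unsupported:
            lines.append("unsupported constructs: " + ", ".join(self.unsupported))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# MathML <-> sympy


def _expr_to_mathml(expr: sp.Expr) -> etree._Element:
    M = lambda tag: etree.SubElement  # noqa: E731 (shorthand below)

    def build(node: sp.Expr, parent: etree._Element) -> None:
        if isinstance(node, sp.Symbol):
            ci = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
            ci.text = f" {node.name} "
        elif isinstance(node, (sp.Integer, sp.Float, sp.Rational)) or node.is_Number:
            cn = etree.SubElement(parent, f"{{{MATHML_NS}}}cn")
            cn.text = f" {float(node):.17g} "
        elif isinstance(node, sp.Add):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}plus")
            for arg in node.args:
                build(arg, ap)
        elif isinstance(node, sp.Mul):
            num, den = node.as_numer_denom()
            if den != 1:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}divide")
                build(num, ap)
                build(den, ap)
            else:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}times")
                for arg in node.args:
                    build(arg, ap)
        elif isinstance(node, sp.Pow):
            base, ex = node.args
            if ex == -1:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}divide")
                cn = etree.SubElement(ap, f"{{{MATHML_NS}}}cn")
                cn.text = " 1 "
                build(base, ap)
            else:
                ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
                etree.SubElement(ap, f"{{{MATHML_NS}}}power")
                build(base, ap)
                build(ex, ap)
        else:
            raise SbmlError(f"cannot serialize rate expression term {node!r}")

    math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
    build(sp.nsimplify(expr, rational=False), math)
    return math


def _mathml_to_expr(math: etree._Element) -> sp.Expr:
    def conv(el: etree._Element) -> sp.Expr:
        tag = etree.QName(el).localname
        if tag == "ci":
            return sp.Symbol(el.text.strip())
        if tag == "cn":
            if el.get("type") == "e-notation":
                mant = float(el.text.strip())
                exp = float(el[0].tail.strip())
                return sp.Float(mant * 10**exp)
            return sp.Float(float(el.text.strip()))
        if tag == "apply":
            children = [c for c in el if isinstance(c.tag, str)]
            op = etree.QName(children[0]).localname
            args = [conv(c) for c in children[1:]]
            if op == "plus":
                return sp.Add(*args) if args else sp.Integer(0)
            if op == "times":
                return sp.Mul(*args) if args else sp.Integer(1)
            if op == "minus":
                return -args[0] if len(args) == 1 else args[0] - args[1]
            if op == "divide":
                return args[0] / args[1]
            if op == "power":
                return args[0] ** args[1]
            raise SbmlError(f"unsupported MathML operator <{op}>")
        raise SbmlError(f"unsupported MathML element <{tag}>")

    children = [c for c in math if isinstance(c.tag, str)]
    if len(children) != 1:
        raise SbmlError("malformed kinetic-law math")
    return conv(children[0])


# ---------------------------------------------------------------------------
# kinetic-law pattern matching


def _law_to_expr(reaction: Reaction) -> sp.Expr:
    """Symbolic flux with species ids and *local* parameter names as symbols."""
    law = reaction.law
    if law.form is LawForm.MASS_ACTION:
        expr = sp.Symbol("k")
        for sid, nu in reaction.substrates:
            expr *= sp.Symbol(sid) ** nu
    elif law.form in (LawForm.MICHAELIS_MENTEN, LawForm.MM_INHIBITED):
        s = sp.Symbol(reaction.substrates[0][0])
        expr = sp.Symbol("Vmax") * s / (sp.Symbol("Km") + s)
    else:
        expr = sp.sympify(law.expression)
    for sid, _ in law.inhibitors:
        expr = expr / (1 + sp.Symbol(sid) / sp.Symbol(f"Ki_{sid}"))
    return expr


def _match_law(
    expr: sp.Expr,
    local_params: dict[str, float],
    substrates: list[tuple[str, int]],
    species_ids: set[str],
) -> KineticLaw:
    """Recognize canonical kinetic forms; fall back to an opaque expression."""
    psyms = {sp.Symbol(name): value for name, value in local_params.items()}
    substrate_ids = {sid for sid, _ in substrates}
    # peel non-competitive inhibition factors: 1/(1+[I]/Ki) contributes a
    # denominator factor (Ki + I) and a numerator factor Ki after together()
    inhibitors: list[tuple[str, float]] = []
    core = sp.together(sp.sympify(expr))
    num, den = sp.fraction(core)
    kept: list[sp.Expr] = []
    for fac in sp.Mul.make_args(sp.factor(den)):
        base, power = fac.as_base_exp()
        terms = sp.Add.make_args(base)
        hit = None
        if power == 1 and len(terms) == 2:
            a, b = terms
            for p, s in ((a, b), (b, a)):
                if (
                    p in psyms
                    and isinstance(s, sp.Symbol)
                    and s.name in species_ids
                    and s.name not in substrate_ids  # keep MM's (Km + S) intact
                ):
                    hit = (s.name, psyms[p], p)
                    break
        if hit is not None:
            inhibitors.append((hit[0], hit[1]))
            num = num / hit[2]
        else:
            kept.append(fac)
    core = sp.cancel(num / sp.Mul(*kept)) if kept else sp.expand(num)

    param_syms = set(psyms)

    def numeric(term: sp.Expr) -> float:
        """Value of a term that is a single parameter symbol (times a number).

        Composite parameter expressions (e.g. products of two parameters) are
        deliberately rejected so they survive as opaque laws and the
        parameter registry round-trips losslessly.
        """
        syms = term.free_symbols
        if not (syms <= param_syms and len(syms) <= 1):
            return -1.0
        try:
            return float(term.subs(psyms))
        except TypeError:
            return -1.0

    # Michaelis-Menten: a*S/(b+S)
    if substrates:
        s = sp.Symbol(substrates[0][0])
        a, b = sp.Wild("a", exclude=[s]), sp.Wild("b", exclude=[s])
        m = core.match(a * s / (b + s))
        if m and m.get(a) is not None and m.get(b) is not None:
            vmax, km = numeric(m[a]), numeric(m[b])
            if vmax > 0 and km > 0:
                form = LawForm.MM_INHIBITED if inhibitors else LawForm.MICHAELIS_MENTEN
                return KineticLaw(form, {"Vmax": vmax, "Km": km}, inhibitors=inhibitors)
    # mass action: c * prod S^nu
    target = sp.Integer(1)
    for sid, nu in substrates:
        target *= sp.Symbol(sid) ** nu
    c = sp.Wild("c", exclude=[sp.Symbol(sid) for sid, _ in substrates])
    m = core.match(c * target)
    if m is not None and m.get(c) is not None:
        kval = numeric(m[c])
        if kval > 0:
            return KineticLaw(LawForm.MASS_ACTION, {"k": kval}, inhibitors=inhibitors)
    # opaque fallback: keep the whole original expression with its parameters
    return KineticLaw(
        LawForm.OPAQUE,
        dict(local_params),
        inhibitors=[],
        expression=str(expr),
    )


# ---------------------------------------------------------------------------
# writer


def write_sbml(net: ReactionNetwork, path: str) -> SbmlDocumentSummary:
    """Serialize the network as an SBML Level 3 Version 2 document."""
    nsmap = {None: SBML_NS, "sfx": ANNOT_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model")
    model.set("id", net.metadata.get("scenario", "model") or "model")

    locs = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for comp in net.compartments:
        el = etree.SubElement(locs, f"{{{SBML_NS}}}compartment")
        el.set("id", comp.id)
        el.set("name", comp.name)
        el.set("size", repr(comp.volume))
        el.set("constant", "true")

    los = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species:
        el = etree.SubElement(los, f"{{{SBML_NS}}}species")
        el.set("id", s.id)
        el.set("name", s.name)
        el.set("compartment", s.compartment or net.compartments[0].id)
        el.set("initialConcentration", repr(s.initial_concentration))
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "true" if s.is_enzyme else "false")
        el.set("constant", "true" if s.is_enzyme else "false")
        if not s.initial_explicit:
            el.set(f"{{{ANNOT_NS}}}defaultInitial", "true")

    lor = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    n_params = 0
    for r in net.reactions:
        el = etree.SubElement(lor, f"{{{SBML_NS}}}reaction")
        el.set("id", r.id)
        el.set("name", r.name)
        el.set("reversible", "false")
        if r.is_transport:
            el.set(f"{{{ANNOT_NS}}}transport", "true")
        if r.substrates:
            lrf = etree.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sid, nu in r.substrates:
                ref = etree.SubElement(lrf, f"{{{SBML_NS}}}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(nu))
                ref.set("constant", "true")
        if r.products:
            lpf = etree.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sid, nu in r.products:
                ref = etree.SubElement(lpf, f"{{{SBML_NS}}}speciesReference")
                ref.set("species", sid)
                ref.set("stoichiometry", str(nu))
                ref.set("constant", "true")
        mods = list(r.modifiers) + [sid for sid, _ in r.law.inhibitors
                                    if sid not in r.modifiers]
        if mods:
            lmf = etree.SubElement(el, f"{{{SBML_NS}}}listOfModifiers")
            for sid in mods:
                ref = etree.SubElement(lmf, f"{{{SBML_NS}}}modifierSpeciesReference")
                ref.set("species", sid)
        kl = etree.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        try:
            expr = _law_to_expr(r)
        except sp.SympifyError as exc:  # pragma: no cover
            raise SbmlError(f"reaction {r.id!r}: cannot serialize rate law") from exc
        kl.append(_expr_to_mathml(expr))
        lop = etree.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for name, value in sorted(r.law.parameters.items()):
            pe = etree.SubElement(lop, f"{{{SBML_NS}}}localParameter")
            pe.set("id", name)
            pe.set("value", repr(value))
            n_params += 1
        for sid, ki in r.law.inhibitors:
            pe = etree.SubElement(lop, f"{{{SBML_NS}}}localParameter")
            pe.set("id", f"Ki_{sid}")
            pe.set("value", repr(ki))
            n_params += 1

    etree.ElementTree(root).write(
        path, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    return SbmlDocumentSummary(
        level=3,
        version=2,
        n_compartments=len(net.compartments),
        n_species=len(net.species),
        n_reactions=len(net.reactions),
        n_parameters=n_params,
    )


# ---------------------------------------------------------------------------
# reader


def read_sbml(path: str) -> ReactionNetwork:
    """Load an SBML Level 2/3 file as a :class:`ReactionNetwork`."""
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"not parseable as SBML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise SbmlError("root element is not <sbml>")
    ns = etree.QName(root).namespace
    level = int(root.get("level", "0"))
    if level not in (2, 3):
        raise SbmlError(f"unsupported SBML level {level}")

    def q(tag):
        return f"{{{ns}}}{tag}"

    model = root.find(q("model"))
    if model is None:
        raise SbmlError("no <model> element")
    for construct in ("listOfRules", "listOfEvents", "listOfConstraints"):
        if model.find(q(construct)) is not None:
            warnings.warn(f"ignoring unsupported SBML construct {construct}")

    compartments = [
        Compartment(
            el.get("id"),
            el.get("name", el.get("id")),
            float(el.get("size", el.get("volume", 1.0) or 1.0)),
        )
        for el in model.findall(f"{q('listOfCompartments')}/{q('compartment')}")
    ]
    if not compartments:
        compartments = [Compartment("default")]

    modifier_ids: set[str] = set()
    for el in model.findall(f"{q('listOfReactions')}/{q('reaction')}"):
        for ref in el.findall(f"{q('listOfModifiers')}/{q('modifierSpeciesReference')}"):
            modifier_ids.add(ref.get("species"))

    species = []
    for el in model.findall(f"{q('listOfSpecies')}/{q('species')}"):
        sid = el.get("id")
        constant = el.get("constant", "false") == "true"
        conc = el.get("initialConcentration")
        if conc is None:
            conc = el.get("initialAmount", "0")
        species.append(
            Species(
                sid,
                name=el.get("name", sid),
                compartment=el.get("compartment", compartments[0].id),
                initial_concentration=float(conc),
                is_enzyme=constant and sid in modifier_ids,
                initial_explicit=el.get(f"{{{ANNOT_NS}}}defaultInitial") != "true",
            )
        )
    species_ids = {s.id for s in species}

    global_params = {
        el.get("id"): float(el.get("value", "0"))
        for el in model.findall(f"{q('listOfParameters')}/{q('parameter')}")
    }

    reactions = []
    for el in model.findall(f"{q('listOfReactions')}/{q('reaction')}"):
        rid = el.get("id")
        subs = [
            (ref.get("species"), int(float(ref.get("stoichiometry", "1"))))
            for ref in el.findall(f"{q('listOfReactants')}/{q('speciesReference')}")
        ]
        prods = [
            (ref.get("species"), int(float(ref.get("stoichiometry", "1"))))
            for ref in el.findall(f"{q('listOfProducts')}/{q('speciesReference')}")
        ]
        mods = [
            ref.get("species")
            for ref in el.findall(f"{q('listOfModifiers')}/{q('modifierSpeciesReference')}")
        ]
        kl = el.find(q("kineticLaw"))
        if kl is None:
            raise SbmlError(f"reaction {rid!r}: missing kinetic law")
        local = {
            p.get("id"): float(p.get("value", "0"))
            for lp_tag in ("listOfLocalParameters", "listOfParameters")
            for p in kl.findall(f"{q(lp_tag)}/{q('localParameter')}")
            + kl.findall(f"{q(lp_tag)}/{q('parameter')}")
        }
        math = kl.find(f"{{{MATHML_NS}}}math")
        if math is None:
            raise SbmlError(f"reaction {rid!r}: kinetic law has no math")
        expr = _mathml_to_expr(math)
        # substitute global parameters that are not shadowed locally
        expr = expr.subs(
            {sp.Symbol(n): v for n, v in global_params.items() if n not in local}
        )
        law = _match_law(expr, local, subs, species_ids)
        # drop dynamic species wrongly kept as modifiers of recognized laws
        mods = [m for m in mods if m not in {i for i, _ in law.inhibitors}]
        reactions.append(
            Reaction(
                rid,
                name=el.get("name", rid),
                substrates=subs,
                products=prods,
                modifiers=mods,
                law=law,
                is_transport=el.get(f"{{{ANNOT_NS}}}transport") == "true",
            )
        )

    return ReactionNetwork(
        compartments,
        species,
        reactions,
        metadata={"scenario": model.get("id", "model"), "sbml_level": level},
    )


def summarize(path: str) -> SbmlDocumentSummary:
    """Parse and summarize an SBML document without building a network."""
    net = read_sbml(path)
    return SbmlDocumentSummary(
        level=net.metadata.get("sbml_level", 3),
        version=2,
        n_compartments=len(net.compartments),
        n_species=len(net.species),
        n_reactions=len(net.reactions),
        n_parameters=len(net.parameter_registry()),
    )
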