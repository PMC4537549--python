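"""Compartmental reaction networks with mass-action and Michaelis-Menten kinetics.

A :class:`ReactionNetwork` is the single source of truth from which the
deterministic rate laws, stochastic propensities and the stoichiometry matrix
are constructed.  Species live in compartments; reactions carry a
:class:`KineticLaw` that is either mass action (flux ``k * prod [S]^nu``),
Michaelis-Menten (``Vmax*[S]/(Km+[S])`` on a single rate-limiting substrate),
or an opaque symbolic rate expression.  Any law may additionally carry
non-competitive inhibitor terms, each multiplying the base flux by
``1/(1 + [I]/Ki)``; a Michaelis-Menten law with inhibitors is the
``MM_INHIBITED`` form.

All compartments default to unit volume, so concentrations and copy numbers
share one scale and stochastic propensities equal macroscopic fluxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import sympy as sp

__all__ = [
    "LawForm",
    "Compartment",
    "Species",
    "KineticLaw",
    "Reaction",
    "ReactionNetwork",
    "NetworkError",
    "stoichiometry_matrix",
    "reaction_flux",
    "build_rhs",
    "build_propensities",
]


class NetworkError(ValueError):
    """Structural problem in a reaction network (dangling reference, bad parameter)."""


class LawForm(str, Enum):
    MASS_ACTION = "mass_action"
    MICHAELIS_MENTEN = "michaelis_menten"
    MM_INHIBITED = "mm_inhibited"
    OPAQUE = "opaque"


@dataclass
class Compartment:
    id: str
    name: str = ""
    volume: float = 1.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise NetworkError(f"compartment {self.id!r}: volume must be > 0")
        if not self.name:
            self.name = self.id


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = ""
    initial_concentration: float = 0.0
    is_enzyme: bool = False
    #: False when the initial value was defaulted rather than stated explicitly.
    initial_explicit: bool = True

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise NetworkError(f"species {self.id!r}: initial concentration must be >= 0")
        if not self.name:
            self.name = self.id


@dataclass
class KineticLaw:
    """Tagged rate law.

    ``parameters`` maps local symbol names to positive values:
    ``{"k": ...}`` for mass action, ``{"Vmax": ..., "Km": ...}`` for the MM
    forms.  ``inhibitors`` is a list of ``(species_id, Ki)`` pairs; each
    contributes a factor ``1/(1+[I]/Ki)``.  ``expression`` holds a
    sympy-parseable rate expression for the OPAQUE form, written in terms of
    species ids and the local parameter names.
    """

    form: LawForm
    parameters: dict[str, float] = field(default_factory=dict)
    inhibitors: list[tuple[str, float]] = field(default_factory=list)
    expression: str | None = None

    def __post_init__(self) -> None:
        self.form = LawForm(self.form)
        for name, value in self.parameters.items():
            if not value > 0:
                raise NetworkError(f"kinetic parameter {name}={value}: must be > 0")
        for sid, ki in self.inhibitors:
            if not ki > 0:
                raise NetworkError(f"inhibition constant for {sid}: must be > 0")
        self.inhibitors = sorted(self.inhibitors)  # canonical order
        if self.form is LawForm.MASS_ACTION and "k" not in self.parameters:
            raise NetworkError("mass-action law requires parameter 'k'")
        if self.form in (LawForm.MICHAELIS_MENTEN, LawForm.MM_INHIBITED):
            missing = {"Vmax", "Km"} - set(self.parameters)
            if missing:
                raise NetworkError(f"MM law requires parameters {sorted(missing)}")
        if self.form is LawForm.MM_INHIBITED and not self.inhibitors:
            raise NetworkError("MM_INHIBITED law requires at least one inhibitor")
        if self.form is LawForm.OPAQUE and not self.expression:
            raise NetworkError("opaque law requires an expression")

    def param_symbols(self) -> list[str]:
        """Local parameter symbol names, inhibition constants last."""
        syms = sorted(self.parameters)
        syms += [f"Ki_{sid}" for sid, _ in self.inhibitors]
        return syms


@dataclass
class Reaction:
    id: str
    name: str = ""
    substrates: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    law: KineticLaw = None  # type: ignore[assignment]
    is_transport: bool = False

    def __post_init__(self) -> None:
        if not self.substrates and not self.products:
            raise NetworkError(f"reaction {self.id!r}: needs at least one substrate or product")
        for sid, nu in self.substrates + self.products:
            if nu < 1:
                raise NetworkError(f"reaction {self.id!r}: coefficient for {sid} must be >= 1")
        if self.law is None:
            raise NetworkError(f"reaction {self.id!r}: missing kinetic law")
        if not self.name:
            self.name = self.id


class ReactionNetwork:
    """Compartments, species and reactions plus a flat parameter registry.

    The registry maps ``"<reaction id>.<symbol>"`` to the parameter value, which
    guarantees key uniqueness across reactions.  Inhibition constants appear as
    ``"<reaction id>.Ki_<species id>"``.
    """

    def __init__(
        self,
        compartments: list[Compartment],
        species: list[Species],
        reactions: list[Reaction],
        metadata: dict | None = None,
    ) -> None:
        self.compartments = list(compartments)
        self.species = list(species)
        self.reactions = list(reactions)
        self.metadata: dict = dict(metadata or {})
        self._validate()
        self._compiled: _CompiledNetwork | None = None

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        comp_ids = [c.id for c in self.compartments]
        if len(set(comp_ids)) != len(comp_ids):
            raise NetworkError("duplicate compartment ids")
        sp_ids = [s.id for s in self.species]
        if len(set(sp_ids)) != len(sp_ids):
            raise NetworkError("duplicate species ids")
        known = set(sp_ids)
        comps = set(comp_ids)
        for s in self.species:
            if s.compartment and s.compartment not in comps:
                raise NetworkError(f"species {s.id!r}: unknown compartment {s.compartment!r}")
        rx_ids = [r.id for r in self.reactions]
        if len(set(rx_ids)) != len(rx_ids):
            raise NetworkError("duplicate reaction ids")
        for r in self.reactions:
            for sid, _ in r.substrates + r.products:
                if sid not in known:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
            for sid in r.modifiers:
                if sid not in known:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown modifier {sid!r}"
                    )
            for sid, _ in r.law.inhibitors:
                if sid not in known:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown inhibitor {sid!r}"
                    )

    @property
    def dynamic_species(self) -> list[Species]:
        """Species that carry state (non-enzymes)."""
        return [s for s in self.species if not s.is_enzyme]

    @property
    def enzymes(self) -> list[Species]:
        return [s for s in self.species if s.is_enzyme]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.dynamic_species)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.dynamic_species])

    # -- parameter registry ------------------------------------------------
    def parameter_registry(self) -> dict[str, float]:
        reg: dict[str, float] = {}
        for r in self.reactions:
            for name, value in sorted(r.law.parameters.items()):
                reg[f"{r.id}.{name}"] = value
            for sid, ki in r.law.inhibitors:
                reg[f"{r.id}.Ki_{sid}"] = ki
        return reg

    def parameter_names(self) -> list[str]:
        return list(self.parameter_registry())

    def parameter_values(self) -> np.ndarray:
        return np.array(list(self.parameter_registry().values()))

    def set_parameter(self, key: str, value: float) -> None:
        if not value > 0:
            raise NetworkError(f"parameter {key}={value}: must be > 0")
        rid, _, sym = key.partition(".")
        r = self.get_reaction(rid)
        if sym.startswith("Ki_"):
            sid = sym[3:]
            for i, (isid, _) in enumerate(r.law.inhibitors):
                if isid == sid:
                    r.law.inhibitors[i] = (isid, value)
                    self._compiled = None
                    return
            raise NetworkError(f"unknown inhibitor parameter {key!r}")
        if sym not in r.law.parameters:
            raise NetworkError(f"unknown parameter {key!r}")
        r.law.parameters[sym] = value
        self._compiled = None

    def get_parameter(self, key: str) -> float:
        try:
            return self.parameter_registry()[key]
        except KeyError:
            raise NetworkError(f"unknown parameter {key!r}") from None

    def copy(self) -> "ReactionNetwork":
        import copy as _copy

        return _copy.deepcopy(self)

    def __repr__(self) -> str:
        return (
            f"<ReactionNetwork {self.metadata.get('scenario', '?')}: "
            f"{len(self.compartments)} compartments, {len(self.dynamic_species)} species, "
            f"{len(self.reactions)} reactions>"
        )

    # -- structured-text serialization ------------------------------------
    def to_dict(self) -> dict:
        """JSON-serializable document, one record per reaction; lossless."""
        return {
            "metadata": {
                k: v for k, v in self.metadata.items()
                if isinstance(v, (str, int, float, bool, list, dict, type(None)))
            },
            "compartments": [
                {"id": c.id, "name": c.name, "volume": c.volume}
                for c in self.compartments
            ],
            "species": [
                {
                    "id": s.id,
                    "name": s.name,
                    "compartment": s.compartment,
                    "initial_concentration": s.initial_concentration,
                    "is_enzyme": s.is_enzyme,
                    "initial_explicit": s.initial_explicit,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "substrates": [list(t) for t in r.substrates],
                    "products": [list(t) for t in r.products],
                    "modifiers": list(r.modifiers),
                    "is_transport": r.is_transport,
                    "law": {
                        "form": r.law.form.value,
                        "parameters": dict(r.law.parameters),
                        "inhibitors": [list(t) for t in r.law.inhibitors],
                        "expression": r.law.expression,
                    },
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ReactionNetwork":
        return cls(
            compartments=[Compartment(**c) for c in doc["compartments"]],
            species=[Species(**s) for s in doc["species"]],
            reactions=[
                Reaction(
                    id=r["id"],
                    name=r["name"],
                    substrates=[(sid, int(nu)) for sid, nu in r["substrates"]],
                    products=[(sid, int(nu)) for sid, nu in r["products"]],
                    modifiers=list(r["modifiers"]),
                    is_transport=r["is_transport"],
                    law=KineticLaw(
                        form=LawForm(r["law"]["form"]),
                        parameters=dict(r["law"]["parameters"]),
                        inhibitors=[(sid, float(ki)) for sid, ki in r["law"]["inhibitors"]],
                        expression=r["law"]["expression"],
                    ),
                )
                for r in doc["reactions"]
            ],
            metadata=doc.get("metadata", {}),
        )

    def to_text(self) -> str:
        import json

        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_text(cls, text: str) -> "ReactionNetwork":
        import json

        return cls.from_dict(json.loads(text))

    # -- compiled numerics -------------------------------------------------
    def compiled(self) -> "_CompiledNetwork":
        if self._compiled is None:
            self._compiled = _CompiledNetwork(self)
        return self._compiled


# ---------------------------------------------------------------------------
# symbolic flux construction


def _flux_expression(
    reaction: Reaction, conc: dict[str, sp.Symbol], params: dict[str, sp.Symbol]
) -> sp.Expr:
    """Symbolic flux of one reaction in terms of species and parameter symbols.

    ``params`` keys are registry keys ``rid.symbol``.
    """
    law = reaction.law
    rid = reaction.id
    if law.form is LawForm.MASS_ACTION:
        expr = params[f"{rid}.k"]
        for sid, nu in reaction.substrates:
            expr = expr * conc[sid] ** nu
    elif law.form in (LawForm.MICHAELIS_MENTEN, LawForm.MM_INHIBITED):
        if not reaction.substrates:
            raise NetworkError(f"reaction {rid!r}: MM law requires a substrate")
        s = conc[reaction.substrates[0][0]]  # first substrate is rate-limiting
        expr = params[f"{rid}.Vmax"] * s / (params[f"{rid}.Km"] + s)
    elif law.form is LawForm.OPAQUE:
        local = {name: params[f"{rid}.{name}"] for name in law.parameters}
        expr = sp.sympify(law.expression, locals={**conc, **local})
    else:  # pragma: no cover
        raise NetworkError(f"unknown law form {law.form}")
    for sid, _ in law.inhibitors:
        expr = expr / (1 + conc[sid] / params[f"{rid}.Ki_{sid}"])
    return expr


class _CompiledNetwork:
    """Lambdified fluxes, RHS and Jacobians for one network.

    Evaluation signature everywhere is ``f(x, p)`` with ``x`` the dynamic
    species vector (network order) and ``p`` the registry parameter vector.
    """

    def __init__(self, net: ReactionNetwork) -> None:
        self.net = net
        dyn = net.dynamic_species
        self.species_ids = [s.id for s in dyn]
        self.param_names = net.parameter_names()
        self.x_syms = [sp.Symbol(f"x{i}") for i in range(len(dyn))]
        conc = {s.id: sym for s, sym in zip(dyn, self.x_syms)}
        # enzymes enter laws only through constant concentrations (absorbed in Vmax);
        # opaque expressions may still reference them by id
        for s in net.enzymes:
            conc[s.id] = sp.Float(s.initial_concentration)
        self.p_syms = [sp.Symbol(f"p{i}") for i in range(len(self.param_names))]
        psym = dict(zip(self.param_names, self.p_syms))
        self.flux_exprs = sp.Matrix(
            [_flux_expression(r, conc, psym) for r in net.reactions]
        )
        self.M = stoichiometry_matrix(net)
        args = (self.x_syms, self.p_syms)
        self._flux = sp.lambdify(args, self.flux_exprs, "numpy")
        self._jac_x = sp.lambdify(args, self.flux_exprs.jacobian(self.x_syms), "numpy")
        self._jac_p = sp.lambdify(args, self.flux_exprs.jacobian(self.p_syms), "numpy")

    def flux(self, x: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        p = self._p(p)
        return np.asarray(self._flux(list(x), list(p)), dtype=float).ravel()

    def rhs(self, x: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        return self.M @ self.flux(x, p)

    def flux_jac_x(self, x: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        p = self._p(p)
        return np.asarray(self._jac_x(list(x), list(p)), dtype=float)

    def flux_jac_p(self, x: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        p = self._p(p)
        return np.asarray(self._jac_p(list(x), list(p)), dtype=float)

    def rhs_jac_x(self, x: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        return self.M @ self.flux_jac_x(x, p)

    def rhs_jac_p(self, x: np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
        return self.M @ self.flux_jac_p(x, p)

    def _p(self, p: np.ndarray | None) -> np.ndarray:
        return self.net.parameter_values() if p is None else np.asarray(p, dtype=float)


# ---------------------------------------------------------------------------
# public operations


def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Net stoichiometry matrix M (dynamic species x reactions), integer-valued.

    Entry ``(n, j)`` is the net coefficient of species *n* in reaction *j*;
    modifiers contribute zero.
    """
    index = net.species_index()
    M = np.zeros((len(index), len(net.reactions)), dtype=int)
    for j, r in enumerate(net.reactions):
        for sid, nu in r.substrates:
            if sid in index:  # enzymes written as substrates would be a modeling error
                M[index[sid], j] -= nu
        for sid, nu in r.products:
            if sid in index:
                M[index[sid], j] += nu
    return M


def reaction_flux(
    reaction: Reaction,
    state: dict[str, float],
    params: dict[str, float] | None = None,
) -> float:
    """Macroscopic flux of a single reaction at the given concentrations.

    ``state`` maps species ids to non-negative concentrations; missing species
    default to zero.  ``params`` may override the law's own parameter values,
    keyed by local symbol name (``k``, ``Vmax``, ``Km``, ``Ki_<species>``).
    """
    for sid, value in state.items():
        if value < 0:
            raise NetworkError(f"negative concentration for {sid!r}")
    law = reaction.law
    p = dict(law.parameters)
    ki = {f"Ki_{sid}": v for sid, v in law.inhibitors}
    if params:
        for key, value in params.items():
            if key in p:
                p[key] = value
            elif key in ki:
                ki[key] = value

    def conc(sid: str) -> float:
        return float(state.get(sid, 0.0))

    if law.form is LawForm.MASS_ACTION:
        flux = p["k"]
        for sid, nu in reaction.substrates:
            flux *= conc(sid) ** nu
    elif law.form in (LawForm.MICHAELIS_MENTEN, LawForm.MM_INHIBITED):
        s = conc(reaction.substrates[0][0])
        flux = p["Vmax"] * s / (p["Km"] + s)
    else:
        local = {**{k: sp.Float(v) for k, v in p.items()}}
        expr = sp.sympify(law.expression, locals=local)
        subs = {sp.Symbol(sid): conc(sid) for sid in map(str, expr.free_symbols)}
        flux = float(expr.subs(subs))
    for sid, _ in law.inhibitors:
        flux /= 1 + conc(sid) / ki[f"Ki_{sid}"]
    return float(flux)


def build_rhs(net: ReactionNetwork):
    """Return ``f(state, t=0) -> dstate/dt`` implementing dS/dt = M v(S)."""
    compiled = net.compiled()
    p = net.parameter_values()

    def rhs(state: np.ndarray, t: float = 0.0) -> np.ndarray:
        return compiled.M @ compiled.flux(np.asarray(state, dtype=float), p)

    return rhs


def build_propensities(net: ReactionNetwork):
    """Return ``a(state) -> propensity vector`` for the stochastic jump process.

    Under the unit-volume convention the propensity of each reaction equals its
    macroscopic flux evaluated at the (copy-number) state.
    """
    compiled = net.compiled()
    p = net.parameter_values()

    def propensities(state: np.ndarray) -> np.ndarray:
        return np.maximum(compiled.flux(np.asarray(state, dtype=float), p), 0.0)

    return propensities
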