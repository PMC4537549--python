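"""The nine-compartment sphingolipid metabolism model and disease scenarios.

The homeostasis network tracks six sphingolipid classes -- ceramide (CER),
sphingomyelin (SM), sphingosine (Sph), sphingosine-1-phosphate (S1P),
ceramide-1-phosphate (C1P) and a glycosphingolipid pool (GSL) -- across nine
subcellular compartments: the outer and inner plasma-membrane leaflets, the
cytoplasm, the endoplasmic reticulum, the cytoplasmic and lumenal faces of
the Golgi apparatus, the nucleus, the mitochondrion and the lysosome.
Molecular transport uses mass-action kinetics, enzymatic conversions and
protein- or vesicle-mediated transfer use Michaelis-Menten kinetics, and S1P
and C1P inhibit acidic sphingomyelinase and the de novo ceramide inflow (the
serine-palmitoyltransferase surrogate) through non-competitive terms.  De
novo ceramide synthesis is a constant inflow into the ER; exogenous C1P,
CER, Sph, S1P and SM enter at the outer membrane; S1P lyase (SPL1) in the ER
irreversibly removes the sphingoid backbone, and hydrophilic monomers leave
the cell from the outer membrane.

Parameterization is *stationary by construction*: a strictly positive flux
distribution balancing every species at the packaged initial concentrations
is found by linear programming against preferred pathway magnitudes, and
each rate constant is then solved from its reaction's flux at that operating
point.  Saturation headroom is set per enzyme family -- sphingomyelinases
and the endocytic SM route run close to saturation, ceramidases far from it
-- which is what gives the Alzheimer's-disease scenario its qualitative
behavior: the uncorrected disease patch overruns the SM hydrolysis capacity
(unbounded SM growth in the lysosome, outer membrane and ER), while the
corrected patch is bounded and shows ceramide accumulation in the ER and
lysosome, an early sphingosine dip followed by accumulation, and reduced
S1P throughout.  See docs/methods.md for the full rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import (
    Compartment,
    KineticLaw,
    LawForm,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
    stoichiometry_matrix,
)

__all__ = [
    "ScenarioPatch",
    "AssemblyError",
    "build_homeostasis_model",
    "build_ad_model",
    "ad_scenario",
    "apply_scenario",
    "EXPECTED_COUNTS",
]

#: printed inventory the assembled model must reproduce
EXPECTED_COUNTS = {
    "compartments": 9,
    "species": 39,
    "reactions": 69,
    "enzymes": 37,
    "parameters": 129,
    "explicit_initials": 38,
}


class AssemblyError(NetworkError):
    pass


# ---------------------------------------------------------------------------
# inventory (single source of truth)

COMPARTMENTS = [
    ("om", "outer plasma-membrane leaflet"),
    ("im", "inner plasma-membrane leaflet"),
    ("cyt", "cytoplasm"),
    ("er", "endoplasmic reticulum"),
    ("gc", "Golgi apparatus, cytoplasmic face"),
    ("gl", "Golgi apparatus, lumenal face"),
    ("nuc", "nucleus"),
    ("mito", "mitochondrion"),
    ("lys", "lysosome"),
]

#: (species id, compartment, initial concentration).  Placeholder levels in
#: relative molar units: SM at the outer membrane dominates, monomeric
#: lipids (Sph, S1P, C1P) are scarce.  GSL on the Golgi cytoplasmic face has
#: no explicit initial value and receives the class default.
SPECIES_LEVELS = [
    ("CER_om", "om", 10.0), ("CER_im", "im", 8.0), ("CER_er", "er", 15.0),
    ("CER_gc", "gc", 6.0), ("CER_gl", "gl", 6.0), ("CER_nuc", "nuc", 8.0),
    ("CER_mito", "mito", 12.0), ("CER_lys", "lys", 10.0),
    ("SM_om", "om", 200.0), ("SM_im", "im", 25.0), ("SM_er", "er", 20.0),
    ("SM_gl", "gl", 30.0), ("SM_nuc", "nuc", 10.0), ("SM_lys", "lys", 25.0),
    ("Sph_om", "om", 3.0), ("Sph_im", "im", 2.5), ("Sph_cyt", "cyt", 2.0),
    ("Sph_er", "er", 3.0), ("Sph_gc", "gc", 1.5), ("Sph_nuc", "nuc", 1.5),
    ("Sph_mito", "mito", 4.0), ("Sph_lys", "lys", 3.0),
    ("S1P_om", "om", 0.6), ("S1P_im", "im", 0.5), ("S1P_cyt", "cyt", 0.8),
    ("S1P_er", "er", 0.7), ("S1P_gc", "gc", 0.3), ("S1P_nuc", "nuc", 0.4),
    ("S1P_mito", "mito", 0.9),
    ("C1P_om", "om", 1.2), ("C1P_im", "im", 0.8), ("C1P_cyt", "cyt", 1.0),
    ("C1P_gc", "gc", 1.5), ("C1P_gl", "gl", 1.0),
    ("GSL_om", "om", 40.0), ("GSL_im", "im", 8.0), ("GSL_gc", "gc", None),
    ("GSL_gl", "gl", 15.0), ("GSL_lys", "lys", 12.0),
]

GSL_DEFAULT_LEVEL = 10.0  # class default used where no explicit value is given

#: enzyme entities (diamond boxes of the pathway diagram); localized but
#: constant -- their abundance is absorbed into Vmax.
ENZYMES = [
    ("SMS1", "gl"), ("SMS2", "om"), ("SMSn", "nuc"), ("SMSr", "er"),
    ("aSMase_pm", "om"), ("aSMase_ly", "lys"),
    ("nSMase1", "er"), ("nSMase2", "im"), ("nSMase_n", "nuc"),
    ("GCS", "gc"), ("FAPP2", "gc"), ("GBA", "lys"), ("GBA2", "im"),
    ("aCDase", "lys"), ("CDase_m", "mito"), ("nCDase", "om"),
    ("alkCDase", "gc"), ("CDase_n", "nuc"),
    ("CerS_r", "er"), ("CerS_m", "mito"), ("CerS_n", "nuc"),
    ("SK1", "im"), ("SK2", "cyt"),
    ("SPP1", "er"), ("SPP2", "nuc"), ("PAP2a", "gc"), ("PAP2b", "im"),
    ("CERK", "gc"), ("PAP2c", "im"), ("SPL1", "er"),
    ("CERT", "er"), ("VTC", "er"), ("EXO", "gl"), ("END", "om"),
    ("SCRM", "om"), ("CPTP", "cyt"), ("MCS", "cyt"),
]

# reaction table: (id, kind, substrate, product, enzyme, preferred flux)
#   kind: "mal" (mass action) or "mm" (Michaelis-Menten)
#   substrate/product None encodes inflow/outflow
#   preferred flux seeds the stationary flux-balance program; inflow rates
#   (the _INFLOWS set) are pinned exactly.
_R = [
    # -- boundary inflows / outflows (mass action) -------------------------
    ("in_cer_om",  "mal", None, "CER_om", None, 1.0),
    ("in_sm_om",   "mal", None, "SM_om",  None, 6.0),
    ("in_sph_om",  "mal", None, "Sph_om", None, 0.8),
    ("in_s1p_om",  "mal", None, "S1P_om", None, 0.4),
    ("in_c1p_om",  "mal", None, "C1P_om", None, 0.5),
    ("denovo_cer_er", "mal", None, "CER_er", None, 2.0),
    ("out_sph_om", "mal", "Sph_om", None, None, 4.9),
    ("out_s1p_om", "mal", "S1P_om", None, None, 0.5),
    ("out_c1p_om", "mal", "C1P_om", None, None, 0.8),
    # -- free transport (mass action) --------------------------------------
    ("flip_cer_im_om", "mal", "CER_im", "CER_om", None, 0.7),
    ("flip_sph_om_im", "mal", "Sph_om", "Sph_im", None, 0.3),
    ("flip_sph_im_om", "mal", "Sph_im", "Sph_om", None, 0.2),
    ("diff_cer_er_nuc", "mal", "CER_er", "CER_nuc", None, 0.5),
    ("diff_cer_nuc_er", "mal", "CER_nuc", "CER_er", None, 0.5),
    # -- sphingomyelin synthesis -------------------------------------------
    ("sms1_gl",  "mm", "CER_gl", "SM_gl", "SMS1", 0.1),
    ("sms2_om",  "mm", "CER_om", "SM_om", "SMS2", 2.5),
    ("smsn_nuc", "mm", "CER_nuc", "SM_nuc", "SMSn", 0.1),
    ("smsr_er",  "mm", "CER_er", "SM_er", "SMSr", 1.0),
    # -- sphingomyelin hydrolysis ------------------------------------------
    ("asmase_om",  "mm", "SM_om", "CER_om", "aSMase_pm", 5.0),
    ("nsmase_im",  "mm", "SM_im", "CER_im", "nSMase2", 0.6),
    ("nsmase_er",  "mm", "SM_er", "CER_er", "nSMase1", 1.0),
    ("nsmase_nuc", "mm", "SM_nuc", "CER_nuc", "nSMase_n", 0.1),
    ("asmase_lys", "mm", "SM_lys", "CER_lys", "aSMase_ly", 3.0),
    # -- glycosphingolipid branch ------------------------------------------
    ("gcs_gc",      "mm", "CER_gc", "GSL_gc", "GCS", 0.7),
    ("fapp2_gc_gl", "mm", "GSL_gc", "GSL_gl", "FAPP2", 0.7),
    ("fapp2_om_im", "mm", "GSL_om", "GSL_im", "FAPP2", 0.1),
    ("gba_lys",     "mm", "GSL_lys", "CER_lys", "GBA", 0.8),
    ("gba2_im",     "mm", "GSL_im", "CER_im", "GBA2", 0.1),
    # -- ceramidases --------------------------------------------------------
    ("acdase_lys", "mm", "CER_lys", "Sph_lys", "aCDase", 3.6),
    ("cdase_mito", "mm", "CER_mito", "Sph_mito", "CDase_m", 3.0),
    ("ncdase_om",  "mm", "CER_om", "Sph_om", "nCDase", 4.2),
    ("alkcdase_gc", "mm", "CER_gc", "Sph_gc", "alkCDase", 0.2),
    ("alkcdase_er", "mm", "CER_er", "Sph_er", "alkCDase", 1.5),
    ("cdase_nuc",  "mm", "CER_nuc", "Sph_nuc", "CDase_n", 0.05),
    # -- ceramide synthases (salvage re-acylation) -------------------------
    ("cers_er",   "mm", "Sph_er", "CER_er", "CerS_r", 0.8),
    ("cers_mito", "mm", "Sph_mito", "CER_mito", "CerS_m", 3.0),
    ("cers_nuc",  "mm", "Sph_nuc", "CER_nuc", "CerS_n", 0.05),
    # -- sphingosine kinases ------------------------------------------------
    ("sk1_im",   "mm", "Sph_im", "S1P_im", "SK1", 0.15),
    ("sk1_gc",   "mm", "Sph_gc", "S1P_gc", "SK1", 0.05),
    ("sk2_cyt",  "mm", "Sph_cyt", "S1P_cyt", "SK2", 3.8),
    ("sk2_nuc",  "mm", "Sph_nuc", "S1P_nuc", "SK2", 0.05),
    ("sk2_mito", "mm", "Sph_mito", "S1P_mito", "SK2", 0.05),
    ("sk2_er",   "mm", "Sph_er", "S1P_er", "SK2", 0.75),
    # -- S1P phosphatases ---------------------------------------------------
    ("spp1_er",   "mm", "S1P_er", "Sph_er", "SPP1", 0.05),
    ("spp2_nuc",  "mm", "S1P_nuc", "Sph_nuc", "SPP2", 0.05),
    ("spp2_mito", "mm", "S1P_mito", "Sph_mito", "SPP2", 0.05),
    ("pap2a_gc",  "mm", "S1P_gc", "Sph_gc", "PAP2a", 0.05),
    ("pap2b_im",  "mm", "S1P_im", "Sph_im", "PAP2b", 0.05),
    # -- ceramide kinase / C1P phosphatase ---------------------------------
    ("cerk_gc", "mm", "CER_gc", "C1P_gc", "CERK", 0.3),
    ("cerk_im", "mm", "CER_im", "C1P_im", "CERK", 0.05),
    ("cerk_gl", "mm", "CER_gl", "C1P_gl", "CERK", 0.05),
    ("pap2c_im", "mm", "C1P_im", "CER_im", "PAP2c", 0.05),
    ("pap2c_gl", "mm", "C1P_gl", "CER_gl", "PAP2c", 0.05),
    # -- S1P lyase (irreversible exit) -------------------------------------
    ("spl1_er", "mm", "S1P_er", None, "SPL1", 4.5),
    # -- protein- and vesicle-mediated transport ---------------------------
    ("cert_er_gl", "mm", "CER_er", "CER_gl", "CERT", 0.1),
    ("vtc_er_gc",  "mm", "CER_er", "CER_gc", "VTC", 1.2),
    ("exo_sm_gl_om",  "mm", "SM_gl", "SM_om", "EXO", 0.1),
    ("exo_gsl_gl_om", "mm", "GSL_gl", "GSL_om", "EXO", 0.7),
    ("end_sm_om_lys",  "mm", "SM_om", "SM_lys", "END", 3.0),
    ("end_gsl_om_lys", "mm", "GSL_om", "GSL_lys", "END", 0.8),
    ("scrm_sm_om_im", "mm", "SM_om", "SM_im", "SCRM", 0.6),
    ("cptp_cyt_om", "mm", "C1P_cyt", "C1P_om", "CPTP", 0.3),
    # -- monomeric exchange at membrane contact sites ----------------------
    ("mcs_s1p_im_om", "mm", "S1P_im", "S1P_om", "MCS", 0.1),
    ("mcs_s1p_cyt_er", "mm", "S1P_cyt", "S1P_er", "MCS", 3.8),
    ("mcs_c1p_gc_cyt", "mm", "C1P_gc", "C1P_cyt", "MCS", 0.3),
    ("mcs_sph_gc_cyt", "mm", "Sph_gc", "Sph_cyt", "MCS", 0.2),
    ("mcs_sph_cyt_mito", "mm", "Sph_cyt", "Sph_mito", "MCS", 0.05),
    ("mcs_sph_mito_cyt", "mm", "Sph_mito", "Sph_cyt", "MCS", 0.05),
    ("mcs_sph_lys_cyt", "mm", "Sph_lys", "Sph_cyt", "MCS", 3.6),
]

_INFLOWS = {"in_cer_om", "in_sm_om", "in_sph_om", "in_s1p_om", "in_c1p_om",
            "denovo_cer_er"}

#: non-competitive inhibition: reaction -> [(inhibitor species, Ki / [I]0)]
_INHIBITION = {
    "denovo_cer_er": [("S1P_er", 40.0), ("C1P_cyt", 40.0)],   # SPT surrogate
    "asmase_om": [("S1P_om", 50.0)],
    "asmase_lys": [("S1P_cyt", 100.0), ("C1P_cyt", 100.0)],
}

#: saturation [S]0/(Km+[S]0) at the operating point.  Sphingomyelinases and
#: the endocytic SM/GSL route run near saturation (little spare capacity),
#: ceramidases far below it (large spare capacity); everything else is
#: half-saturated.
_SAT_DEFAULT = 0.5
_SAT_OVERRIDE = {
    "asmase_om": 0.9, "nsmase_im": 0.9, "nsmase_er": 0.9, "nsmase_nuc": 0.9,
    "asmase_lys": 0.98,
    "end_sm_om_lys": 0.8, "scrm_sm_om_im": 0.9,
    "ncdase_om": 0.35,
    "acdase_lys": 0.2, "cdase_mito": 0.2,
    "alkcdase_gc": 0.2, "alkcdase_er": 0.2, "cdase_nuc": 0.2,
}

_TRANSPORT_PREFIXES = (
    "in", "out", "flip", "diff", "cert", "vtc", "exo", "end", "scrm",
    "cptp", "mcs",
)


def _balanced_fluxes(M: np.ndarray) -> np.ndarray:
    """Strictly positive flux vector with M v = 0 (stationary by construction).

    Inflow fluxes are pinned to their stated magnitudes; every other flux is
    kept as close as possible (L1) to its preferred pathway magnitude, with a
    floor so no reaction is dead at the operating point.  The linear program
    is deterministic, so the parameterization is reproducible.
    """
    n = len(_R)
    pref = np.array([row[5] for row in _R])
    lo = np.array([row[5] if row[0] in _INFLOWS else 0.02 for row in _R])
    hi = np.array([row[5] if row[0] in _INFLOWS else 50.0 for row in _R])
    # v = pref + e_plus - e_minus; minimize sum(e_plus + e_minus)
    A_eq = np.hstack([M.astype(float), -M.astype(float)])
    b_eq = -M.astype(float) @ pref
    bounds = [(0.0, float(h - p)) for p, h in zip(pref, hi)]
    bounds += [(0.0, float(p - l)) for p, l in zip(pref, lo)]
    res = linprog(c=np.ones(2 * n), A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise AssemblyError(f"no balanced flux distribution: {res.message}")
    v = pref + res.x[:n] - res.x[n:]
    if np.any(v <= 0):
        raise AssemblyError("flux balance produced a non-positive flux")
    return v


def build_homeostasis_model() -> ReactionNetwork:
    """Assemble the nine-compartment homeostasis model.

    Raises :class:`AssemblyError` if the assembled inventory deviates from
    the declared counts (39 species, 69 reactions, 9 compartments, 37
    enzymes, 129 parameters, 38 explicit initial concentrations).
    """
    compartments = [Compartment(cid, name) for cid, name in COMPARTMENTS]
    species = []
    for sid, comp, level in SPECIES_LEVELS:
        explicit = level is not None
        species.append(
            Species(
                sid,
                compartment=comp,
                initial_concentration=level if explicit else GSL_DEFAULT_LEVEL,
                initial_explicit=explicit,
            )
        )
    species += [
        Species(eid, compartment=comp, initial_concentration=1.0, is_enzyme=True)
        for eid, comp in ENZYMES
    ]
    conc0 = {s.id: s.initial_concentration for s in species}

    # first pass with unit rates to obtain the stoichiometry matrix
    reactions = [_make_reaction(row, conc0, flux=None) for row in _R]
    probe = ReactionNetwork(compartments, species, reactions, {"scenario": "probe"})
    v = _balanced_fluxes(stoichiometry_matrix(probe))
    reactions = [_make_reaction(row, conc0, flux=v[j]) for j, row in enumerate(_R)]

    net = ReactionNetwork(
        compartments,
        species,
        reactions,
        metadata={
            "scenario": "homeostasis",
            "flux_distribution": {row[0]: float(v[j]) for j, row in enumerate(_R)},
        },
    )
    _check_counts(net)
    return net


def _make_reaction(row, conc0, flux):
    rid, kind, sub, prod, enz, _pref = row
    substrates = [(sub, 1)] if sub else []
    products = [(prod, 1)] if prod else []
    modifiers = [enz] if enz else []
    inhibitors = [
        (isid, factor * conc0[isid]) for isid, factor in _INHIBITION.get(rid, [])
    ]
    inh_scale = float(np.prod([1 + conc0[isid] / ki for isid, ki in inhibitors])) if inhibitors else 1.0
    v = 1.0 if flux is None else float(flux)
    if kind == "mal":
        base = v / (conc0[sub] if sub else 1.0)
        law = KineticLaw(LawForm.MASS_ACTION, {"k": base * inh_scale}, inhibitors=inhibitors)
    else:
        s0 = conc0[sub]
        sat = _SAT_OVERRIDE.get(rid, _SAT_DEFAULT)
        km = s0 * (1 - sat) / sat
        vmax = v / sat * inh_scale
        form = LawForm.MM_INHIBITED if inhibitors else LawForm.MICHAELIS_MENTEN
        law = KineticLaw(form, {"Vmax": vmax, "Km": km}, inhibitors=inhibitors)
    return Reaction(
        rid,
        substrates=substrates,
        products=products,
        modifiers=modifiers,
        law=law,
        is_transport=rid.split("_")[0] in _TRANSPORT_PREFIXES,
    )


def _check_counts(net: ReactionNetwork) -> None:
    got = {
        "compartments": len(net.compartments),
        "species": len(net.dynamic_species),
        "reactions": len(net.reactions),
        "enzymes": len(net.enzymes),
        "parameters": len(net.parameter_registry()),
        "explicit_initials": sum(1 for s in net.dynamic_species if s.initial_explicit),
    }
    diff = {k: (got[k], v) for k, v in EXPECTED_COUNTS.items() if got[k] != v}
    if diff:
        raise AssemblyError(
            "assembled model deviates from the declared inventory: "
            + ", ".join(f"{k}: got {g}, expected {e}" for k, (g, e) in diff.items())
        )


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class ScenarioPatch:
    """Named set of parameter edits: ``(registry key, op, value, note)``.

    ``op`` is ``"mul"`` (multiply the current value) or ``"set"`` (absolute).
    """

    label: str
    entries: list[tuple[str, str, float, str]] = field(default_factory=list)

    def add(self, key: str, op: str, value: float, note: str = "") -> None:
        if op not in ("mul", "set"):
            raise ValueError(f"unknown op {op!r}")
        if value <= 0:
            raise ValueError("patch values must be positive")
        self.entries.append((key, op, value, note))

    def multipliers(self) -> dict[str, float]:
        return {k: v for k, op, v, _ in self.entries if op == "mul"}

    def to_text(self) -> str:
        lines = [f"# scenario: {self.label}"]
        for key, op, value, note in self.entries:
            lines.append(f"{key}\t{op}\t{value:g}\t{note}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScenarioPatch":
        patch = cls("scenario")
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "scenario:" in line:
                    patch.label = line.split("scenario:", 1)[1].strip()
                continue
            key, op, value, *rest = line.split("\t")
            patch.add(key, op, float(value), rest[0] if rest else "")
        return patch


def apply_scenario(net: ReactionNetwork, patch: ScenarioPatch) -> ReactionNetwork:
    """Return a patched copy of the network; the original is untouched."""
    out = net.copy()
    registry = out.parameter_registry()
    for key, op, value, _ in patch.entries:
        if key not in registry:
            raise NetworkError(f"scenario {patch.label!r}: unknown parameter {key!r}")
        out.set_parameter(key, value if op == "set" else registry[key] * value)
        registry = out.parameter_registry()
    out.metadata = dict(out.metadata)
    out.metadata["scenario"] = patch.label
    out.metadata.setdefault("patches", []).append(
        {"label": patch.label, "entries": list(patch.entries)}
    )
    return out


#: reaction groups touched by the disease scenario
_CDASE_RX = ["acdase_lys", "cdase_mito", "ncdase_om", "alkcdase_gc",
             "alkcdase_er", "cdase_nuc"]
_SK_RX = ["sk1_im", "sk1_gc", "sk2_cyt", "sk2_nuc", "sk2_mito", "sk2_er"]
_CERK_RX = ["cerk_gc", "cerk_im", "cerk_gl"]
_SMASE_RX = ["asmase_om", "nsmase_im", "nsmase_er", "nsmase_nuc", "asmase_lys"]


def ad_scenario(corrected: bool = True) -> ScenarioPatch:
    """The Alzheimer's-disease perturbation.

    The core set down-regulates ceramidase activity, slows the sphingosine
    and ceramide kinases, inhibits CERT-mediated ER-to-Golgi ceramide
    transport and up-regulates de novo ceramide synthesis.  On its own this
    set overruns the near-saturated sphingomyelin hydrolysis capacity and SM
    grows without bound; ``corrected=True`` adds the stabilizing
    modifications -- reduced CERT-independent (vesicular) ER-to-Golgi
    ceramide transport, increased sphingomyelinase activity and minor
    adjustments of SM/GSL transport between compartments.  All magnitudes
    are documented placeholders (the published direction of change with
    round factors).
    """
    patch = ScenarioPatch("AD" if corrected else "AD-uncorrected")
    for rid in _CDASE_RX:
        patch.add(f"{rid}.Vmax", "mul", 0.5, "ceramidase down-regulation")
    for rid in _SK_RX:
        patch.add(f"{rid}.Vmax", "mul", 0.5, "sphingosine kinase slow-down")
    for rid in _CERK_RX:
        patch.add(f"{rid}.Vmax", "mul", 0.5, "ceramide kinase slow-down")
    patch.add("cert_er_gl.Vmax", "mul", 0.1, "CERT down-regulation")
    patch.add("denovo_cer_er.k", "mul", 1.15, "de novo ceramide synthesis up-regulated")
    if corrected:
        patch.add("vtc_er_gc.Vmax", "mul", 0.8,
                  "reduced CERT-independent ER->Golgi CER transport")
        for rid in _SMASE_RX:
            patch.add(f"{rid}.Vmax", "mul", 2.0, "increased sphingomyelinase activity")
        patch.add("scrm_sm_om_im.Vmax", "mul", 0.8, "minor SM transport adjustment")
    return patch


def build_ad_model(corrected: bool = True) -> ReactionNetwork:
    """Homeostasis model with the disease patch applied."""
    return apply_scenario(build_homeostasis_model(), ad_scenario(corrected=corrected))
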