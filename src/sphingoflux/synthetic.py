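"""Synthetic toy networks with known analytic behavior.

These fixtures make every pipeline stage testable against closed-form or
brute-force oracles: the linear birth-death process (Poisson stationary law),
the open linear chain (product-Poisson stationary law), a structurally
non-identifiable parameter pair, and random mass-action/Michaelis-Menten
networks with guaranteed inflow/outflow.
"""

from __future__ import annotations

import numpy as np

from .network import (
    Compartment,
    KineticLaw,
    LawForm,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
)

__all__ = [
    "make_birth_death",
    "make_linear_chain",
    "make_redundant_pair",
    "make_random_network",
]

_CELL = Compartment("cell", "toy cell", 1.0)


def make_birth_death(k1: float = 10.0, k2: float = 1.0) -> ReactionNetwork:
    """Birth-death process ``0 -> X`` (rate k1), ``X -> 0`` (rate k2*x).

    Stationary mean and LNA variance are both ``k1/k2`` (Poisson law).
    """
    if not (k1 > 0 and k2 > 0):
        raise NetworkError("rates must be positive")
    return ReactionNetwork(
        compartments=[Compartment("cell")],
        species=[Species("X", compartment="cell", initial_concentration=0.0)],
        reactions=[
            Reaction("birth", products=[("X", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": k1})),
            Reaction("death", substrates=[("X", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": k2})),
        ],
        metadata={"scenario": "birth_death", "k1": k1, "k2": k2},
    )


def make_linear_chain(k0: float = 4.0, k1: float = 2.0, k2: float = 1.0) -> ReactionNetwork:
    """Open chain ``0 -> A -> B -> 0`` with rates ``k0``, ``k1*a``, ``k2*b``.

    Stationary state is ``(k0/k1, k0/k2)``; the stationary LNA covariance is
    ``diag(k0/k1, k0/k2)`` with zero cross-covariance (product-Poisson law of
    open first-order networks).
    """
    if not (k0 > 0 and k1 > 0 and k2 > 0):
        raise NetworkError("rates must be positive")
    return ReactionNetwork(
        compartments=[Compartment("cell")],
        species=[
            Species("A", compartment="cell", initial_concentration=0.0),
            Species("B", compartment="cell", initial_concentration=0.0),
        ],
        reactions=[
            Reaction("influx", products=[("A", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": k0})),
            Reaction("convert", substrates=[("A", 1)], products=[("B", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": k1})),
            Reaction("efflux", substrates=[("B", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": k2})),
        ],
        metadata={"scenario": "linear_chain", "k0": k0, "k1": k1, "k2": k2},
    )


def make_redundant_pair(ka: float = 2.0, kb: float = 3.0, kd: float = 1.0) -> ReactionNetwork:
    """One species fed by a flux proportional to ``ka*kb`` and degraded at ``kd``.

    Because the two production parameters enter only through their product,
    their log-scale sensitivity columns are identical: the Fisher information
    matrix is rank-deficient on the pair and the canonical correlation between
    them is exactly 1, so both fail the identifiability test for any delta > 0.
    The decay parameter remains identifiable.
    """
    return ReactionNetwork(
        compartments=[Compartment("cell")],
        species=[Species("X", compartment="cell", initial_concentration=0.0)],
        reactions=[
            Reaction(
                "prod",
                products=[("X", 1)],
                law=KineticLaw(
                    LawForm.OPAQUE, {"ka": ka, "kb": kb}, expression="ka*kb"
                ),
            ),
            Reaction("decay", substrates=[("X", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": kd})),
        ],
        metadata={"scenario": "redundant_pair"},
    )


def make_random_network(
    n_species: int,
    n_reactions: int,
    mm_fraction: float = 0.5,
    seed: int = 0,
    max_tries: int = 50,
) -> ReactionNetwork:
    """Random connected open network with a finite stable stationary state.

    A linear inflow -> chain -> outflow backbone guarantees connectivity and a
    flow-through; extra reactions are random first-order conversions, a
    ``mm_fraction`` of which use saturating MM kinetics with bounded
    ``Vmax/Km`` so the drift matrix stays Hurwitz with high probability.
    Draws whose linearization at the stationary state is not Hurwitz are
    rejected and re-sampled (the number of rejections is recorded in the
    network metadata).
    """
    if n_species < 1 or n_reactions < n_species + 1:
        raise NetworkError(
            f"need n_reactions >= n_species+1 (got {n_species}, {n_reactions})"
        )
    if not 0 <= mm_fraction <= 1:
        raise NetworkError("mm_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        net = _draw_random(n_species, n_reactions, mm_fraction, rng, seed, attempt)
        if _is_stable(net):
            net.metadata["rejected_draws"] = attempt
            return net
    raise NetworkError(f"no stable draw in {max_tries} tries for seed {seed}")


def _draw_random(n_species, n_reactions, mm_fraction, rng, seed, attempt):
    species = [
        Species(f"S{i}", compartment="cell",
                initial_concentration=float(rng.uniform(0.5, 2.0)))
        for i in range(n_species)
    ]
    reactions = [
        Reaction("influx", products=[("S0", 1)],
                 law=KineticLaw(LawForm.MASS_ACTION, {"k": float(rng.uniform(1, 5))}))
    ]
    # chain backbone S0 -> S1 -> ... -> S(n-1) -> outside
    for i in range(n_species - 1):
        reactions.append(
            Reaction(
                f"conv{i}",
                substrates=[(f"S{i}", 1)],
                products=[(f"S{i+1}", 1)],
                law=KineticLaw(LawForm.MASS_ACTION, {"k": float(rng.uniform(0.5, 2))}),
            )
        )
    reactions.append(
        Reaction(
            "efflux",
            substrates=[(f"S{n_species-1}", 1)],
            law=KineticLaw(LawForm.MASS_ACTION, {"k": float(rng.uniform(0.5, 2))}),
        )
    )
    idx = 0
    while len(reactions) < n_reactions:
        i, j = rng.choice(n_species, size=2, replace=False)
        if rng.uniform() < mm_fraction:
            km = float(rng.uniform(0.5, 3.0))
            law = KineticLaw(
                LawForm.MICHAELIS_MENTEN,
                # bounded Vmax/Km keeps the linearized drift well conditioned
                {"Vmax": float(rng.uniform(0.2, 1.0) * km), "Km": km},
            )
        else:
            law = KineticLaw(LawForm.MASS_ACTION, {"k": float(rng.uniform(0.1, 0.8))})
        reactions.append(
            Reaction(f"extra{idx}", substrates=[(f"S{i}", 1)],
                     products=[(f"S{j}", 1)], law=law)
        )
        idx += 1
    return ReactionNetwork(
        compartments=[Compartment("cell")],
        species=species,
        reactions=reactions,
        metadata={"scenario": f"random_mal_mm(seed={seed})"},
    )


def _is_stable(net: ReactionNetwork) -> bool:
    from .dynamics import find_stationary_state

    try:
        ss = find_stationary_state(net, net.initial_state())
    except Exception:
        return False
    A = net.compiled().rhs_jac_x(ss.state)
    return bool(np.all(np.linalg.eigvals(A).real < -1e-12))
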