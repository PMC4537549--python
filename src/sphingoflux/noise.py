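"""Linear Noise Approximation and per-reaction variance decomposition.

At a stationary state ``Phi`` the LNA covariance solves the Lyapunov equation
``A Sigma + Sigma A^T + D = 0`` with drift ``A_ik = sum_j m_ij df_j/dPhi_k``
and diffusion ``D = sum_j D^(j)``, ``D^(j) = f_j(Phi) m_j m_j^T``.  Because
the equation is linear in ``D``, the covariance splits additively into
per-reaction components ``Sigma^(j)`` solving the same equation with
``D^(j)``; the diagonal of each component attributes a share of every
species' variance to one reaction.  A species' component is flagged when it
exceeds 110 % of the mean component of that species over all reactions.

The unit-volume convention of the network module makes the concentration- and
copy-number-scale LNA identical; absolute variance magnitudes therefore
depend on that convention, while the flag pattern does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_continuous_lyapunov

from .network import ReactionNetwork

__all__ = [
    "LnaOperators",
    "VarianceDecomposition",
    "lna_operators",
    "stationary_covariance",
    "decompose_variance",
    "flag_components",
    "plot_components",
]

THRESHOLD_FACTOR = 1.1  # flag components above 110 % of the species mean

ADDITIVITY_RTOL = 1e-8


class StabilityError(RuntimeError):
    """The drift matrix is not Hurwitz: no stable stationary fluctuation law."""


@dataclass
class LnaOperators:
    A: np.ndarray  # drift, N x N
    D: np.ndarray  # total diffusion, N x N
    D_components: list[np.ndarray]  # one rank-<=1 PSD matrix per reaction
    phi: np.ndarray
    species_ids: list[str]
    reaction_ids: list[str]


@dataclass
class VarianceDecomposition:
    total: np.ndarray  # stationary covariance Sigma
    components: list[np.ndarray]  # Sigma^(j) per reaction
    species_ids: list[str]
    reaction_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def component_table(self) -> pd.DataFrame:
        """Per-species variance components: rows species, columns reactions."""
        data = np.column_stack([np.diag(c) for c in self.components])
        return pd.DataFrame(data, index=self.species_ids, columns=self.reaction_ids)


def lna_operators(net: ReactionNetwork, phi: np.ndarray) -> LnaOperators:
    """Drift and (decomposed) diffusion matrices evaluated at ``phi``."""
    compiled = net.compiled()
    phi = np.asarray(phi, dtype=float)
    fluxes = compiled.flux(phi)
    A = compiled.M @ compiled.flux_jac_x(phi)
    components = []
    for j, f in enumerate(fluxes):
        m = compiled.M[:, j].astype(float)
        components.append(max(f, 0.0) * np.outer(m, m))
    D = np.sum(components, axis=0)
    return LnaOperators(
        A=A,
        D=D,
        D_components=components,
        phi=phi,
        species_ids=[s.id for s in net.dynamic_species],
        reaction_ids=[r.id for r in net.reactions],
    )


def _solve_stationary(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    sigma = solve_continuous_lyapunov(A, -D)
    return 0.5 * (sigma + sigma.T)  # symmetrize against roundoff


def _check_hurwitz(A: np.ndarray) -> None:
    eigs = np.linalg.eigvals(A)
    if np.any(eigs.real >= 0):
        raise StabilityError(
            "no stable stationary state: drift eigenvalue with non-negative real part "
            f"(max Re = {eigs.real.max():.3e})"
        )


def stationary_covariance(ops: LnaOperators) -> np.ndarray:
    """Solve ``A Sigma + Sigma A^T + D = 0`` for the stationary covariance."""
    _check_hurwitz(ops.A)
    return _solve_stationary(ops.A, ops.D)


def decompose_variance(ops: LnaOperators) -> VarianceDecomposition:
    """Per-reaction covariance components summing to the total covariance."""
    _check_hurwitz(ops.A)
    components = [_solve_stationary(ops.A, Dj) for Dj in ops.D_components]
    total = _solve_stationary(ops.A, ops.D)
    gap = np.linalg.norm(total - np.sum(components, axis=0))
    scale = max(np.linalg.norm(total), 1e-300)
    if gap > 1e-6 * scale:  # additivity is exact up to linear-solver roundoff
        raise RuntimeError(f"component additivity violated: {gap / scale:.3e} relative")
    return VarianceDecomposition(
        total=total,
        components=components,
        species_ids=ops.species_ids,
        reaction_ids=ops.reaction_ids,
        metadata={"additivity_gap_rel": float(gap / scale)},
    )


def flag_components(decomp: VarianceDecomposition) -> pd.DataFrame:
    """Tidy flag table: one row per (species, reaction) variance component.

    The threshold for each species is ``THRESHOLD_FACTOR`` times the mean of
    its components over all reactions.
    """
    table = decomp.component_table()
    rows = []
    for sid in table.index:
        comps = table.loc[sid]
        mean = float(comps.mean())
        threshold = THRESHOLD_FACTOR * mean
        for rid in table.columns:
            value = float(comps[rid])
            rows.append(
                {
                    "species": sid,
                    "reaction": rid,
                    "component": value,
                    "mean_component": mean,
                    "threshold": threshold,
                    "flagged": value > threshold,
                }
            )
    return pd.DataFrame(rows)


def plot_components(decomp: VarianceDecomposition, species: list[str] | None = None, path=None):
    """Bar plot of per-reaction variance components, one panel per species.

    Flagged components (above 110 % of the species mean, red line) are drawn
    in red.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = decomp.component_table()
    species = list(species or table.index)
    fig, axes = plt.subplots(len(species), 1, figsize=(8, 2.2 * len(species)), squeeze=False)
    for ax, sid in zip(axes.ravel(), species):
        comps = table.loc[sid].to_numpy()
        mean = comps.mean()
        colors = ["red" if c > THRESHOLD_FACTOR * mean else "steelblue" for c in comps]
        ax.bar(np.arange(comps.size), comps, color=colors)
        ax.axhline(mean, color="red", lw=1)
        ax.set_ylabel(sid, fontsize=8)
    axes.ravel()[-1].set_xlabel("reaction index")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
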