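"""Fisher information, functional redundancy and parameter clustering.

The Fisher information matrix (FIM) at a reference parameter point is built
from forward sensitivities of the observed species on a design time grid,
``FIM = sum_t S(t)^T S(t)`` with unit observation noise, in either raw or
log-parameter scale.  The functional redundancy between two disjoint
parameter blocks A and B is

    I(A, B) = -1/2 * sum_j ln(1 - rho_j^2)

over the canonical correlations ``rho_j`` of the two blocks under the FIM
inner product (for jointly Gaussian parameters with covariance FIM^-1 this is
exactly the Gaussian mutual information between the blocks, in nats).
A parameter is (delta, zeta)-identifiable when its FIM diagonal exceeds
``zeta`` and its multiple (canonical) correlation with all remaining
parameters stays below ``1 - delta``.

Clustering proceeds agglomeratively: starting from identifiable singletons,
each turn merges the pair of current sets with the largest redundancy and
re-applies the identifiability filter to the remaining parameters; a pair of
perfectly confounded parameters has redundancy +inf and is ordered above
every finite height.  The dendrogram is cut at the largest relative gap
between consecutive merge heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork
from .sensitivity import forward_sensitivities

__all__ = [
    "FisherInformation",
    "RedundancyTree",
    "fisher_information",
    "canonical_correlations",
    "functional_redundancy",
    "identifiability_filter",
    "cluster_parameters",
]

#: canonical correlations closer to 1 than this are treated as exactly 1
RHO_ONE_TOL = 1e-12

#: relative eigenvalue cutoff for pseudo-inversion of rank-deficient blocks
PINV_RTOL = 1e-12


@dataclass
class FisherInformation:
    matrix: np.ndarray
    param_names: list[str]
    theta: np.ndarray
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.param_names),) * 2:
            raise ValueError("FIM dimensions do not match parameter count")
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise ValueError("FIM must be symmetric")

    def index(self, names: list[str]) -> list[int]:
        lookup = {n: i for i, n in enumerate(self.param_names)}
        return [lookup[n] for n in names]


def fisher_information(
    net: ReactionNetwork,
    x0: np.ndarray | None = None,
    theta: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    observed: list[str] | None = None,
    scale: str = "log",
    normalize: bool = True,
    horizon: float = 50.0,
    n_points: int = 50,
) -> FisherInformation:
    """FIM from forward sensitivities with unit observation noise.

    Default design: all non-enzyme species observed on ``n_points``
    log-spaced times up to ``horizon``, log-parameter scale, matrix divided
    by its largest diagonal entry so identifiability thresholds are
    scale-free.
    """
    if grid is None:
        grid = np.concatenate([[0.0], np.geomspace(horizon / 1e3, horizon, n_points)])
    sens = forward_sensitivities(net, x0=x0, theta0=theta, grid=grid)
    if scale == "log":
        sens = sens.normalized()
    elif scale != "raw":
        raise ValueError(f"unknown parameter scale {scale!r}")
    derivs = sens.derivatives
    if observed is not None:
        keep = [sens.species_ids.index(s) for s in observed]
        derivs = derivs[:, keep, :]
    fim = np.einsum("tnl,tnm->lm", derivs, derivs)
    fim = 0.5 * (fim + fim.T)
    if normalize:
        top = fim.diagonal().max()
        if top > 0:
            fim = fim / top
    return FisherInformation(
        matrix=fim,
        param_names=sens.param_names,
        theta=sens.theta0,
        design={
            "grid": np.asarray(grid),
            "observed": observed,
            "scale": scale,
            "normalized": normalize,
        },
    )


def _pinv_sqrt(block: np.ndarray) -> np.ndarray:
    """Symmetric pseudo-inverse square root with relative eigenvalue cutoff."""
    w, V = np.linalg.eigh(block)
    cut = PINV_RTOL * max(w.max(initial=0.0), 0.0)
    inv_sqrt = np.where(w > cut, 1.0 / np.sqrt(np.clip(w, cut, None)), 0.0)
    return (V * inv_sqrt) @ V.T


def canonical_correlations(
    fim: FisherInformation | np.ndarray,
    set_a: list[int],
    set_b: list[int],
) -> np.ndarray:
    """Canonical correlations of two disjoint index blocks, descending in [0, 1]."""
    F = fim.matrix if isinstance(fim, FisherInformation) else np.asarray(fim)
    a = list(set_a)
    b = list(set_b)
    if not a or not b:
        raise ValueError("both parameter sets must be non-empty")
    if set(a) & set(b):
        raise ValueError("parameter sets must be disjoint")
    Faa = F[np.ix_(a, a)]
    Fbb = F[np.ix_(b, b)]
    Fab = F[np.ix_(a, b)]
    core = _pinv_sqrt(Faa) @ Fab @ _pinv_sqrt(Fbb)
    svals = np.linalg.svd(core, compute_uv=False)
    rho = np.clip(svals, 0.0, 1.0)
    k = min(len(a), len(b))
    out = np.zeros(k)
    out[: min(k, rho.size)] = np.sort(rho)[::-1][:k]
    return out


def functional_redundancy(
    fim: FisherInformation | np.ndarray,
    set_a: list[int],
    set_b: list[int],
) -> float:
    """``-1/2 sum ln(1 - rho_j^2)`` in nats; +inf when any rho equals 1."""
    rho = canonical_correlations(fim, set_a, set_b)
    if np.any(rho >= 1.0 - RHO_ONE_TOL):
        return math.inf
    return float(-0.5 * np.sum(np.log1p(-rho**2)))


def identifiability_filter(
    fim: FisherInformation,
    delta: float = 0.01,
    zeta: float = 1e-6,
    subset: list[int] | None = None,
) -> tuple[list[int], list[tuple[int, str]]]:
    """(delta, zeta)-identifiability over ``subset`` (default: all parameters).

    A parameter passes when its FIM diagonal exceeds ``zeta`` and the single
    canonical correlation between it and the remaining subset parameters is
    below ``1 - delta``.  Returns (identifiable indices, removed
    [(index, failed test)]).
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if zeta <= 0:
        raise ValueError("zeta must be > 0")
    idx = list(range(len(fim.param_names))) if subset is None else list(subset)
    keep: list[int] = []
    removed: list[tuple[int, str]] = []
    diag = fim.matrix.diagonal()
    for i in idx:
        if diag[i] <= zeta:
            removed.append((i, "zeta"))
            continue
        others = [j for j in idx if j != i]
        if others:
            rho = canonical_correlations(fim, [i], others)[0]
            if rho >= 1 - delta:
                removed.append((i, "delta"))
                continue
        keep.append(i)
    return keep, removed


@dataclass
class RedundancyTree:
    """Merge history with heights, removals and the final cluster cut."""

    param_names: list[str]
    merges: list[tuple[int, frozenset, frozenset, float]]
    removed: list[tuple[str, int, str]]  # (param, step, reason)
    clusters: list[set[str]]
    delta: float
    zeta: float
    cut_height: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def removed_params(self) -> list[str]:
        return [name for name, _, _ in self.removed]

    def to_newick(self) -> str:
        """Dendrogram over the identifiable parameters, heights as branch lengths."""
        node: dict[frozenset, str] = {}
        height_of: dict[frozenset, float] = {}
        for step, a, b, h in self.merges:
            for part in (a, b):
                if part not in node:
                    node[part] = next(iter(part)) if len(part) == 1 else "(" + ",".join(sorted(part)) + ")"
                    height_of[part] = 0.0
            hh = h if math.isfinite(h) else 0.0
            la = max(hh - height_of[a], 0.0)
            lb = max(hh - height_of[b], 0.0)
            merged = a | b
            node[merged] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height_of[merged] = hh
        if not node:
            leaves = ",".join(sorted(n for c in self.clusters for n in c))
            return f"({leaves});"
        roots = [k for k in node if not any(k < other for other in node)]
        if len(roots) == 1:
            return node[roots[0]] + ";"
        return "(" + ",".join(node[r] for r in sorted(roots, key=sorted)) + ");"


def cluster_parameters(
    fim: FisherInformation,
    delta: float = 0.01,
    zeta: float = 1e-6,
    refilter: str = "per_iteration",
) -> RedundancyTree:
    """Iterative merge-and-remove hierarchical clustering of parameters.

    Each turn merges the two current sets with the largest functional
    redundancy, then (``refilter="per_iteration"``) re-applies the
    identifiability filter to the remaining parameters so that parameters
    whose confounders were removed earlier can drop out mid-run;
    ``refilter="once"`` filters only up front.  The final assignment cuts the
    dendrogram at the largest relative gap between consecutive merge heights.
    """
    if refilter not in ("per_iteration", "once"):
        raise ValueError(f"unknown refilter mode {refilter!r}")
    names = fim.param_names
    active, removed0 = identifiability_filter(fim, delta, zeta)
    removed = [(names[i], 0, reason) for i, reason in removed0]
    if not active:
        raise ValueError(f"model fully non-identifiable under (delta={delta}, zeta={zeta})")

    sets: list[frozenset[int]] = [frozenset([i]) for i in active]
    merges: list[tuple[int, frozenset, frozenset, float]] = []
    cache: dict[tuple[frozenset, frozenset], float] = {}

    def redundancy(a: frozenset, b: frozenset) -> float:
        key = (a, b) if sorted(a)[0] < sorted(b)[0] else (b, a)
        if key not in cache:
            cache[key] = functional_redundancy(fim, sorted(key[0]), sorted(key[1]))
        return cache[key]

    step = 0
    while len(sets) > 1:
        step += 1
        best, best_val = None, -1.0
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                val = redundancy(sets[i], sets[j])
                if val > best_val:
                    best, best_val = (i, j), val
        if best is None or best_val <= 0.0:
            break  # all remaining redundancies vanish
        i, j = best
        a, b = sets[i], sets[j]
        merged = a | b
        merges.append(
            (step, frozenset(names[k] for k in a), frozenset(names[k] for k in b), best_val)
        )
        sets = [s for k, s in enumerate(sets) if k not in (i, j)] + [merged]

        if refilter == "per_iteration":
            current = sorted(set().union(*sets))
            keep, dropped = identifiability_filter(fim, delta, zeta, subset=current)
            if dropped:
                gone = {i for i, _ in dropped}
                removed.extend((names[i], step, reason) for i, reason in dropped)
                sets = [frozenset(s - gone) for s in sets]
                sets = [s for s in sets if s]
                cache = {k: v for k, v in cache.items() if not (set(k[0]) | set(k[1])) & gone}
                if not sets:
                    break

    clusters, cut = _cut_clusters(names, merges, sets)
    return RedundancyTree(
        param_names=names,
        merges=merges,
        removed=removed,
        clusters=clusters,
        delta=delta,
        zeta=zeta,
        cut_height=cut,
    )


def _cut_clusters(names, merges, final_sets):
    """Cut at the largest relative gap between consecutive finite merge heights."""
    leaf_sets = [frozenset(names[i] for i in s) for s in final_sets]
    finite = sorted({h for _, _, _, h in merges if math.isfinite(h)}, reverse=True)
    if len(finite) < 2:
        return [set(s) for s in leaf_sets], None
    gaps = [(finite[k] - finite[k + 1]) / finite[k] for k in range(len(finite) - 1)]
    kmax = int(np.argmax(gaps))
    cut = 0.5 * (finite[kmax] + finite[kmax + 1])
    # replay merges above the cut over the surviving parameters
    survivors = set().union(*leaf_sets) if leaf_sets else set()
    parts: list[set[str]] = [{n} for n in sorted(survivors)]

    def find(name):
        for p in parts:
            if name in p:
                return p
        return None

    for _, a, b, h in merges:
        if not (math.isinf(h) or h > cut):
            continue
        pa = next((find(n) for n in sorted(a) if find(n)), None)
        pb = next((find(n) for n in sorted(b) if find(n)), None)
        if pa is None or pb is None or pa is pb:
            continue
        pa |= pb
        parts.remove(pb)
    return parts, cut
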