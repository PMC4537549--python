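"""Deterministic simulation, stationary states, divergence detection and SSA.

Deterministic time courses solve ``dS/dt = M v(S)`` with a stiff-capable
implicit integrator (relative tolerance 1e-8, absolute 1e-12) so that the
stationary residuals feeding the LNA and Fisher-information stages are clean.
The exact stochastic oracle is a direct-method Gillespie simulation of the
jump process defined by the same propensities and stoichiometry columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import NetworkError, ReactionNetwork

__all__ = [
    "Trajectory",
    "StationaryState",
    "SimulationError",
    "simulate",
    "find_stationary_state",
    "detect_divergence",
    "ssa_simulate",
]

RTOL = 1e-8
ATOL = 1e-12


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """Time grid x species concentration matrix with solver metadata."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    species_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(self.species_ids)):
            raise ValueError("trajectory grid does not match value matrix")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.values < -10 * ATOL * max(1.0, np.abs(self.values).max(initial=1.0))):
            raise ValueError("negative concentrations beyond solver tolerance")

    def final_state(self) -> np.ndarray:
        return self.values[-1]

    def series(self, sid: str) -> np.ndarray:
        return self.values[:, self.species_ids.index(sid)]

    def to_frame(self):
        """Tidy (time, species, value, scenario) table."""
        import pandas as pd

        scen = self.metadata.get("scenario", "")
        rows = [
            {"time": t, "species": sid, "value": v, "scenario": scen}
            for i, t in enumerate(self.times)
            for sid, v in zip(self.species_ids, self.values[i])
        ]
        return pd.DataFrame(rows)


@dataclass
class StationaryState:
    state: np.ndarray
    residual_norm: float
    method: str
    species_ids: list[str]


def simulate(
    net: ReactionNetwork,
    x0: np.ndarray | None = None,
    t_end: float = 100.0,
    grid: np.ndarray | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the ODE system from ``x0`` to ``t_end`` on the given grid."""
    compiled = net.compiled()
    p = net.parameter_values()
    if x0 is None:
        x0 = net.initial_state()
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise NetworkError("initial state must be non-negative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if grid is None:
        grid = np.linspace(0.0, t_end, 201)
    grid = np.asarray(grid, dtype=float)

    sol = solve_ivp(
        lambda t, x: compiled.rhs(x, p),
        (grid[0], grid[-1]),
        x0,
        method="LSODA",
        t_eval=grid,
        jac=lambda t, x: compiled.rhs_jac_x(x, p),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"solver failed: {sol.message}", last_time=float(sol.t[-1]) if sol.t.size else None)
    values = np.clip(sol.y.T, -10 * atol, None)
    return Trajectory(
        times=sol.t,
        values=values,
        species_ids=[s.id for s in net.dynamic_species],
        metadata={
            "scenario": net.metadata.get("scenario", ""),
            "rtol": rtol,
            "atol": atol,
            "solver": "LSODA",
        },
    )


def find_stationary_state(
    net: ReactionNetwork,
    x0: np.ndarray | None = None,
    horizon: float = 1e4,
    tol: float = 1e-9,
    polish: bool = True,
) -> StationaryState:
    """Stabilize to the stationary state by long integration with plateau detection.

    Integration proceeds in windows; the plateau criterion
    ``||dx/dt||_inf < tol * (1 + ||x||_inf)`` must hold throughout a window of
    10 % of the horizon.  The plateau point is optionally polished by Newton
    root-finding on ``M v(x) = 0`` (kept only when it stays non-negative and
    reduces the residual).
    """
    compiled = net.compiled()
    p = net.parameter_values()
    if x0 is None:
        x0 = net.initial_state()
    x = np.asarray(x0, dtype=float)
    if np.any(x < 0):
        raise NetworkError("initial state must be non-negative")

    window = max(horizon / 10.0, 1.0)
    t = 0.0
    method = "integration"
    while t < horizon:
        sol = solve_ivp(
            lambda tt, xx: compiled.rhs(xx, p),
            (0.0, window),
            x,
            method="LSODA",
            jac=lambda tt, xx: compiled.rhs_jac_x(xx, p),
            rtol=RTOL,
            atol=ATOL,
            dense_output=True,
        )
        if not sol.success:
            raise SimulationError(f"stabilization failed: {sol.message}", last_time=t)
        t += window
        x = np.clip(sol.y[:, -1], 0.0, None)
        # plateau: residual small across the whole window, checked at samples
        checks = sol.sol(np.linspace(0.0, window, 8))
        resid = max(
            np.abs(compiled.rhs(np.clip(c, 0.0, None), p)).max()
            for c in checks.T
        )
        if resid < tol * (1 + np.abs(x).max()):
            break
    else:
        resid = np.abs(compiled.rhs(x, p)).max()
        raise SimulationError(
            f"no stationary plateau before horizon {horizon}: residual {resid:.3e}",
            last_time=horizon,
        )

    if polish:
        res = root(
            lambda xx: compiled.rhs(xx, p),
            x,
            jac=lambda xx: compiled.rhs_jac_x(xx, p),
            method="hybr",
        )
        if res.success and np.all(res.x >= -ATOL):
            cand = np.clip(res.x, 0.0, None)
            if np.linalg.norm(compiled.rhs(cand, p)) <= np.linalg.norm(compiled.rhs(x, p)):
                x = cand
                method = "integration+root"
    return StationaryState(
        state=x,
        residual_norm=float(np.linalg.norm(compiled.rhs(x, p))),
        method=method,
        species_ids=[s.id for s in net.dynamic_species],
    )


def detect_divergence(
    traj: Trajectory, threshold: float | None = None
) -> list[tuple[str, float]]:
    """Species whose concentration crosses ``threshold``, with first crossing time.

    The default threshold is 1e6 times the largest initial concentration
    (which must exceed every initial value for the crossing to be meaningful).
    """
    if threshold is None:
        threshold = 1e6 * max(traj.values[0].max(), 1.0)
    if threshold <= traj.values[0].max():
        raise ValueError("threshold must exceed the largest initial concentration")
    out: list[tuple[str, float]] = []
    for i, sid in enumerate(traj.species_ids):
        above = traj.values[:, i] > threshold
        if above.any():
            out.append((sid, float(traj.times[np.argmax(above)])))
    return out


def ssa_simulate(
    net: ReactionNetwork,
    x0_counts: np.ndarray | None = None,
    t_end: float = 20.0,
    n_paths: int = 1,
    seed: int = 0,
    sample_times: np.ndarray | None = None,
) -> np.ndarray:
    """Exact (direct-method) stochastic simulation of the jump process.

    Returns an array of shape ``(n_paths, n_sample_times, n_species)`` holding
    the state at each requested sample time (default: the single time
    ``t_end``).  Each path uses an independent generator spawned from the root
    seed, so results are reproducible and independent of ``n_paths`` ordering.
    """
    compiled = net.compiled()
    p = net.parameter_values()
    M = compiled.M
    if x0_counts is None:
        x0_counts = np.rint(net.initial_state())
    x0_counts = np.asarray(x0_counts, dtype=float)
    if np.any(x0_counts < 0) or np.any(x0_counts != np.rint(x0_counts)):
        raise NetworkError("initial counts must be non-negative integers")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if sample_times is None:
        sample_times = np.array([t_end])
    sample_times = np.asarray(sample_times, dtype=float)

    n_sp = M.shape[0]
    out = np.empty((n_paths, sample_times.size, n_sp))
    seeds = np.random.SeedSequence(seed).spawn(n_paths)
    for ipath in range(n_paths):
        rng = np.random.default_rng(seeds[ipath])
        x = x0_counts.copy()
        t = 0.0
        k = 0
        while k < sample_times.size:
            a = compiled.flux(x, p)
            a = np.where(_feasible(M, x), np.maximum(a, 0.0), 0.0)
            a0 = a.sum()
            if a0 <= 0:
                t_next = np.inf  # absorbed: state holds forever
            else:
                t_next = t + rng.exponential(1.0 / a0)
            while k < sample_times.size and sample_times[k] < t_next:
                out[ipath, k] = x
                k += 1
            if k >= sample_times.size:
                break
            j = np.searchsorted(np.cumsum(a), rng.uniform(0, a0), side="right")
            j = min(j, a.size - 1)
            x = x + M[:, j]
            t = t_next
    return out


def _feasible(M: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Reactions that would not drive any copy number negative."""
    return np.all(x[:, None] + M >= 0, axis=0)
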