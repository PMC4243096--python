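"""Independent numerical checks of the closed-form occupancy solution.

Two oracles validate the Poisson solution p_j(t) = lambda(t)^j e^-lambda / j!:

* direct integration of the master equation, either with the time-dependent
  rate mu(t) applied uniformly across states (``eq5_time_rate``) or with
  per-state staircase rates mu_i = mu(t_i) frozen at the self-consistent
  expected transition times t_i (``eq4_state_rates``);
* seeded stochastic simulation of per-cell mutation counts and of
  first-passage times across a pool of cells.

The state space is truncated at order J with an absorbing top state, so the
integrated system conserves probability mass exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.stats import poisson

from .core import (
    ProgressionParams,
    cumulative_intensity,
    mutation_rate,
    waiting_time,
    detection_threshold_lambda,
)

__all__ = [
    "OccupancyTrajectory",
    "SimulationResult",
    "FirstPassageResult",
    "ConvergenceError",
    "staircase_times",
    "closed_form_trajectory",
    "integrate_master_equation",
    "mean_mutated_loci",
    "simulate_cell_mutations",
    "first_passage_time",
    "MAX_SIMULATION_DRAWS",
]

# Hard cap on n_cells * n_reps draws held in memory by the samplers.
MAX_SIMULATION_DRAWS = 100_000_000


class ConvergenceError(RuntimeError):
    """Fixed-point or ODE solve failed; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class OccupancyTrajectory:
    """p_j(t) on a time grid for j = 0..J, from one of several sources."""

    t: np.ndarray  # (n_times,)
    p: np.ndarray  # (n_times, J+1)
    source: str  # closed_form | ode_eq4 | ode_eq5 | simulation
    J: int
    params: ProgressionParams

    def mass(self) -> np.ndarray:
        """Total probability captured by the truncated state space at each time."""
        return self.p.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long format (t, j, p)."""
        n_t, n_j = self.p.shape
        return pd.DataFrame(
            {
                "t": np.repeat(self.t, n_j),
                "j": np.tile(np.arange(n_j), n_t),
                "p": self.p.ravel(),
            }
        )


def default_truncation(params: ProgressionParams, t_end: float) -> int:
    """J = max(50, ceil(lambda + 10*sqrt(lambda))) at the end of the grid."""
    lam = cumulative_intensity(t_end, params)
    return max(50, int(math.ceil(lam + 10.0 * math.sqrt(lam))))


def closed_form_trajectory(
    params: ProgressionParams, t_grid, J: int | None = None
) -> OccupancyTrajectory:
    """Analytic Poisson occupancy evaluated on a grid (reference trajectory)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if J is None:
        J = default_truncation(params, t_grid[-1])
    lam = np.atleast_1d(cumulative_intensity(t_grid, params))
    j = np.arange(J + 1)
    p = poisson.pmf(j[None, :], lam[:, None])
    return OccupancyTrajectory(t_grid, p, "closed_form", J, params)


def staircase_times(
    params: ProgressionParams, n_stages: int, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Self-consistent expected transition times t_1 < t_2 < ... < t_n.

    Each holding time in state i-1 averages 1/mu(t_i), so t_i solves
    t_i = t_{i-1} + 1/mu(t_i).  Starting from the waiting-time inverse
    t_i ~ lambda^{-1}(i), the residual f(t) = t - t_{i-1} - 1/mu(t) is
    driven below ``tol`` by damped Newton steps (f' = 1 + b/mu(t) > 1, so
    the plain substitution map need not contract when mu is small).
    """
    times = np.empty(n_stages + 1)
    times[0] = 0.0
    trace: list[tuple[int, int, float]] = []
    for i in range(1, n_stages + 1):
        t = max(waiting_time(float(i), params), times[i - 1])
        for it in range(max_iter):
            inv_rate = 1.0 / mutation_rate(max(t, 0.0), params)
            f = t - times[i - 1] - inv_rate
            if abs(f) < tol:
                break
            fprime = 1.0 + params.b * inv_rate  # d/dt [t - 1/mu(t)]
            t_new = t - f / fprime
            if t_new < times[i - 1]:
                t_new = 0.5 * (t + times[i - 1])
            t = t_new
        else:
            trace.append((i, max_iter, abs(f)))
            raise ConvergenceError(
                f"staircase time t_{i} did not reach |residual| < {tol} "
                f"after {max_iter} iterations (last residual {f:.3g})",
                trace=trace,
            )
        trace.append((i, it, abs(f)))
        times[i] = t
    return times[1:]


def _band_jacobian(rates: np.ndarray) -> np.ndarray:
    """Packed banded Jacobian (ml=1, mu=0) for the bidiagonal system."""
    J = rates.shape[0] - 1  # rates[i] multiplies outflow from state i
    band = np.zeros((2, J + 1))
    band[0, :] = -rates  # diagonal: -outflow
    band[0, J] = 0.0  # absorbing top state
    band[1, :-1] = rates[:-1]  # subdiagonal: inflow from j-1
    return band


def integrate_master_equation(
    params: ProgressionParams,
    J: int | None = None,
    t_grid=None,
    variant: str = "eq5_time_rate",
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> OccupancyTrajectory:
    """Numerically integrate the truncated master equation.

    ``eq5_time_rate``: dp_j/dt = mu(t) (p_{j-1} - p_j) — one global
    time-dependent rate.  ``eq4_state_rates``: dp_i/dt = mu_i p_{i-1} -
    mu_{i+1} p_i with constant per-state rates mu_i = mu(t_i) at the
    staircase times.  Mass leaving state J-1 is absorbed at state J.
    """
    if t_grid is None:
        raise ValueError("t_grid is required")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing and start at 0")
    if J is None:
        J = default_truncation(params, float(t_grid[-1]))
    if J < 2:
        raise ValueError(f"truncation J must be >= 2, got {J}")
    if variant not in ("eq5_time_rate", "eq4_state_rates"):
        raise ValueError(f"unknown variant {variant!r}")

    y0 = np.zeros(J + 1)
    y0[0] = 1.0  # all cells unmutated at t = 0

    if variant == "eq5_time_rate":

        def rhs(y, t):
            mu = params.mu0 * math.exp(params.b * t)
            out = np.empty_like(y)
            out[0] = -mu * y[0]
            out[1:] = mu * (y[:-1] - y[1:])
            out[J] = mu * y[J - 1]  # absorbing top state
            return out

        def jac(y, t):
            mu = params.mu0 * math.exp(params.b * t)
            rates = np.full(J + 1, mu)
            return _band_jacobian(rates)

    else:
        # per-state outflow rate from state i is mu_{i+1} = mu(t_{i+1})
        t_stairs = staircase_times(params, J + 1)
        mu_out = mutation_rate(t_stairs, params)  # mu_out[i] = mu(t_{i+1})
        rates = np.append(mu_out, 0.0)[: J + 1]  # outflow from state i

        def rhs(y, t):
            out = np.empty_like(y)
            out[0] = -rates[0] * y[0]
            out[1:] = rates[:-1] * y[:-1] - rates[1:] * y[1:]
            out[J] = rates[J - 1] * y[J - 1]
            return out

        band = _band_jacobian(rates)

        def jac(y, t):
            return band

    sol, info = odeint(
        rhs,
        y0,
        t_grid,
        Dfun=jac,
        ml=1,
        mu=0,
        rtol=rtol,
        atol=atol,
        full_output=True,
        mxstep=100_000,
    )
    if info["message"] != "Integration successful.":
        raise ConvergenceError(
            f"master-equation integration failed (rtol={rtol}, atol={atol}): "
            f"{info['message']}"
        )
    source = "ode_eq5" if variant == "eq5_time_rate" else "ode_eq4"
    return OccupancyTrajectory(t_grid, sol, source, J, params)


def mean_mutated_loci(trajectory: OccupancyTrajectory, mass_tol: float = 1e-6) -> np.ndarray:
    """Mean driver count <j>(t) = sum_j j p_j(t); equals lambda(t) in closed form."""
    loss = 1.0 - trajectory.mass()
    if np.max(np.abs(loss)) > mass_tol:
        warnings.warn(
            f"truncation at J={trajectory.J} loses up to {np.max(np.abs(loss)):.3g} "
            f"probability mass (tolerance {mass_tol:g}); mean is biased low",
            RuntimeWarning,
            stacklevel=2,
        )
    j = np.arange(trajectory.p.shape[1])
    return trajectory.p @ j


@dataclass(frozen=True)
class SimulationResult:
    """Per-cell driver counts at t_end plus empirical occupancy frequencies."""

    counts: np.ndarray
    seed: int
    n_cells: int
    t_end: float
    lambda_end: float
    arrival_times: list[np.ndarray] | None = None

    def frequencies(self) -> pd.DataFrame:
        j, n = np.unique(self.counts, return_counts=True)
        return pd.DataFrame({"j": j, "frequency": n / self.n_cells})

    def to_json(self) -> str:
        """Deterministic serialization (used for byte-level reproducibility)."""
        payload = {
            "seed": self.seed,
            "n_cells": self.n_cells,
            "t_end": self.t_end,
            "lambda_end": self.lambda_end,
            "counts": self.counts.tolist(),
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def simulate_cell_mutations(
    params: ProgressionParams,
    t_end: float,
    n_cells: int,
    seed: int,
    return_arrival_times: bool = False,
) -> SimulationResult:
    """Sample per-cell mutation counts at ``t_end`` by time-rescaling.

    In rescaled time the process is a unit-rate Poisson process on
    [0, lambda(t_end)], so each cell's count is Poisson(lambda(t_end)) and
    its arrival epochs are sorted uniforms on that interval mapped back
    through the inverse of lambda (the waiting-time formula).  Cells are
    drawn in index order from a single seeded stream, so enlarging
    ``n_cells`` extends the sample without reordering earlier cells' draws.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    if n_cells > MAX_SIMULATION_DRAWS:
        raise MemoryError(
            f"n_cells={n_cells:g} exceeds the in-memory cap of "
            f"{MAX_SIMULATION_DRAWS:g} draws; reduce the pool or use the "
            f"rescaled small-N regime"
        )
    rng = _rng(seed)
    lam = float(cumulative_intensity(t_end, params))
    counts = rng.poisson(lam, size=n_cells)
    arrivals = None
    if return_arrival_times:
        arrivals = [
            waiting_time(np.sort(rng.uniform(0.0, lam, size=c)), params)
            if c
            else np.empty(0)
            for c in counts
        ]
        arrivals = [np.atleast_1d(a) for a in arrivals]
    return SimulationResult(counts, seed, int(n_cells), float(t_end), lam, arrivals)


@dataclass(frozen=True)
class FirstPassageResult:
    """Empirical first time any of n_cells accumulates k drivers."""

    samples: np.ndarray  # (n_reps,) in generations
    k: int
    n_cells: int
    seed: int
    predicted_t: float  # waiting_time(detection_threshold_lambda(k, N))

    def quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> dict[float, float]:
        vals = np.quantile(self.samples, q)
        return {float(qq): float(v) for qq, v in zip(q, vals)}


def first_passage_time(
    params: ProgressionParams,
    k: int,
    n_cells: int,
    n_reps: int,
    seed: int,
    method: str = "linearized",
) -> FirstPassageResult:
    """Monte-Carlo distribution of the first k-th driver arrival in a pool.

    Per cell the k-th arrival epoch in rescaled time is Gamma(k, 1); the
    pool's first passage is the minimum over cells mapped through the
    inverse intensity.  Compared against the detection-threshold heuristic
    t_k = lambda^{-1}(lambda_k), which times the moment the *expected*
    k-driver occupancy reaches one cell in N.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n_reps < 1 or n_cells < 1:
        raise ValueError("n_reps and n_cells must be >= 1")
    if n_cells * n_reps > MAX_SIMULATION_DRAWS:
        raise MemoryError(
            f"n_cells*n_reps = {n_cells * n_reps:g} exceeds the cap of "
            f"{MAX_SIMULATION_DRAWS:g} draws; rerun in the rescaled small-N "
            f"regime (smaller pool, same lambda thresholds)"
        )
    rng = _rng(seed)
    min_rescaled = np.empty(n_reps)
    for r in range(n_reps):
        min_rescaled[r] = rng.gamma(k, 1.0, size=n_cells).min()
    samples = waiting_time(min_rescaled, params)
    if n_cells > 1:
        lam_k = detection_threshold_lambda(k, n_cells, method).lambda_k
    else:
        # single cell: the 1/N convention degenerates to p_k = 1, whose
        # linearized threshold is (k!)^(1/k)
        lam_k = math.exp(math.lgamma(k + 1) / k)
    predicted = waiting_time(lam_k, params)
    return FirstPassageResult(np.atleast_1d(samples), k, int(n_cells), seed, float(predicted))
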