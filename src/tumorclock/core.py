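"""Closed-form multistage progression model.

A cell accumulates driver mutations as an inhomogeneous Poisson process
whose per-generation rate grows exponentially with time,

    mu(t) = mu0 * exp(b * t),        b = a * s,

where ``mu0`` is the initial driver-mutation rate per cell per generation,
``s`` the selective advantage coefficient of a mutated lineage and ``a`` a
dimensionless transform factor linking selection strength to the curvature
of the rate law.  Only the product ``b = a*s`` (and ``mu0``) enters every
observable quantity.

The cumulative intensity

    lambda(t) = integral_0^t mu(x) dx = (mu0 / b) * (exp(b*t) - 1)

is the mean of the Poisson-distributed mutation count, so the fraction of
cells carrying exactly ``j`` drivers at time ``t`` is
``p_j(t) = lambda(t)^j exp(-lambda(t)) / j!``.

A stage with ``k`` drivers is called detectable in a pool of ``N`` sensitive
cells once ``p_k`` reaches ``1/N`` (one expected cell in state ``k``).  The
intensity at that moment is the detection threshold ``lambda_k``, the smaller
positive root of ``lambda^k exp(-lambda) / k! = 1/N``:

    lambda_k = -k * W0( -(k!)^(1/k) / (k * N^(1/k)) )          (exact)
    lambda_k ~  (k! / N)^(1/k)                                  (linearized)

with ``W0`` the principal branch of the Lambert W function; the linearized
form drops the ``exp(-lambda)`` factor and is what published threshold
tables actually print.  Inverting the cumulative intensity gives the
waiting time until the stage is detectable,

    t_k = ln(b * lambda_k / mu0 + 1) / b            [generations].

All internal times are in cell generations; conversions to days and years
use the per-parameter generation time (default 4 days) and 365-day years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, lambertw
from scipy.stats import poisson

__all__ = [
    "EPSILON_B",
    "N_CAN_GENES",
    "DAYS_PER_YEAR",
    "DEFAULT_GENERATION_TIME_DAYS",
    "DetectionError",
    "ProgressionParams",
    "ThresholdResult",
    "StageDefinition",
    "DEFAULT_STAGES",
    "WaitingTimeTable",
    "mutation_rate",
    "cumulative_intensity",
    "stage_probability",
    "detection_threshold_lambda",
    "waiting_time",
    "waiting_time_table",
    "convert_time",
]

# Below this curvature (per generation) the homogeneous-limit formulas are
# used; avoids cancellation in (exp(b*t)-1)/b and ln(1+x)/b.
EPSILON_B = 1e-12

# Working count of cancer candidate (CAN-) genes.  Metadata only: the model
# keeps the unbounded Poisson state space, no finite-sites cap is applied.
N_CAN_GENES = 30

DAYS_PER_YEAR = 365.0
DEFAULT_GENERATION_TIME_DAYS = 4.0


class DetectionError(ValueError):
    """No detection solution: the peak of p_k(lambda) never reaches 1/N."""


@dataclass(frozen=True)
class ProgressionParams:
    """Parameter bundle (mu0, s, a) with derived curvature b = a*s.

    Either both ``s`` and ``a`` are given (then ``b`` is derived), or ``b``
    is given directly; waiting times depend only on ``(mu0, b)``, so fits
    return ``b`` without a unique (s, a) decomposition.
    """

    mu0: float
    s: float | None = None
    a: float | None = None
    b: float = field(default=None)  # type: ignore[assignment]
    generation_time_days: float = DEFAULT_GENERATION_TIME_DAYS

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if not self.generation_time_days > 0:
            raise ValueError(
                f"generation_time_days must be positive, got {self.generation_time_days}"
            )
        s, a, b = self.s, self.a, self.b
        if s is not None and s < 0:
            raise ValueError(f"s must be nonnegative, got {s}")
        if a is not None and a < 0:
            raise ValueError(f"a must be nonnegative, got {a}")
        if s is not None and a is not None:
            derived = a * s
            if b is not None and b != derived:
                raise ValueError(f"b={b} inconsistent with a*s={derived}")
            object.__setattr__(self, "b", derived)
        elif b is not None:
            if b < 0:
                raise ValueError(f"b must be nonnegative, got {b}")
            # one known factor determines the other
            if s is not None and s > 0:
                object.__setattr__(self, "a", b / s)
            elif a is not None and a > 0:
                object.__setattr__(self, "s", b / a)
        else:
            raise ValueError("supply either (s and a) or b")

    @classmethod
    def from_b(
        cls,
        mu0: float,
        b: float,
        generation_time_days: float = DEFAULT_GENERATION_TIME_DAYS,
    ) -> "ProgressionParams":
        return cls(mu0=mu0, b=b, generation_time_days=generation_time_days)

    @property
    def is_homogeneous(self) -> bool:
        return self.b <= EPSILON_B

    def with_generation_time(self, days: float) -> "ProgressionParams":
        return replace(self, generation_time_days=days)


# Parameter sets for the two colorectal patients: Mx34 follows the stated
# rate curve mu(t) = 2e-5 * exp(0.0032 t) (s=0.01, a=0.32); Co82 follows the
# tabulated (s, a, mu0) with b = a*s.
MX34_PARAMS = ProgressionParams(mu0=2e-5, s=0.01, a=0.32)
CO82_PARAMS = ProgressionParams(mu0=2e-7, s=0.0075, a=0.309)


@dataclass(frozen=True)
class ThresholdResult:
    k: int
    n_cells: float
    method: str  # "exact" | "linearized"
    lambda_k: float


@dataclass(frozen=True)
class StageDefinition:
    """Ordered mapping from clinical stage label to driver count k."""

    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        ks = [k for _, k in self.stages]
        if any(k < 1 for k in ks):
            raise ValueError(f"driver counts must be positive: {ks}")
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError(f"driver counts must strictly increase along stages: {ks}")

    @classmethod
    def from_mapping(cls, mapping: dict[str, int]) -> "StageDefinition":
        return cls(tuple(mapping.items()))

    def label_for(self, k: int) -> str:
        for label, kk in self.stages:
            if kk == k:
                return label
        return ""

    def items(self) -> tuple[tuple[str, int], ...]:
        return self.stages


# 3 drivers mark an adenoma (microadenoma), 12 a carcinoma.
DEFAULT_STAGES = StageDefinition(
    (
        ("microadenoma", 3),
        ("small_adenoma", 4),
        ("large_adenoma", 5),
        ("carcinoma", 12),
    )
)


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def mutation_rate(t, params: ProgressionParams):
    """Driver-mutation rate mu(t) = mu0 * exp(b*t), per generation."""
    t = _check_time(t)
    out = params.mu0 * np.exp(params.b * t)
    return float(out) if out.ndim == 0 else out


def cumulative_intensity(t, params: ProgressionParams):
    """Cumulative intensity lambda(t) = (mu0/b)(exp(b*t) - 1); mu0*t for b ~ 0."""
    t = _check_time(t)
    if params.is_homogeneous:
        out = params.mu0 * t
    else:
        out = params.mu0 * np.expm1(params.b * t) / params.b
    return float(out) if out.ndim == 0 else out


def stage_probability(j, t, params: ProgressionParams):
    """Fraction of cells carrying exactly j drivers at time t (Poisson mass)."""
    j_arr = np.asarray(j)
    if np.any(j_arr < 0) or not np.issubdtype(j_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(j_arr, 1), 0)) or np.any(j_arr < 0):
            raise ValueError("j must be a nonnegative integer")
    lam = cumulative_intensity(t, params)
    out = poisson.pmf(j, lam)
    return float(out) if np.ndim(out) == 0 else out


def detection_threshold_lambda(
    k: int, n_cells: float, method: str = "linearized"
) -> ThresholdResult:
    """Intensity lambda_k at which the k-driver stage reaches frequency 1/N.

    ``linearized`` returns (k!/N)^(1/k) (drops exp(-lambda); what threshold
    tables print).  ``exact`` returns the smaller positive root of
    lambda^k exp(-lambda)/k! = 1/N via the principal Lambert W branch; it
    fails when even the peak of the Poisson mass at k stays below 1/N.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if not n_cells > 1:
        raise ValueError(f"n_cells must exceed 1, got {n_cells}")
    if method not in ("linearized", "exact"):
        raise ValueError(f"unknown method {method!r}")

    # (k!/N)^(1/k) in log space: exp((ln k! - ln N) / k)
    linearized = math.exp((gammaln(k + 1) - math.log(n_cells)) / k)
    if method == "linearized":
        return ThresholdResult(k, n_cells, "linearized", linearized)

    arg = -linearized / k
    if arg < -1.0 / math.e:
        raise DetectionError(
            f"no detection solution for k={k}, N={n_cells:g}: "
            f"max_lambda p_k(lambda) < 1/N (Lambert-W argument {arg:.6g} < -1/e)"
        )
    lam = -k * lambertw(arg, 0).real
    return ThresholdResult(k, n_cells, "exact", float(lam))


def waiting_time(lambda_k, params: ProgressionParams):
    """Invert lambda(t): generations until the cumulative intensity reaches lambda_k."""
    lam = np.asarray(lambda_k, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda_k must be nonnegative")
    if params.is_homogeneous:
        out = lam / params.mu0
    else:
        out = np.log1p(params.b * lam / params.mu0) / params.b
    return float(out) if out.ndim == 0 else out


def convert_time(
    value,
    from_unit: str,
    to_unit: str,
    generation_time_days: float = DEFAULT_GENERATION_TIME_DAYS,
):
    """Linear conversion between generations, days and years (365-day years)."""
    factors = {
        "generations": generation_time_days,
        "days": 1.0,
        "years": DAYS_PER_YEAR,
    }
    for unit in (from_unit, to_unit):
        if unit not in factors:
            raise ValueError(f"unknown time unit {unit!r}; expected one of {sorted(factors)}")
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("time value must be nonnegative")
    out = value * (factors[from_unit] / factors[to_unit])
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WaitingTimeTable:
    """Per-k detection thresholds and waiting times for one cell pool size."""

    table: pd.DataFrame  # columns: k, lambda_k, t_generations, t_years, stage, note
    params: ProgressionParams
    n_cells: float
    method: str

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def waiting_time_table(
    params: ProgressionParams,
    n_cells: float,
    k_max: int,
    stage_defs: StageDefinition | None = None,
    method: str = "linearized",
) -> WaitingTimeTable:
    """Threshold lambda_k and waiting time t_k for k = 1..k_max.

    Rows where the exact threshold has no solution are kept with NaN values
    and an explanatory note instead of aborting the table.
    """
    if not k_max >= 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    stage_defs = stage_defs if stage_defs is not None else DEFAULT_STAGES
    rows = []
    for k in range(1, int(k_max) + 1):
        note = ""
        try:
            lam = detection_threshold_lambda(k, n_cells, method).lambda_k
            t_gen = waiting_time(lam, params)
            t_years = convert_time(t_gen, "generations", "years", params.generation_time_days)
        except DetectionError as err:
            lam = t_gen = t_years = math.nan
            note = str(err)
        rows.append(
            {
                "k": k,
                "lambda_k": lam,
                "t_generations": t_gen,
                "t_years": t_years,
                "stage": stage_defs.label_for(k),
                "note": note,
            }
        )
    return WaitingTimeTable(pd.DataFrame(rows), params, float(n_cells), method)
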