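"""Per-patient parameter fitting and synthetic timeline generation.

A patient timeline is a short ordered list of (stage, driver count k,
observed age in years).  The forward model maps k to a predicted detection
age through the threshold lambda_k and the waiting-time inverse of the
cumulative intensity; fitting minimizes squared log-time residuals

    sum_i ( ln t_model(k_i; b, mu0) - ln t_obs,i )^2

over (ln b, ln mu0) with a deterministic multi-start grid of local
least-squares solves.  Only the product b = a*s is identifiable from
waiting times; ``decompose_b`` splits it when one factor is known from
elsewhere.  A seeded generator produces noisy synthetic timelines with
lognormal multiplicative noise for parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    DEFAULT_GENERATION_TIME_DAYS,
    DEFAULT_STAGES,
    ProgressionParams,
    StageDefinition,
    convert_time,
    detection_threshold_lambda,
    waiting_time,
)

__all__ = [
    "StageObservation",
    "PatientTimeline",
    "FitResult",
    "CohortSummary",
    "UnderDeterminedError",
    "predict_timeline",
    "fit_progression_params",
    "decompose_b",
    "generate_synthetic_timeline",
    "summarize_cohort",
]


class UnderDeterminedError(ValueError):
    """Fewer observations than free parameters (b, mu0)."""


@dataclass(frozen=True)
class StageObservation:
    stage: str
    k: int
    t_obs: float  # years from process initiation

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not self.t_obs > 0:
            raise ValueError(f"t_obs must be positive, got {self.t_obs}")


@dataclass(frozen=True)
class PatientTimeline:
    patient_id: str
    observations: tuple[StageObservation, ...]
    n_cells: float = 1e10
    generation_time_days: float = DEFAULT_GENERATION_TIME_DAYS

    def __post_init__(self) -> None:
        if len(self.observations) == 0:
            raise ValueError("timeline must contain at least one observation")
        ks = [o.k for o in self.observations]
        ts = [o.t_obs for o in self.observations]
        if any(b <= a for a, b in zip(ks, ks[1:])) or any(
            b <= a for a, b in zip(ts, ts[1:])
        ):
            raise ValueError(
                f"driver counts and observed times must jointly increase, "
                f"got k={ks}, t={ts}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [o.stage for o in self.observations],
                "k": [o.k for o in self.observations],
                "t_years": [o.t_obs for o in self.observations],
            }
        )


def _model_times_years(
    ks,
    mu0: float,
    b: float,
    lambda_ks: np.ndarray,
    generation_time_days: float,
) -> np.ndarray:
    """Forward model: detection age in years for each driver count."""
    params = ProgressionParams.from_b(mu0, b, generation_time_days)
    t_gen = waiting_time(lambda_ks, params)
    return np.atleast_1d(
        convert_time(t_gen, "generations", "years", generation_time_days)
    )


def predict_timeline(
    params: ProgressionParams,
    n_cells: float,
    stage_defs: StageDefinition | None = None,
    method: str = "linearized",
) -> pd.DataFrame:
    """Predicted (stage, k, t_years) rows for every stage in the definition."""
    stage_defs = stage_defs if stage_defs is not None else DEFAULT_STAGES
    labels = [lab for lab, _ in stage_defs.items()]
    ks = np.array([k for _, k in stage_defs.items()])
    lams = np.array(
        [detection_threshold_lambda(int(k), n_cells, method).lambda_k for k in ks]
    )
    t_years = _model_times_years(
        ks, params.mu0, params.b, lams, params.generation_time_days
    )
    return pd.DataFrame({"stage": labels, "k": ks, "t_years": t_years})


@dataclass(frozen=True)
class FitResult:
    b_hat: float
    mu0_hat: float
    residuals: np.ndarray  # log-time residuals, one per observation
    objective: float  # sum of squared residuals
    converged: bool
    seed: int
    n_starts: int
    method: str
    message: str = ""
    s_hat: float | None = None
    a_hat: float | None = None

    def predicted_times(self, timeline: PatientTimeline) -> np.ndarray:
        ks = [o.k for o in timeline.observations]
        lams = np.array(
            [
                detection_threshold_lambda(k, timeline.n_cells, self.method).lambda_k
                for k in ks
            ]
        )
        return _model_times_years(
            ks, self.mu0_hat, self.b_hat, lams, timeline.generation_time_days
        )

    def to_dict(self) -> dict:
        return {
            "b_hat": self.b_hat,
            "mu0_hat": self.mu0_hat,
            "s_hat": self.s_hat,
            "a_hat": self.a_hat,
            "residuals": [float(r) for r in self.residuals],
            "objective": self.objective,
            "converged": self.converged,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "method": self.method,
            "message": self.message,
        }


# Deterministic multi-start grid in log parameter space: the objective
# surface is smooth but can have a shallow valley in the b direction.
DEFAULT_START_GRID = {
    "log_mu0": (math.log(1e-8), math.log(1e-4), 5),
    "log_b": (math.log(1e-4), math.log(1e-1), 5),
}


def fit_progression_params(
    timeline: PatientTimeline,
    method: str = "linearized",
    optimizer_options: dict | None = None,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of (b, mu0) to a patient's stage ages.

    Residuals are differences of log detection ages (years), so early and
    late stages weigh equally.  Local solves start from every node of a
    deterministic grid over (ln mu0, ln b); the best optimum is returned
    with convergence diagnostics.
    """
    if len(timeline.observations) < 2:
        raise UnderDeterminedError(
            f"need >= 2 observations to determine (b, mu0); "
            f"got {len(timeline.observations)}"
        )
    opts = dict(DEFAULT_START_GRID)
    opts.update(optimizer_options or {})
    ks = [o.k for o in timeline.observations]
    log_t_obs = np.log([o.t_obs for o in timeline.observations])
    lambda_ks = np.array(
        [detection_threshold_lambda(k, timeline.n_cells, method).lambda_k for k in ks]
    )

    def residual(theta: np.ndarray) -> np.ndarray:
        b = math.exp(theta[0])
        mu0 = math.exp(theta[1])
        t_model = _model_times_years(
            ks, mu0, b, lambda_ks, timeline.generation_time_days
        )
        return np.log(t_model) - log_t_obs

    lo_m, hi_m, n_m = opts["log_mu0"]
    lo_b, hi_b, n_b = opts["log_b"]
    starts = [
        np.array([lb, lm])
        for lb in np.linspace(lo_b, hi_b, int(n_b))
        for lm in np.linspace(lo_m, hi_m, int(n_m))
    ]
    best = None
    n_converged = 0
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:  # singular start; other starts cover the surface
            continue
        if sol.success:
            n_converged += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or n_converged == 0:
        raise RuntimeError(
            f"no multi-start converged for patient {timeline.patient_id!r} "
            f"({len(starts)} starts over grid {opts})"
        )
    res = residual(best.x)
    return FitResult(
        b_hat=float(math.exp(best.x[0])),
        mu0_hat=float(math.exp(best.x[1])),
        residuals=res,
        objective=float(np.sum(res**2)),
        converged=bool(n_converged > 0),
        seed=seed,
        n_starts=len(starts),
        method=method,
        message=str(best.message),
    )


def decompose_b(
    b_hat: float, s: float | None = None, a: float | None = None
) -> dict:
    """Split b = a*s given exactly one factor.

    (s, a) are not separately identifiable from waiting times — the law
    depends on them only through their product — so one must be fixed from
    external knowledge.
    """
    if (s is None) == (a is None):
        raise ValueError("supply exactly one of s or a")
    if b_hat <= 0:
        raise ValueError(f"b_hat must be positive, got {b_hat}")
    if s is not None:
        if s <= 0:
            raise ValueError("fixed s must be positive")
        out = {"s_hat": s, "a_hat": b_hat / s}
    else:
        if a <= 0:
            raise ValueError("fixed a must be positive")
        out = {"s_hat": b_hat / a, "a_hat": a}
    out["identifiable"] = False  # only the product b is determined by the data
    return out


def generate_synthetic_timeline(
    true_params: ProgressionParams,
    n_cells: float,
    stage_defs: StageDefinition | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    patient_id: str = "synthetic",
    method: str = "linearized",
    max_redraws: int = 1000,
) -> PatientTimeline:
    """Noisy stage ages from the forward model: t_obs = t_model * exp(eps).

    eps ~ Normal(0, noise_sigma^2) i.i.d. per stage; a whole timeline is
    redrawn if the noise breaks the monotone ordering of observed ages.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    stage_defs = stage_defs if stage_defs is not None else DEFAULT_STAGES
    model = predict_timeline(true_params, n_cells, stage_defs, method)
    t_model = model["t_years"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _ in range(max_redraws):
        eps = rng.normal(0.0, noise_sigma, size=len(t_model)) if noise_sigma else 0.0
        t_obs = t_model * np.exp(eps)
        if np.all(np.diff(t_obs) > 0):
            break
    else:
        raise RuntimeError(
            f"could not draw a monotone timeline in {max_redraws} attempts "
            f"(noise_sigma={noise_sigma} too large for these stage gaps)"
        )
    obs = tuple(
        StageObservation(stage, int(k), float(t))
        for stage, k, t in zip(model["stage"], model["k"], t_obs)
    )
    return PatientTimeline(
        patient_id, obs, n_cells, true_params.generation_time_days
    )


def _truncate(x: float, decimals: int) -> float:
    if math.isnan(x):
        return x
    scale = 10.0**decimals
    return math.floor(x * scale) / scale


def _round_sigfigs(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sig - 1)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    nms_mean: float | None
    mu0_mean: float
    s_mean: float
    rounding: dict = field(default_factory=dict)


def summarize_cohort(
    cohort,
    s_truncate_decimals: int | None = 4,
    mu0_sigfigs: int | None = 2,
) -> CohortSummary:
    """Arithmetic cohort means of mutation counts, mu0 and s.

    ``cohort`` is a DataFrame with columns (mu0, s) and optionally ``nms``,
    or a list of FitResult (using mu0_hat/s_hat).  Published summary rows
    truncate the mean s at 4 decimals and round the mean mu0 to 2
    significant figures; both behaviours are options with those defaults.
    """
    if isinstance(cohort, pd.DataFrame):
        df = cohort
    else:
        records = []
        for fit in cohort:
            records.append(
                {
                    "mu0": fit.mu0_hat,
                    "s": fit.s_hat if fit.s_hat is not None else math.nan,
                }
            )
        df = pd.DataFrame(records)
    if len(df) == 0:
        raise ValueError("cohort is empty")
    mu0_mean = float(df["mu0"].mean())
    s_mean = float(df["s"].mean())
    if mu0_sigfigs is not None:
        mu0_mean = _round_sigfigs(mu0_mean, mu0_sigfigs)
    if s_truncate_decimals is not None:
        s_mean = _truncate(s_mean, s_truncate_decimals)
    nms_mean = float(df["nms"].mean()) if "nms" in df.columns else None
    return CohortSummary(
        n=len(df),
        nms_mean=nms_mean,
        mu0_mean=mu0_mean,
        s_mean=s_mean,
        rounding={
            "s_truncate_decimals": s_truncate_decimals,
            "mu0_sigfigs": mu0_sigfigs,
        },
    )
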