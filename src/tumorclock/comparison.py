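"""Published waiting-time clocks used as points of comparison.

Three literature formulas estimate when the k-th driver mutation (or a
target tumour size) is reached:

* Wright-Fisher fixation clock (Beerenwinkel et al.):
  t_k = k * ln(s / (u d^2)) / (2 s ln N), linear in k.
* Branching-process clock (Bozic et al.):
  t_k = (T / (k s)) * ln(2 k s / u); independent of population size.
* Comparative lesion sequencing (Jones et al.):
  the interval between two lesions' founder cells is Delta-T = F * T,
  where F is the fraction of the later lesion's mutations absent from the
  earlier lesion and T the later founder's birthdate (patient age, years).
* Exponential growth clock (Yachida-style): time for one cell to reach n
  cells growing at rate r per generation, t = T_gen * ln(n) / r.

The first two formulas' algebraic grouping is fixed here exactly as stated
above and recorded in each result's ``note``; swapping in an alternative
grouping is a one-line change in the corresponding function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ComparisonParams",
    "LesionPair",
    "ClockValue",
    "beerenwinkel_waiting_time",
    "bozic_waiting_time",
    "jones_interval",
    "growth_clock_time",
]


class ParameterDomainError(ValueError):
    """A comparison formula was evaluated outside its log/positivity domain."""


@dataclass(frozen=True)
class ComparisonParams:
    """Inputs to the Wright-Fisher and branching-process clocks."""

    u: float  # driver mutation rate per division
    s: float  # selective advantage
    d: int  # number of sensitively mutated genes
    n_pop: float  # population size
    T: float = 1.0  # cell-division time (unit carried through to outputs)

    def __post_init__(self) -> None:
        if not (self.u > 0 and self.s > 0 and self.n_pop > 0 and self.T > 0):
            raise ValueError("u, s, n_pop and T must all be strictly positive")
        if not (isinstance(self.d, (int,)) and self.d >= 1):
            raise ValueError(f"d must be an integer >= 1, got {self.d!r}")


@dataclass(frozen=True)
class LesionPair:
    """F: later-lesion mutation fraction absent earlier; founder age in years."""

    F: float
    T_founder: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {self.F}")
        if self.T_founder < 0:
            raise ValueError(f"T_founder must be nonnegative, got {self.T_founder}")


@dataclass(frozen=True)
class ClockValue:
    """A clock estimate with its units and the formula interpretation used."""

    value: float
    units: str
    note: str

    def __float__(self) -> float:
        return self.value


def beerenwinkel_waiting_time(k: int, params: ComparisonParams) -> ClockValue:
    """Wright-Fisher clock: t_k = k ln(s/(u d^2)) / (2 s ln N), in generations."""
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    ratio = params.s / (params.u * params.d**2)
    if ratio <= 1.0:
        raise ParameterDomainError(
            f"s/(u*d^2) = {ratio:.6g} must exceed 1 for a positive log"
        )
    if params.n_pop <= 1.0:
        raise ParameterDomainError(f"n_pop = {params.n_pop:g} must exceed 1 (ln N > 0)")
    value = k * math.log(ratio) / (2.0 * params.s * math.log(params.n_pop))
    return ClockValue(
        value,
        "generations",
        "grouping t_k = k*ln(s/(u*d^2)) / (2*s*ln(N))",
    )


def bozic_waiting_time(k: int, s: float, u: float, T: float) -> ClockValue:
    """Branching-process clock: t_k = (T/(k s)) ln(2 k s / u), in T's unit.

    Deliberately independent of tumour size.  When u >= 2ks the log is
    nonpositive; a warning is issued and the (nonpositive) value returned.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not (s > 0 and u > 0 and T > 0):
        raise ValueError("s, u and T must be strictly positive")
    arg = 2.0 * k * s / u
    if arg <= 1.0:
        warnings.warn(
            f"2ks/u = {arg:.6g} <= 1: waiting time is nonpositive (mutation "
            f"supply outpaces selection in this grouping)",
            RuntimeWarning,
            stacklevel=2,
        )
    value = (T / (k * s)) * math.log(arg)
    return ClockValue(value, "same as T", "grouping t_k = (T/(k*s))*ln(2*k*s/u)")


def jones_interval(pair: LesionPair) -> ClockValue:
    """Comparative lesion sequencing: Delta-T = F * T_founder, in years."""
    return ClockValue(
        pair.F * pair.T_founder, "years", "Delta-T = F * T_founder (bilinear)"
    )


def growth_clock_time(n_target_cells: float, T_gen: float, r: float) -> ClockValue:
    """Exponential growth clock: time for 1 cell -> n cells at rate r/generation."""
    if n_target_cells < 1:
        raise ValueError(f"n_target_cells must be >= 1, got {n_target_cells}")
    if not (T_gen > 0 and r > 0):
        raise ValueError("T_gen and r must be strictly positive")
    value = T_gen * math.log(n_target_cells) / r
    return ClockValue(value, "same as T_gen", "t = T_gen * ln(n) / r")
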