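"""Minimum sample size for a cross-sectional prevalence survey.

The individual-level minimum is the classic normal-approximation formula with
a design effect,

    n0 = Z²_{1-α/2} · P(1-P) · Deff / e²,

and is then converted to households by dividing by the share of the target
population (under-fives), the mean household size, and the expected valid
response rate, with a single ceiling at the end:

    households = ceil( n0 / (p_target · hh_size) / valid_rate ).

At the study defaults (α=0.05, P=0.15, Deff=1.5, e=0.05, target share 0.15,
household size 4.5, valid rate 0.90) this yields 484 households, whether Z is
taken as the exact normal quantile or the conventionally printed 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import DomainError


@dataclass(frozen=True)
class SampleSizeParams:
    """Design parameters for the prevalence-survey sample size.

    alpha       type-I error for the normal quantile Z_{1-α/2}
    prevalence  expected outcome prevalence P in the target group
    deff        design effect (≥1) inflating for clustered sampling
    moe         margin of error e at the (1-α) confidence level
    p_target    share of the population in the target group (under-fives)
    hh_size     mean household size (persons)
    valid_rate  expected share of households with fully valid answers
    z_value     optional override for Z (e.g. the printed 1.96); when None,
                the exact normal quantile is used
    """

    alpha: float = 0.05
    prevalence: float = 0.15
    deff: float = 1.5
    moe: float = 0.05
    p_target: float = 0.15
    hh_size: float = 4.5
    valid_rate: float = 0.90
    z_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 <= self.prevalence <= 1:
            raise DomainError(f"prevalence must be in [0,1], got {self.prevalence}")
        if self.deff < 1:
            raise DomainError(f"design effect must be >= 1, got {self.deff}")
        if self.moe <= 0:
            raise DomainError(f"margin of error must be > 0, got {self.moe}")
        if not 0 < self.p_target <= 1:
            raise DomainError(f"p_target must be in (0,1], got {self.p_target}")
        if self.hh_size <= 0:
            raise DomainError(f"hh_size must be > 0, got {self.hh_size}")
        if not 0 < self.valid_rate <= 1:
            raise DomainError(f"valid_rate must be in (0,1], got {self.valid_rate}")

    @property
    def z(self) -> float:
        return self.z_value if self.z_value is not None else float(norm.ppf(1 - self.alpha / 2))


def base_individuals(params: SampleSizeParams) -> float:
    """Minimum number of individuals n0 (real-valued; rounding is deferred)."""
    z = params.z
    return z * z * params.prevalence * (1 - params.prevalence) * params.deff / params.moe**2


def households_required(n0: float, p_target: float, hh_size: float, valid_rate: float,
                        round_per_step: bool = False) -> int:
    """Convert the individual minimum into a minimum number of households.

    Default keeps fractional values through the adjustment chain and applies a
    single final ceiling; ``round_per_step`` ceilings after each adjustment
    instead (both give 484 at the study defaults).
    """
    if p_target <= 0 or hh_size <= 0 or valid_rate <= 0:
        raise DomainError("p_target, hh_size and valid_rate must be positive")
    if round_per_step:
        n = math.ceil(n0 / (p_target * hh_size))
        return math.ceil(n / valid_rate)
    return math.ceil(n0 / (p_target * hh_size) / valid_rate)


def minimum_households(params: SampleSizeParams | None = None,
                       round_per_step: bool = False) -> dict:
    """Full chain: returns ``{"n0": ..., "households": ...}``."""
    params = params or SampleSizeParams()
    n0 = base_individuals(params)
    return {
        "n0": n0,
        "households": households_required(
            n0, params.p_target, params.hh_size, params.valid_rate, round_per_step
        ),
    }
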