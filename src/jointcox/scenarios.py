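"""Scenario definitions for the simulation study.

A scenario fixes every ingredient of one simulation set: the fixed effects of
the latent linear trajectory, the covariance of the subject-level random
intercept/slope, the measurement-error variance, the log-linear hazard
parameters, the missingness regime and the sample sizes.  The full study is a
grid of 32 zero-group-effect sets (2 fixed slopes x 4 random-effect
covariance forms x 2 error variances x 2 missingness patterns) plus 4 extra
sets that clone the worst-performing sets with a non-zero group effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "RandomEffectsCov",
    "SimScenario",
    "COV_FORMS",
    "scenario_grid",
    "get_scenario",
]

Missingness = Literal["monotone", "nonmonotone"]


@dataclass(frozen=True)
class RandomEffectsCov:
    """2x2 covariance of the random intercept b0 and random slope b1."""

    var_b0: float
    var_b1: float
    cov_b0b1: float

    def __post_init__(self) -> None:
        if self.var_b0 <= 0 or self.var_b1 <= 0:
            raise ValueError("random-effect variances must be positive")
        if self.cov_b0b1**2 > self.var_b0 * self.var_b1:
            raise ValueError("covariance matrix is not positive semi-definite")

    @property
    def correlation(self) -> float:
        return self.cov_b0b1 / math.sqrt(self.var_b0 * self.var_b1)

    def as_matrix(self):
        import numpy as np

        return np.array(
            [[self.var_b0, self.cov_b0b1], [self.cov_b0b1, self.var_b1]]
        )


#: The four covariance forms used in the study: large/small variances crossed
#: with large/small intercept-slope correlation.
COV_FORMS: dict[str, RandomEffectsCov] = {
    "a": RandomEffectsCov(32.0, 0.002, 0.06),
    "b": RandomEffectsCov(32.0, 0.002, 0.02),
    "c": RandomEffectsCov(8.0, 0.0005, 0.02),
    "d": RandomEffectsCov(8.0, 0.0005, 0.002),
}


@dataclass(frozen=True)
class SimScenario:
    """Complete parameterization of one simulation set.

    The latent predictor for subject i follows
    ``m_i(t) = a0 + a1*t + b0_i + b1_i*t`` with (b0, b1) bivariate normal,
    observed at visits with N(0, error_var) noise, and the daily hazard is
    ``h_i(t) = exp(lambda0 + lambda1*m_i(t) + tau*u_i)`` with u_i the group
    indicator.  Time is measured in days on a ~one-year horizon with
    ~monthly visits.
    """

    a0: float = 40.0
    a1: float = 0.02
    cov: RandomEffectsCov = field(default_factory=lambda: COV_FORMS["a"])
    error_var: float = 16.0
    lambda0: float = -4.8
    lambda1: float = -0.03
    tau: float = 0.0
    missingness: Missingness = "monotone"
    n_per_group: int = 150
    n_groups: int = 2
    horizon_days: int = 365  # days 0..364
    visit_interval: int = 30
    window_days: int = 7
    seed: int = 0
    set_id: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        if self.missingness not in ("monotone", "nonmonotone"):
            raise ValueError(f"unknown missingness regime {self.missingness!r}")

    @property
    def n_subjects(self) -> int:
        return self.n_per_group * self.n_groups

    @property
    def last_day(self) -> int:
        return self.horizon_days - 1

    @property
    def n_nominal_postbaseline(self) -> int:
        # 12 for the default 30-day grid on a 365-day horizon
        return self.last_day // self.visit_interval


def scenario_grid(seed: int = 0) -> list[SimScenario]:
    """Build the 36 study scenarios in their canonical numbering.

    Sets 1-16 use monotone missingness and 17-32 the non-monotone regime;
    within each block the error variance varies slowest (16 then 4), then the
    fixed slope (0.02 then 0.1), then the covariance form (a, b, c, d).
    Sets 33-36 repeat sets 3, 7, 19 and 23 with group effect tau = -0.5.
    """
    grid: list[SimScenario] = []
    set_id = 1
    for missingness in ("monotone", "nonmonotone"):
        for error_var in (16.0, 4.0):
            for a1 in (0.02, 0.1):
                for form in ("a", "b", "c", "d"):
                    grid.append(
                        SimScenario(
                            a1=a1,
                            cov=COV_FORMS[form],
                            error_var=error_var,
                            missingness=missingness,  # type: ignore[arg-type]
                            seed=seed,
                            set_id=set_id,
                        )
                    )
                    set_id += 1
    for base in (3, 7, 19, 23):
        grid.append(replace(grid[base - 1], tau=-0.5, set_id=set_id))
        set_id += 1
    return grid


def get_scenario(set_id: int, seed: int = 0) -> SimScenario:
    """Return scenario ``set_id`` (1-36) with the given root seed."""
    if not 1 <= set_id <= 36:
        raise ValueError("set_id must be in 1..36")
    return scenario_grid(seed=seed)[set_id - 1]
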