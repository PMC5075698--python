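"""Synthetic longitudinal + time-to-event data generator.

Each subject carries a latent linear trajectory ``m(t) = a0 + a1*t + b0 +
b1*t`` (random intercept/slope, bivariate normal) observed with Gaussian
error at ~monthly visits, and a daily hazard ``h(t) = exp(lambda0 +
lambda1*m(t) + tau*u)``.  Event times are drawn from the piecewise
exponential distribution with that day-by-day hazard: within day t the
hazard is constant at h(t), so survival to day k is exp(-sum_{t<k} h(t)) and
event times are continuous.  Censoring is uniform on [1, 364] under the
monotone regime; under the non-monotone regime visits are jittered within a
+/-7-day window, a random subset of occasions is missing, and censoring is
the day of the last non-missing assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import RandomEffectsCov, SimScenario

__all__ = [
    "SubjectRecord",
    "SimDataset",
    "true_trajectory",
    "draw_random_effects",
    "daily_hazard",
    "draw_event_time",
    "draw_censoring_monotone",
    "observe_monotone",
    "observe_nonmonotone",
    "simulate_dataset",
    "replicate_rng",
]


@dataclass
class SubjectRecord:
    """One simulated subject: latent effects, outcome and observed visits."""

    subject_id: int
    group: int
    b0: float
    b1: float
    event_time: float
    status: int
    visits: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in (0, 1):
            raise ValueError("status must be 0 or 1")
        days = [d for d, _ in self.visits]
        if days != sorted(set(days)):
            raise ValueError("visits must be strictly increasing in day")
        if self.status == 1 and days and days[-1] >= self.event_time:
            raise ValueError("post-event visits must be discarded")

    @property
    def visit_days(self) -> list[float]:
        return [d for d, _ in self.visits]

    @property
    def visit_values(self) -> list[float]:
        return [v for _, v in self.visits]


@dataclass
class SimDataset:
    """One simulated replicate of a scenario."""

    scenario: SimScenario
    subjects: list[SubjectRecord]
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if len(self.subjects) != self.scenario.n_subjects:
            raise ValueError("wrong number of subjects for scenario")

    def to_longitudinal_frame(self) -> pd.DataFrame:
        rows = [
            (s.subject_id, d, v)
            for s in self.subjects
            for d, v in s.visits
        ]
        return pd.DataFrame(rows, columns=["subject_id", "day", "value"])

    def to_survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "time": [s.event_time for s in self.subjects],
                "status": [s.status for s in self.subjects],
            }
        )


def true_trajectory(
    scenario: SimScenario, b0: float, b1: float, t
) -> np.ndarray | float:
    """Latent predictor value m(t) = a0 + a1*t + b0 + b1*t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > scenario.last_day):
        raise ValueError(f"t must lie in [0, {scenario.last_day}]")
    out = scenario.a0 + scenario.a1 * t + b0 + b1 * t
    return out if out.ndim else float(out)


def draw_random_effects(
    cov: RandomEffectsCov, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n (b0, b1) pairs from the bivariate normal N(0, cov)."""
    return rng.multivariate_normal(
        np.zeros(2), cov.as_matrix(), size=n, method="cholesky"
    )


def daily_hazard(
    scenario: SimScenario, b0: float, b1: float, group: int, t
) -> np.ndarray | float:
    """Hazard h(t) = exp(lambda0 + lambda1*m(t) + tau*u); strictly positive."""
    m = true_trajectory(scenario, b0, b1, t)
    out = np.exp(scenario.lambda0 + scenario.lambda1 * np.asarray(m) + scenario.tau * group)
    return out if out.ndim else float(out)


def draw_event_time(
    scenario: SimScenario,
    b0: float,
    b1: float,
    group: int,
    rng: np.random.Generator,
) -> float | None:
    """Draw one event time under the day-by-day piecewise-exponential scheme.

    For each integer day t the waiting time w ~ Exponential(rate=h(t)) is
    drawn; if w <= 1 the event occurs at t + w, otherwise the clock advances
    one day.  Returns None if no event occurs by the end of the horizon.
    """
    for t in range(scenario.horizon_days):
        h = daily_hazard(scenario, b0, b1, group, t)
        w = rng.exponential(1.0 / h)
        if w <= 1.0:
            return t + w
    return None


def _draw_event_times_vec(
    scenario: SimScenario,
    b: np.ndarray,
    group: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized event-time draw; np.inf marks no event within the horizon.

    Equivalent to per-day Exponential(h(t)) waiting times: with E ~ Exp(1),
    w = E/h(t) and the event triggers on the first day where E <= h(t).
    """
    n = len(b)
    days = np.arange(scenario.horizon_days)
    m = scenario.a0 + scenario.a1 * days + b[:, :1] + b[:, 1:] * days
    h = np.exp(scenario.lambda0 + scenario.lambda1 * m + scenario.tau * group[:, None])
    e = rng.standard_exponential((n, scenario.horizon_days))
    hit = e <= h
    times = np.full(n, np.inf)
    any_hit = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    idx = np.flatnonzero(any_hit)
    times[idx] = first[idx] + e[idx, first[idx]] / h[idx, first[idx]]
    return times


def draw_censoring_monotone(
    rng: np.random.Generator, size: int | None = None
) -> np.ndarray | float:
    """Censoring time(s) ~ continuous Uniform(1, 364)."""
    out = rng.uniform(1.0, 364.0, size=size)
    return out


def _observe(
    scenario: SimScenario,
    b0: float,
    b1: float,
    days: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    m = scenario.a0 + scenario.a1 * days + b0 + b1 * days
    noise = rng.normal(0.0, np.sqrt(scenario.error_var), size=len(days))
    return list(zip((days.astype(float)).tolist(), (m + noise).tolist()))


def observe_monotone(
    scenario: SimScenario,
    subject_id: int,
    group: int,
    b0: float,
    b1: float,
    recorded_time: float,
    status: int,
    rng: np.random.Generator,
) -> SubjectRecord:
    """Observe the trajectory on the regular 0, 30, 60, ... visit grid.

    Visits run up to the last scheduled occasion strictly before the
    recorded event/censoring time; post-event and post-censoring data are
    discarded.
    """
    grid = np.arange(0, scenario.horizon_days, scenario.visit_interval)
    days = grid[grid < recorded_time]
    if len(days) == 0:
        days = grid[:1]  # baseline is always observed
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        b0=b0,
        b1=b1,
        event_time=recorded_time,
        status=status,
        visits=_observe(scenario, b0, b1, days, rng),
    )


def observe_nonmonotone(
    scenario: SimScenario,
    subject_id: int,
    group: int,
    b0: float,
    b1: float,
    event_time: float,
    rng: np.random.Generator,
) -> SubjectRecord:
    """Observe under haphazard missingness with jittered assessment days.

    The 12 nominal post-baseline occasions are each moved by an integer
    drawn uniformly from [-7, 7]; a uniformly-sized random subset (0..12) of
    occasions is missing; the censoring time is the day of the last
    non-missing assessment unless the event occurred earlier.  Pass
    ``event_time=np.inf`` when no event occurred within the horizon.
    """
    k = scenario.n_nominal_postbaseline
    nominal = scenario.visit_interval * np.arange(1, k + 1)
    jitter = rng.integers(-scenario.window_days, scenario.window_days + 1, size=k)
    actual = nominal + jitter
    n_missing = int(rng.integers(0, k + 1))
    missing = rng.choice(k, size=n_missing, replace=False)
    keep = np.ones(k, dtype=bool)
    keep[missing] = False
    observed_days = np.sort(actual[keep]).astype(float)

    censor = float(observed_days[-1]) if len(observed_days) else 0.0
    if event_time <= censor:
        status, time = 1, float(event_time)
    else:
        status, time = 0, censor

    days = observed_days[observed_days < time] if status == 1 else observed_days
    days = np.concatenate([[0.0], days])
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        b0=b0,
        b1=b1,
        event_time=time,
        status=status,
        visits=_observe(scenario, b0, b1, days, rng),
    )


def replicate_rng(scenario: SimScenario, replicate_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate of one scenario."""
    key = (int(scenario.seed), int(scenario.set_id or 0), int(replicate_index))
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_dataset(scenario: SimScenario, replicate_index: int = 0) -> SimDataset:
    """Generate one complete replicate of a scenario.

    Subjects are split evenly between the two groups; event times come from
    the piecewise-exponential scheme, censoring from the regime the scenario
    prescribes, and observed visits carry measurement error.
    """
    rng = replicate_rng(scenario, replicate_index)
    n = scenario.n_subjects
    group = np.repeat(np.arange(scenario.n_groups), scenario.n_per_group)
    b = draw_random_effects(scenario.cov, n, rng)
    T = _draw_event_times_vec(scenario, b, group, rng)

    subjects: list[SubjectRecord] = []
    if scenario.missingness == "monotone":
        C = np.asarray(draw_censoring_monotone(rng, size=n))
        for i in range(n):
            if T[i] <= C[i]:
                time, status = T[i], 1
            else:
                time, status = C[i], 0
            subjects.append(
                observe_monotone(
                    scenario, i + 1, int(group[i]), b[i, 0], b[i, 1], time, status, rng
                )
            )
    else:
        for i in range(n):
            subjects.append(
                observe_nonmonotone(
                    scenario, i + 1, int(group[i]), b[i, 0], b[i, 1], T[i], rng
                )
            )
    return SimDataset(scenario=scenario, subjects=subjects, replicate_index=replicate_index)
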