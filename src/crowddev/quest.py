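"""QUEST adaptive staircase with child-friendly modifications.

A standard QUEST staircase maintains a Bayesian posterior over the log10
threshold and places each trial at the running posterior-mean estimate,
assuming a Weibull psychometric function (here with 4AFC guessing rate 0.25
and a small assumed lapse).  Four modifications make it suitable for
testing young children:

1. Five practice trials at a large fixed gap (5.3 arcmin) begin each block;
   if fewer than the pass criterion are answered correctly the block is
   restarted (up to a restart limit), mirroring re-explanation of the task.
2. Easy *catch* trials are inserted on trials 5, 15, 25 and 35, presented at
   triple the current threshold estimate, to monitor attention.
3. Thresholds are not taken from the staircase itself but from a later
   psychometric-function refit of the full trial log (see ``crowddev.psychfit``).
4. Non-catch stimulus sizes are jittered with Gaussian noise whose standard
   deviation is half the current estimate, widening the sampled size range
   for that refit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .observer import CONDITIONS, ObserverModel, Participant, simulate_trial

__all__ = [
    "QuestConfig",
    "QuestState",
    "TrialRecord",
    "BlockResult",
    "NoncomplianceError",
    "quest_init",
    "quest_update",
    "quest_estimate",
    "next_gap",
    "run_block",
    "run_session",
]


class NoncomplianceError(RuntimeError):
    """Raised when a simulated observer repeatedly fails the practice trials.

    Mirrors the exclusion of participants who could not perform the task
    even after re-explanation.
    """


@dataclass(frozen=True)
class QuestConfig:
    """Parameters of the staircase and its child-friendly modifications."""

    prior_guess: float = 2.0  # arcmin; centre of the threshold prior
    prior_sd: float = 0.4  # log10 units
    grid_min: float = -1.5  # log10 arcmin
    grid_max: float = 1.6  # log10 arcmin
    grid_points: int = 201
    beta: float = 3.5  # assumed Weibull slope
    assumed_lapse: float = 0.01
    chance: float = 0.25
    criterion: float = 0.625
    n_trials: int = 35
    practice_trials: int = 5
    practice_gap: float = 5.3  # arcmin
    catch_schedule: tuple[int, ...] = (5, 15, 25, 35)
    catch_multiplier: float = 3.0
    jitter_sd_fraction: float = 0.5
    jitter_floor_fraction: float = 0.1
    update_on_catch: bool = True
    practice_pass_min: int = 4
    max_restarts: int = 3

    def __post_init__(self) -> None:
        if self.grid_points < 50:
            raise ValueError("grid too coarse: need at least 50 points")
        if not self.prior_guess > 0:
            raise ValueError("prior_guess must be positive")
        lo = math.log10(self.prior_guess) - 3 * self.prior_sd
        hi = math.log10(self.prior_guess) + 3 * self.prior_sd
        if self.grid_min > lo or self.grid_max < hi:
            raise ValueError(
                "grid must cover prior_guess +/- 3 prior_sd in log10 units: "
                f"need [{lo:.3f}, {hi:.3f}], have [{self.grid_min}, {self.grid_max}]"
            )
        if abs(self.criterion - (self.chance + 1.0) / 2.0) > 1e-9:
            raise ValueError("criterion must be midway between chance and ceiling")
        if any(not 1 <= t <= self.n_trials for t in self.catch_schedule):
            raise ValueError("catch_schedule must lie within [1, n_trials]")

    @property
    def weibull_offset(self) -> float:
        """log10 offset ``c`` such that the assumed Weibull passes through the
        convergence criterion exactly at the threshold parameter.

        Solves ``lapse*chance + (1-lapse)*(1 - (1-chance)*exp(-10**c)) = criterion``.
        """
        p_core = (self.criterion - self.assumed_lapse * self.chance) / (1.0 - self.assumed_lapse)
        return math.log10(-math.log((1.0 - p_core) / (1.0 - self.chance)))


@dataclass(frozen=True)
class QuestState:
    """Posterior over log10 threshold. Immutable; updates return new states."""

    grid: np.ndarray  # log10 gap values
    posterior: np.ndarray  # probability mass, sums to 1
    trial_count: int
    config: QuestConfig

    def entropy(self) -> float:
        p = self.posterior[self.posterior > 0]
        return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    phase: str  # "practice" | "main"
    is_catch: bool
    nominal_estimate: float  # arcmin; running estimate before the trial
    presented_gap: float  # arcmin
    correct: bool


@dataclass(frozen=True)
class BlockResult:
    condition: str
    records: tuple[TrialRecord, ...]
    final_state: QuestState
    n_restarts: int = 0

    @property
    def main_records(self) -> tuple[TrialRecord, ...]:
        return tuple(r for r in self.records if r.phase == "main")


def quest_init(config: QuestConfig) -> QuestState:
    """Gaussian prior over log10 threshold, centred on ``prior_guess``."""
    grid = np.linspace(config.grid_min, config.grid_max, config.grid_points)
    z = (grid - math.log10(config.prior_guess)) / config.prior_sd
    posterior = np.exp(-0.5 * z * z)
    posterior /= posterior.sum()
    return QuestState(grid=grid, posterior=posterior, trial_count=0, config=config)


def _p_correct_given_threshold(state: QuestState, log_gap: float) -> np.ndarray:
    """Assumed Weibull likelihood of a correct response at ``log_gap`` for
    every candidate threshold on the grid."""
    cfg = state.config
    x = cfg.beta * (log_gap - state.grid) + cfg.weibull_offset
    p = 1.0 - (1.0 - cfg.chance) * np.exp(-np.power(10.0, x))
    return cfg.assumed_lapse * cfg.chance + (1.0 - cfg.assumed_lapse) * p


def quest_update(state: QuestState, presented_gap: float, correct: bool) -> QuestState:
    """Bayes update of the posterior after one observed outcome."""
    if not presented_gap > 0:
        raise ValueError("presented_gap must be positive")
    p = _p_correct_given_threshold(state, math.log10(presented_gap))
    likelihood = p if correct else 1.0 - p
    posterior = state.posterior * likelihood
    total = posterior.sum()
    if not total > 0:
        raise FloatingPointError("posterior underflow in quest_update")
    return replace(state, posterior=posterior / total, trial_count=state.trial_count + 1)


def quest_estimate(state: QuestState) -> float:
    """Threshold estimate: 10 ** (posterior mean of log10 gap)."""
    return float(10.0 ** np.dot(state.posterior, state.grid))


def next_gap(
    state: QuestState,
    trial_index: int,
    phase: str,
    rng: np.random.Generator,
    config: QuestConfig | None = None,
    estimate: float | None = None,
) -> tuple[float, bool]:
    """Stimulus placement rule. Returns ``(presented_gap, is_catch)``.

    Practice trials use the fixed large practice gap.  Catch trials present
    triple the running estimate with no jitter.  All other main trials
    jitter the estimate with Gaussian noise (SD = ``jitter_sd_fraction`` of
    the estimate), clamped below at ``jitter_floor_fraction`` of the
    estimate to keep sizes positive.

    One jitter draw is consumed per non-catch main trial regardless of
    clamping, keeping the rng stream aligned across runs.
    """
    cfg = config or state.config
    if trial_index < 1:
        raise ValueError("trial_index starts at 1")
    if phase == "practice":
        return cfg.practice_gap, False
    est = quest_estimate(state) if estimate is None else estimate
    if trial_index in cfg.catch_schedule:
        return cfg.catch_multiplier * est, True
    gap = est + rng.normal(0.0, cfg.jitter_sd_fraction * est)
    return max(gap, cfg.jitter_floor_fraction * est), False


def run_block(
    observer: ObserverModel,
    config: QuestConfig,
    rng: np.random.Generator,
    condition: str = "unflanked",
) -> BlockResult:
    """Run one staircase block: practice phase, then the scored main trials.

    The practice phase repeats (fresh trials, same fixed gap) if fewer than
    ``practice_pass_min`` of ``practice_trials`` are correct, up to
    ``max_restarts`` restarts; beyond that a :class:`NoncomplianceError` is
    raised.  Only the passing attempt's practice records are retained.
    Practice trials never update the posterior.  Catch trials update it only
    when ``update_on_catch`` is set (default on: their outcomes are
    informative and they are kept for the later psychometric refit).
    """
    state = quest_init(config)

    n_restarts = 0
    while True:
        practice: list[TrialRecord] = []
        for i in range(1, config.practice_trials + 1):
            gap, _ = next_gap(state, i, "practice", rng, config)
            correct = simulate_trial(observer, gap, rng)
            practice.append(
                TrialRecord(
                    trial_index=i,
                    phase="practice",
                    is_catch=False,
                    nominal_estimate=quest_estimate(state),
                    presented_gap=gap,
                    correct=correct,
                )
            )
        if sum(r.correct for r in practice) >= config.practice_pass_min:
            break
        n_restarts += 1
        if n_restarts > config.max_restarts:
            raise NoncomplianceError(
                f"practice failed {n_restarts} times (< {config.practice_pass_min}"
                f"/{config.practice_trials} correct); simulated participant excluded"
            )

    records = list(practice)
    for i in range(1, config.n_trials + 1):
        est = quest_estimate(state)
        gap, is_catch = next_gap(state, i, "main", rng, config, estimate=est)
        correct = simulate_trial(observer, gap, rng)
        records.append(
            TrialRecord(
                trial_index=i,
                phase="main",
                is_catch=is_catch,
                nominal_estimate=est,
                presented_gap=gap,
                correct=correct,
            )
        )
        if not is_catch or config.update_on_catch:
            state = quest_update(state, gap, correct)

    return BlockResult(
        condition=condition, records=tuple(records), final_state=state, n_restarts=n_restarts
    )


def _condition_order(conditions: Iterable[str]) -> list[str]:
    """Canonical administration order: unflanked always first."""
    conds = list(conditions)
    unknown = set(conds) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    return [c for c in CONDITIONS if c in conds]


def run_session(
    participant: Participant,
    conditions: Sequence[str],
    blocks_per_condition: int,
    rng: np.random.Generator,
    config: QuestConfig | None = None,
):
    """Run every block for one participant and return the trial-log table.

    Conditions are administered in canonical order (unflanked first), each
    as ``blocks_per_condition`` independent staircase blocks.  Returns a
    :class:`pandas.DataFrame` with the trial-log schema used throughout the
    package.
    """
    import pandas as pd

    if blocks_per_condition < 1:
        raise ValueError("blocks_per_condition must be >= 1")
    cfg = config or QuestConfig()
    rows = []
    for cond in _condition_order(conditions):
        for block in range(1, blocks_per_condition + 1):
            result = run_block(participant.observer(cond), cfg, rng, condition=cond)
            for r in result.records:
                rows.append(
                    {
                        "participant_id": participant.id,
                        "age_years": participant.age,
                        "condition": cond,
                        "block": block,
                        "trial_index": r.trial_index,
                        "phase": r.phase,
                        "is_catch": r.is_catch,
                        "nominal_estimate_arcmin": r.nominal_estimate,
                        "presented_gap_arcmin": r.presented_gap,
                        "correct": r.correct,
                    }
                )
    return pd.DataFrame(rows)
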