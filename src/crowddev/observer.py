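"""Simulated 4AFC observers and developmental cohorts.

The analysis pipeline in this package is exercised end-to-end against
simulated observers rather than human participants.  Each observer responds
to a gap-identification task (which of four orientations a Landolt-C-like
"mouth" gap faces) according to a cumulative-Gaussian psychometric function
rising from the 4AFC chance level (25 %) to ceiling.  The *threshold* is
defined throughout as the gap size yielding 62.5 % correct — midway between
chance and ceiling — which for this parameterization coincides with the
Gaussian midpoint ``mu``.

Cohorts of observers follow logistic developmental trajectories: thresholds
are elevated in young children and decline to an adult asymptote, with
separate trajectories for unflanked (acuity), flanked same-polarity
(crowding) and flanked opposite-polarity (release from crowding) conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "CONDITIONS",
    "ObserverModel",
    "TrajectoryParams",
    "CohortSpec",
    "Participant",
    "psychometric_probability",
    "simulate_trial",
    "simulate_trials",
    "true_threshold_at_age",
    "generate_cohort",
    "cohort_to_frame",
    "DEFAULT_UNFLANKED",
    "DEFAULT_FLANKED_SAME",
]

#: Canonical condition labels, in the order blocks are administered.
CONDITIONS = ("unflanked", "flanked_same", "flanked_different")


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth psychometric function of one simulated observer.

    Parameters
    ----------
    threshold_gap:
        Gap size (arcmin) at which the lapse-free curve reaches the 62.5 %
        criterion.  Because performance runs from 25 % to 100 %, this is
        exactly the midpoint ``mu`` of the underlying cumulative Gaussian.
    slope_sigma:
        Standard deviation (arcmin) of the underlying Gaussian; smaller is
        steeper.
    lapse_rate:
        Probability of a stimulus-independent attentional lapse, on which
        the observer guesses at chance.
    chance_rate:
        Guessing rate; 0.25 for the 4AFC task.
    """

    threshold_gap: float
    slope_sigma: float
    lapse_rate: float = 0.0
    chance_rate: float = 0.25

    def __post_init__(self) -> None:
        if not self.threshold_gap > 0:
            raise ValueError(f"threshold_gap must be positive, got {self.threshold_gap}")
        if not self.slope_sigma > 0:
            raise ValueError(f"slope_sigma must be positive, got {self.slope_sigma}")
        if not 0.0 <= self.lapse_rate <= 0.06:
            raise ValueError(f"lapse_rate must lie in [0, 0.06], got {self.lapse_rate}")
        if not 0.0 < self.chance_rate < 1.0:
            raise ValueError(f"chance_rate must lie in (0, 1), got {self.chance_rate}")


def psychometric_probability(observer: ObserverModel, gap) -> np.ndarray | float:
    """Probability of a correct response at ``gap`` arcmin.

    The lapse-free curve is ``chance + (1 - chance) * Phi((gap - mu) / sigma)``;
    lapses mix it toward chance: ``p = (1 - lapse) * p_core + lapse * chance``.
    Monotone non-decreasing in ``gap`` and bounded in
    ``[chance, 1 - lapse * (1 - chance)]``.
    """
    c = observer.chance_rate
    if np.isscalar(gap) or getattr(gap, "ndim", None) == 0:
        g = float(gap)
        if g < 0:
            raise ValueError("gap must be non-negative")
        z = (g - observer.threshold_gap) / observer.slope_sigma
        p_core = c + (1.0 - c) * 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
        return (1.0 - observer.lapse_rate) * p_core + observer.lapse_rate * c
    gap = np.asarray(gap, dtype=float)
    if np.any(gap < 0):
        raise ValueError("gap must be non-negative")
    z = (gap - observer.threshold_gap) / observer.slope_sigma
    p_core = c + (1.0 - c) * ndtr(z)
    return (1.0 - observer.lapse_rate) * p_core + observer.lapse_rate * c


def simulate_trial(observer: ObserverModel, gap: float, rng: np.random.Generator) -> bool:
    """One Bernoulli response draw at ``gap``."""
    return bool(rng.random() < psychometric_probability(observer, gap))


def simulate_trials(
    observer: ObserverModel, gap, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized convenience: ``n`` independent responses at ``gap``."""
    p = psychometric_probability(observer, gap)
    return rng.random(n) < p


@dataclass(frozen=True)
class TrajectoryParams:
    """Logistic developmental trajectory of a threshold.

    ``threshold(age) = adult_asymptote + child_elevation / (1 + exp((age - midpoint_age) / steepness))``

    so thresholds fall from ``adult_asymptote + child_elevation`` at the
    youngest ages to ``adult_asymptote`` in adulthood.
    """

    adult_asymptote: float  # arcmin
    child_elevation: float  # arcmin added at the youngest ages
    midpoint_age: float  # years
    steepness: float  # years
    between_subject_cv: float = 0.25

    def __post_init__(self) -> None:
        if not self.adult_asymptote > 0:
            raise ValueError("adult_asymptote must be positive")
        if self.child_elevation < 0:
            raise ValueError("child_elevation must be non-negative")
        if not self.steepness > 0:
            raise ValueError("steepness must be positive")


def true_threshold_at_age(age, params: TrajectoryParams) -> np.ndarray | float:
    """Evaluate the generative logistic trajectory at ``age`` (years)."""
    age = np.asarray(age, dtype=float)
    out = params.adult_asymptote + params.child_elevation / (
        1.0 + np.exp((age - params.midpoint_age) / params.steepness)
    )
    return float(out) if out.ndim == 0 else out


# Default trajectory calibration.  The absolute scale (adult unflanked
# asymptote 0.8') is a documented convention; the calibrated anchors are the
# ratios: flanked-same / unflanked thresholds ~2.0 at age 3.8 and ~1.4 in
# adults, with acuity maturing by 5-6 years and crowding by 7-8 years.
DEFAULT_UNFLANKED = TrajectoryParams(
    adult_asymptote=0.8, child_elevation=0.6, midpoint_age=4.0, steepness=0.8
)
DEFAULT_FLANKED_SAME = TrajectoryParams(
    adult_asymptote=1.12, child_elevation=1.36, midpoint_age=5.2, steepness=0.8
)

#: Default child group structure: (label, low age, high age, n).
DEFAULT_CHILD_GROUPS = (
    ("3-4", 3.0, 5.0, 10),
    ("5-6", 5.0, 7.0, 22),
    ("7-8", 7.0, 9.0, 24),
    ("9-10", 9.0, 11.0, 14),
    ("11-12", 11.0, 13.0, 19),
)
DEFAULT_ADULT_GROUP = ("adult", 18.0, 38.0, 30)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    ``groups`` is a sequence of ``(label, age_low, age_high, n)``; the default
    reproduces the study structure of 10/22/24/14/19 children across the
    3-4 ... 11-12 year ranges plus 30 adults.  Ages are drawn uniformly
    within each range.

    Per-participant scatter is lognormal (mean 1, coefficient of variation
    ``between_subject_cv`` from the unflanked trajectory) applied to the
    unflanked threshold; the flanked-same threshold is generated through a
    crowding *ratio* (clamped at >= 1) so the ordering
    ``unflanked <= flanked_different <= flanked_same`` holds by construction.
    ``flanked_different`` sits a fraction ``release_fraction`` of the way down
    from flanked-same toward unflanked (0.5 = halfway, i.e. 50 % release); if
    ``flanked_different_params`` is supplied, the trajectory value is used
    instead, clamped into ``[unflanked, flanked_same]``.
    """

    groups: Sequence[tuple[str, float, float, int]] = field(
        default_factory=lambda: DEFAULT_CHILD_GROUPS + (DEFAULT_ADULT_GROUP,)
    )
    unflanked_params: TrajectoryParams = DEFAULT_UNFLANKED
    flanked_same_params: TrajectoryParams = DEFAULT_FLANKED_SAME
    flanked_different_params: TrajectoryParams | None = None
    release_fraction: float = 0.5
    ratio_cv: float = 0.12
    slope_fraction: float = 0.3
    lapse_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("CohortSpec.groups must contain at least one group")
        for label, lo, hi, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} has n={n}; all n must be >= 1")
            if not hi >= lo:
                raise ValueError(f"group {label!r} has empty age range [{lo}, {hi}]")
        if not 0.0 <= self.release_fraction <= 1.0:
            raise ValueError("release_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Participant:
    """One simulated participant: an age plus one observer per condition."""

    id: str
    age: float
    group: str
    observers: dict[str, ObserverModel]

    def observer(self, condition: str) -> ObserverModel:
        try:
            return self.observers[condition]
        except KeyError:
            raise KeyError(f"participant {self.id} has no condition {condition!r}") from None


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Draw from a lognormal with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2)))


def generate_cohort(spec: CohortSpec) -> list[Participant]:
    """Generate the cohort described by ``spec``, reproducibly under its seed.

    Each participant derives from an independent child of the spec's seed
    sequence, so cohorts are stable under seed and participant count changes
    in earlier groups do not perturb later participants' draws within their
    own stream.
    """
    participants: list[Participant] = []
    pid = 0
    for g_idx, (label, lo, hi, n) in enumerate(spec.groups):
        group_ss = np.random.SeedSequence((spec.seed, g_idx))
        for k, child_ss in enumerate(group_ss.spawn(n)):
            rng = np.random.default_rng(child_ss)
            age = float(rng.uniform(lo, hi))
            u_true = true_threshold_at_age(age, spec.unflanked_params)
            fs_true = true_threshold_at_age(age, spec.flanked_same_params)
            u = u_true * _lognormal_factor(rng, spec.unflanked_params.between_subject_cv)
            ratio = max(1.0, (fs_true / u_true) * _lognormal_factor(rng, spec.ratio_cv))
            fs = u * ratio
            if spec.flanked_different_params is not None:
                fd_raw = true_threshold_at_age(
                    age, spec.flanked_different_params
                ) * _lognormal_factor(rng, spec.flanked_different_params.between_subject_cv)
                fd = float(np.clip(fd_raw, u, fs))
            else:
                fd = fs - spec.release_fraction * (fs - u)
            observers = {
                cond: ObserverModel(
                    threshold_gap=t,
                    slope_sigma=spec.slope_fraction * t,
                    lapse_rate=spec.lapse_rate,
                )
                for cond, t in zip(CONDITIONS, (u, fs, fd))
            }
            participants.append(
                Participant(id=f"P{pid:03d}", age=age, group=label, observers=observers)
            )
            pid += 1
    return participants


def cohort_to_frame(participants: Sequence[Participant]):
    """Long-format table of true thresholds (one row per participant x condition)."""
    import pandas as pd

    rows = []
    for p in participants:
        for cond, obs in p.observers.items():
            rows.append(
                {
                    "participant_id": p.id,
                    "age_years": p.age,
                    "group": p.group,
                    "condition": cond,
                    "true_threshold_arcmin": obs.threshold_gap,
                }
            )
    return pd.DataFrame(rows)
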