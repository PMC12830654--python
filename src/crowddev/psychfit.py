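"""Trial-weighted psychometric fitting of staircase logs.

Because the staircase jitters stimulus sizes, thresholds are not read off
the staircase posterior.  Instead, for each participant and condition the
repeated blocks are combined, responses are collated into size bins
(practice excluded, catch trials included), and a cumulative Gaussian

    p(s) = chance + (1 - chance) * Phi((s - mu) / sigma)

with two free parameters (midpoint ``mu`` and slope ``sigma``) is fitted by
least squares weighted by the number of trials in each bin.  The threshold
is the size where the fitted curve reaches the 62.5 % criterion — midway
between the 25 % guessing rate and ceiling — which is ``mu`` itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import ndtr
from scipy.stats import norm

__all__ = [
    "CollatedData",
    "PsychometricFit",
    "FitError",
    "collate_trials",
    "fit_weighted_cumgauss",
    "threshold_at_criterion",
    "catch_trial_score",
    "fit_thresholds",
]

DEFAULT_BIN_WIDTH = 0.25  # arcmin
DEFAULT_CHANCE = 0.25
DEFAULT_CRITERION = 0.625


class FitError(RuntimeError):
    """Raised when no optimization start converges to a usable fit."""


@dataclass(frozen=True)
class CollatedData:
    """Size-binned response counts: parallel arrays sorted by gap."""

    gap: np.ndarray  # bin centres, arcmin
    n_trials: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.n_correct > self.n_trials):
            raise ValueError("n_correct cannot exceed n_trials")
        if np.any(np.diff(self.gap) <= 0):
            raise ValueError("bins must be sorted ascending and distinct")

    @property
    def proportion_correct(self) -> np.ndarray:
        return self.n_correct / self.n_trials


@dataclass(frozen=True)
class PsychometricFit:
    midpoint_mu: float  # arcmin
    slope_sigma: float  # arcmin
    weighted_sse: float
    n_points: int
    chance: float = DEFAULT_CHANCE

    def predict(self, gap) -> np.ndarray | float:
        gap = np.asarray(gap, dtype=float)
        p = self.chance + (1.0 - self.chance) * norm.cdf(
            (gap - self.midpoint_mu) / self.slope_sigma
        )
        return float(p) if p.ndim == 0 else p


def collate_trials(trials: pd.DataFrame, bin_width: float = DEFAULT_BIN_WIDTH) -> CollatedData:
    """Bin one participant x condition's main trials into size bins.

    Practice trials are excluded; catch trials are included.  Bin edges sit
    at integer multiples of ``bin_width`` (so 1.9' and 2.1' fall in distinct
    0.25' bins either side of 2.0'), and each bin is labelled by its centre.
    Counts are conserved exactly.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    main = trials[trials["phase"] == "main"]
    if len(main) == 0:
        raise ValueError("no main-phase trials to collate")
    idx = np.floor(main["presented_gap_arcmin"].to_numpy(float) / bin_width)
    centres = (idx + 0.5) * bin_width
    correct = main["correct"].to_numpy(bool)
    order = np.argsort(centres, kind="stable")
    uniq, inverse = np.unique(np.round(centres[order], 9), return_inverse=True)
    n = np.bincount(inverse, minlength=len(uniq))
    k = np.bincount(inverse, weights=correct[order].astype(float), minlength=len(uniq))
    return CollatedData(gap=uniq, n_trials=n.astype(int), n_correct=k.astype(int))


_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _residuals(params, gap, phat, w, chance):
    mu, sigma = params
    model = chance + (1.0 - chance) * ndtr((gap - mu) / sigma)
    return w * (phat - model)


def _jacobian(params, gap, phat, w, chance):
    mu, sigma = params
    z = (gap - mu) / sigma
    phi = np.exp(-0.5 * z * z) / _SQRT_2PI
    common = w * (1.0 - chance) * phi / sigma
    return np.column_stack([common, common * z])


def fit_weighted_cumgauss(
    data: CollatedData,
    chance: float = DEFAULT_CHANCE,
    n_starts: int = 5,
    sigma_floor_fraction: float = 1e-3,
) -> PsychometricFit:
    """Fit the two-parameter cumulative Gaussian by trial-weighted least squares.

    Minimizes ``sum_i n_i * (phat_i - p(s_i; mu, sigma))**2`` with a
    multi-start bounded local optimizer: starts take ``mu`` from weighted
    data quantiles and ``sigma`` from fractions of the sampled size range.
    ``sigma`` is bounded below at ``sigma_floor_fraction * mu`` to avoid
    step-function degeneracy.
    """
    active = data.n_trials > 0
    if active.sum() < 3:
        raise ValueError("need at least 3 bins with trials for a two-parameter fit")
    gap = data.gap[active]
    n = data.n_trials[active]
    phat = (data.n_correct[active] / n).astype(float)
    w = np.sqrt(n.astype(float))

    if np.all(phat >= 1.0 - 1e-12):
        warnings.warn("all proportions at ceiling; midpoint poorly constrained")

    span = max(gap.max() - gap.min(), 1e-6)
    qs = np.quantile(np.repeat(gap, n), [0.2, 0.35, 0.5, 0.65, 0.8])
    sigmas0 = span * np.array([0.15, 0.3, 0.5, 0.2, 0.4])
    lo_mu, hi_mu = 1e-6, gap.max() * 3.0

    best = None
    for mu0, s0 in zip(qs[:n_starts], sigmas0[:n_starts]):
        mu0 = float(np.clip(mu0, lo_mu, hi_mu))
        try:
            res = least_squares(
                _residuals,
                x0=[mu0, max(s0, 1e-4)],
                jac=_jacobian,
                bounds=([lo_mu, 1e-6], [hi_mu, span * 10.0]),
                args=(gap, phat, w, chance),
                method="trf",
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("weighted cumulative-Gaussian fit failed from every start")

    mu, sigma = best.x
    sigma = max(sigma, sigma_floor_fraction * mu)
    sse = float(np.sum(n * (phat - (chance + (1 - chance) * ndtr((gap - mu) / sigma))) ** 2))
    return PsychometricFit(
        midpoint_mu=float(mu),
        slope_sigma=float(sigma),
        weighted_sse=sse,
        n_points=int(active.sum()),
        chance=chance,
    )


def threshold_at_criterion(fit: PsychometricFit, criterion: float = DEFAULT_CRITERION) -> float:
    """Gap size where the fitted curve reaches ``criterion`` proportion correct.

    Solves ``chance + (1 - chance) * Phi((s - mu)/sigma) = criterion`` in
    closed form.  At the midway criterion (0.625 for 4AFC) this is exactly
    the fitted midpoint.
    """
    if not fit.chance < criterion < 1.0:
        raise ValueError(f"criterion must lie in ({fit.chance}, 1), got {criterion}")
    z = norm.ppf((criterion - fit.chance) / (1.0 - fit.chance))
    return float(fit.midpoint_mu + fit.slope_sigma * z)


def catch_trial_score(trials: pd.DataFrame) -> float:
    """Percent correct on catch trials (easy, large-size attention checks)."""
    catch = trials[(trials["phase"] == "main") & trials["is_catch"]]
    if len(catch) == 0:
        raise ValueError("no catch trials in log")
    return 100.0 * float(catch["correct"].mean())


def fit_thresholds(
    trials: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    criterion: float = DEFAULT_CRITERION,
    require_perfect_catch: bool = False,
) -> pd.DataFrame:
    """Fit every participant x condition in a trial log; return a threshold table.

    Columns: participant_id, age_years, condition, threshold_gap_arcmin,
    slope_sigma_arcmin, catch_pct, n_trials.  With ``require_perfect_catch``
    participants scoring below 100 % on catch trials in that condition are
    dropped (the stricter screening variant).
    """
    out = []
    for (pid, cond), sub in trials.groupby(["participant_id", "condition"], sort=False):
        collated = collate_trials(sub, bin_width=bin_width)
        fit = fit_weighted_cumgauss(collated)
        catch_pct = catch_trial_score(sub)
        if require_perfect_catch and catch_pct < 100.0:
            continue
        out.append(
            {
                "participant_id": pid,
                "age_years": float(sub["age_years"].iloc[0]),
                "condition": cond,
                "threshold_gap_arcmin": threshold_at_criterion(fit, criterion),
                "slope_sigma_arcmin": fit.slope_sigma,
                "catch_pct": catch_pct,
                "n_trials": int(collated.n_trials.sum()),
            }
        )
    return pd.DataFrame(out)
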