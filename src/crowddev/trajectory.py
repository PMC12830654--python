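"""Developmental trajectories, planned contrasts and meta-analysis pooling.

Thresholds (or derived crowding metrics) are modelled as a logistic
function of age,

    v(a) = L + A / (1 + exp((a - a0) / k)),

declining from ``L + A`` in early childhood to the adult asymptote ``L``.
Uncertainty bands come from refitting bootstrap resamples of participants
(stratified by age group).  Development is additionally tested with planned
contrasts: independent-samples Student t-tests (pooled variance, hence
df = n1 + n2 - 2) between each child age group and the adults, reported
with Cohen's d.  The meta-analysis stage pools range-normalized values from
multiple studies within common age bins and runs the same contrasts against
the pooled adult values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "AGE_BINS",
    "META_AGE_BINS",
    "ADULT_AGE",
    "TrajectoryFit",
    "ContrastResult",
    "assign_age_bin",
    "fit_logistic_trajectory",
    "bootstrap_trajectory",
    "contrast_vs_adults",
    "contrasts_by_group",
    "pool_meta",
]

#: Analysis age bins: label -> [low, high) in years.  Adults are collapsed
#: to a nominal age of 18 for trajectory fitting.
AGE_BINS: dict[str, tuple[float, float]] = {
    "3-4": (3.0, 5.0),
    "5-6": (5.0, 7.0),
    "7-8": (7.0, 9.0),
    "9-10": (9.0, 11.0),
    "11-12": (11.0, 13.0),
    "adult": (18.0, np.inf),
}

#: The meta-analysis adds a 13-17-year bin for studies with teenage data.
META_AGE_BINS: dict[str, tuple[float, float]] = {
    **{k: v for k, v in AGE_BINS.items() if k != "adult"},
    "13-17": (13.0, 18.0),
    "adult": (18.0, np.inf),
}

ADULT_AGE = 18.0


def assign_age_bin(age: float, bins: Mapping[str, tuple[float, float]] = AGE_BINS) -> str:
    for label, (lo, hi) in bins.items():
        if lo <= age < hi or (np.isinf(hi) and age >= lo):
            return label
    raise ValueError(f"age {age} falls outside every bin")


@dataclass(frozen=True)
class TrajectoryFit:
    """Fitted logistic trajectory, optionally with a bootstrap band."""

    lower_asymptote: float  # L, adult level
    amplitude: float  # A, childhood elevation
    midpoint_age: float  # a0, years
    steepness: float  # k, years
    eval_ages: np.ndarray | None = None
    band_low: np.ndarray | None = None  # per-age 2.5th percentile
    band_high: np.ndarray | None = None  # per-age 97.5th percentile
    n_boot: int = 0

    def predict(self, ages) -> np.ndarray | float:
        a = np.asarray(ages, dtype=float)
        v = self.lower_asymptote + self.amplitude / (
            1.0 + np.exp((a - self.midpoint_age) / self.steepness)
        )
        return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class ContrastResult:
    """Planned contrast of one child group against adults."""

    t_statistic: float
    df: int
    p_value: float
    cohens_d: float
    group_ns: tuple[int, int]


def _logistic(params, a):
    L, A, a0, k = params
    return L + A / (1.0 + np.exp((a - a0) / k))


def _logistic_jac(params, a):
    L, A, a0, k = params
    u = np.exp((a - a0) / k)
    s2 = 1.0 / (1.0 + u) ** 2
    return np.column_stack(
        [
            np.ones_like(a),
            1.0 / (1.0 + u),
            A * u * s2 / k,
            A * u * (a - a0) * s2 / (k * k),
        ]
    )


def fit_logistic_trajectory(
    ages: Sequence[float],
    values: Sequence[float],
    n_starts: int = 4,
    x0: Sequence[float] | None = None,
) -> TrajectoryFit:
    """Least-squares logistic fit of values against age (adults at age 18).

    Multi-start local optimization: midpoint starts spread over the child
    age range, asymptote/amplitude starts taken from the oldest/youngest
    value levels.  ``x0`` supplies a single warm start instead (used for
    speed inside the bootstrap).
    """
    a = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    if a.size < 8:
        raise ValueError("need at least 8 points spanning children and adults")

    resid = lambda p: _logistic(p, a) - v
    jac = lambda p: _logistic_jac(p, a)
    lo = [1e-9, 0.0, 0.5, 0.05]
    hi = [np.inf, np.inf, 25.0, 10.0]

    old = float(np.mean(v[a >= np.quantile(a, 0.8)]))
    young = float(np.mean(v[a <= np.quantile(a, 0.2)]))
    amp0 = max(young - old, 1e-6)
    if x0 is not None:
        starts = [np.clip(np.asarray(x0, float), lo, hi)]
    else:
        starts = [
            np.clip([max(old, 1e-6), amp0, m, k], lo, hi)
            for m, k in ((4.0, 1.0), (6.0, 1.0), (8.0, 2.0), (5.0, 0.5))
        ][:n_starts]

    best = None
    for s in starts:
        try:
            res = least_squares(resid, x0=s, jac=jac, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("logistic trajectory fit failed from every start")
    L, A, a0, k = best.x
    return TrajectoryFit(
        lower_asymptote=float(L), amplitude=float(A), midpoint_age=float(a0), steepness=float(k)
    )


def bootstrap_trajectory(
    records: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    eval_ages: np.ndarray | None = None,
    value_col: str = "threshold_gap_arcmin",
    max_failure_fraction: float = 0.2,
) -> TrajectoryFit:
    """Logistic fit with a 95 % bootstrap band.

    ``records`` needs columns ``participant_id``, ``age_years`` and
    ``value_col`` (one row per participant).  Participants are resampled
    with replacement *within* age groups so each bootstrap cohort keeps the
    study's age structure; each resample is refit (warm-started from the
    point estimate) and the band is the per-age 2.5th/97.5th percentile of
    the fitted curves.
    """
    ages_full = records["age_years"].to_numpy(float)
    ages = np.minimum(ages_full, ADULT_AGE)  # collapse adults to age 18
    values = records[value_col].to_numpy(float)
    point = fit_logistic_trajectory(ages, values)

    if eval_ages is None:
        eval_ages = np.linspace(3.0, ADULT_AGE, 61)
    eval_ages = np.asarray(eval_ages, dtype=float)

    groups = [assign_age_bin(a) for a in ages_full]
    idx_by_group = {
        g: np.flatnonzero([gi == g for gi in groups]) for g in dict.fromkeys(groups)
    }
    rng = np.random.default_rng(seed)
    x0 = [point.lower_asymptote, point.amplitude, point.midpoint_age, point.steepness]

    curves = np.empty((n_boot, eval_ages.size))
    failures = 0
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True) for idx in idx_by_group.values()]
        )
        try:
            fit_b = fit_logistic_trajectory(ages[take], values[take], x0=x0)
            curves[b] = fit_b.predict(eval_ages)
        except Exception:
            failures += 1
            curves[b] = np.nan
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")

    band_low = np.nanpercentile(curves, 2.5, axis=0)
    band_high = np.nanpercentile(curves, 97.5, axis=0)
    # the band must bracket the point-estimate curve
    centre = point.predict(eval_ages)
    band_low = np.minimum(band_low, centre)
    band_high = np.maximum(band_high, centre)
    return TrajectoryFit(
        lower_asymptote=point.lower_asymptote,
        amplitude=point.amplitude,
        midpoint_age=point.midpoint_age,
        steepness=point.steepness,
        eval_ages=eval_ages,
        band_low=band_low,
        band_high=band_high,
        n_boot=n_boot,
    )


def contrast_vs_adults(child_values: Sequence[float], adult_values: Sequence[float]) -> ContrastResult:
    """Student's independent-samples t-test (pooled variance) with Cohen's d.

    The pooled-variance form fixes df = n1 + n2 - 2; d is the mean
    difference divided by the pooled standard deviation.
    """
    c = np.asarray(child_values, dtype=float)
    a = np.asarray(adult_values, dtype=float)
    if c.size < 2 or a.size < 2:
        raise ValueError("both groups need n >= 2")
    n1, n2 = c.size, a.size
    sp2 = ((n1 - 1) * c.var(ddof=1) + (n2 - 1) * a.var(ddof=1)) / (n1 + n2 - 2)
    if not sp2 > 0:
        raise ValueError("zero pooled variance; contrast degenerate")
    t, p = stats.ttest_ind(c, a, equal_var=True)
    d = float((c.mean() - a.mean()) / np.sqrt(sp2))
    return ContrastResult(
        t_statistic=float(t), df=n1 + n2 - 2, p_value=float(p), cohens_d=d, group_ns=(n1, n2)
    )


def contrasts_by_group(
    records: pd.DataFrame,
    value_col: str = "threshold_gap_arcmin",
    bins: Mapping[str, tuple[float, float]] = AGE_BINS,
) -> pd.DataFrame:
    """Planned contrasts of every child age bin against the adult bin."""
    labels = records["age_years"].map(lambda a: assign_age_bin(a, bins))
    adult = records.loc[labels == "adult", value_col].to_numpy(float)
    rows = []
    for label in bins:
        if label == "adult":
            continue
        child = records.loc[labels == label, value_col].to_numpy(float)
        if child.size < 2:
            continue
        r = contrast_vs_adults(child, adult)
        rows.append(
            {
                "group": label,
                "t": r.t_statistic,
                "df": r.df,
                "p": r.p_value,
                "cohens_d": r.cohens_d,
                "n_child": r.group_ns[0],
                "n_adult": r.group_ns[1],
            }
        )
    return pd.DataFrame(rows)


def pool_meta(
    datasets: Mapping[str, pd.DataFrame],
    bins: Mapping[str, tuple[float, float]] = META_AGE_BINS,
    one_value_per_study: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool normalized study values within common age bins and contrast
    each child bin against the pooled adult values.

    Each dataset is a table with columns ``age_years`` (bin midpoint or
    participant age) and ``value`` (already normalized onto the reference
    range).  With ``one_value_per_study`` each study contributes at most its
    within-bin mean to a bin (the single-value-per-study variant); otherwise
    all rows pool directly.

    Returns ``(pooled, contrasts)``: per-bin values with study provenance,
    and the contrast table (bins with fewer than 2 values are skipped).
    """
    rows = []
    for study, df in datasets.items():
        labelled = df.assign(
            _bin=df["age_years"].map(lambda a: assign_age_bin(a, bins)), study_id=study
        )
        if one_value_per_study:
            labelled = (
                labelled.groupby("_bin", as_index=False)
                .agg(value=("value", "mean"), study_id=("study_id", "first"))
                .rename(columns={"_bin": "age_bin"})
            )
        else:
            labelled = labelled.rename(columns={"_bin": "age_bin"})[
                ["study_id", "age_bin", "value"]
            ]
        rows.append(labelled)
    pooled = pd.concat(rows, ignore_index=True)

    adult = pooled.loc[pooled["age_bin"] == "adult", "value"].to_numpy(float)
    contrast_rows = []
    for label in bins:
        if label == "adult":
            continue
        vals = pooled.loc[pooled["age_bin"] == label, "value"].to_numpy(float)
        if vals.size < 2 or adult.size < 2:
            continue
        r = contrast_vs_adults(vals, adult)
        contrast_rows.append(
            {
                "age_bin": label,
                "pooled_mean": float(vals.mean()),
                "t": r.t_statistic,
                "df": r.df,
                "p": r.p_value,
                "cohens_d": r.cohens_d,
                "n_bin": r.group_ns[0],
                "n_adult": r.group_ns[1],
            }
        )
    return pooled, pd.DataFrame(contrast_rows)
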