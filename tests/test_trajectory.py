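"""Developmental trajectory fitting, planned contrasts, meta pooling."""

import numpy as np
import pandas as pd
import pytest

from crowddev import (
    contrast_vs_adults,
    fit_logistic_trajectory,
    bootstrap_trajectory,
    pool_meta,
)
from crowddev.trajectory import assign_age_bin, contrasts_by_group


def _logistic(a, L, A, a0, k):
    return L + A / (1 + np.exp((a - a0) / k))


class TestLogisticFit:
    def test_noiseless_recovery(self):
        """Exact logistic data recover the generating parameters."""
        ages = np.concatenate([np.linspace(3, 13, 30), np.full(10, 18.0)])
        v = _logistic(ages, 0.9, 1.5, 5.5, 1.0)
        fit = fit_logistic_trajectory(ages, v)
        assert fit.lower_asymptote == pytest.approx(0.9, abs=1e-4)
        assert fit.amplitude == pytest.approx(1.5, abs=1e-4)
        assert fit.midpoint_age == pytest.approx(5.5, abs=1e-3)
        assert fit.steepness == pytest.approx(1.0, abs=1e-3)
        np.testing.assert_allclose(fit.predict(ages), v, atol=1e-6)

    def test_flat_data_degenerates_gracefully(self):
        ages = np.concatenate([np.linspace(3, 13, 20), np.full(8, 18.0)])
        fit = fit_logistic_trajectory(ages, np.full_like(ages, 2.0))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-3)
        assert fit.predict(10.0) == pytest.approx(2.0, abs=1e-3)

    def test_fitted_curve_monotone_for_decreasing_cohort(self):
        rng = np.random.default_rng(2)
        ages = np.concatenate([rng.uniform(3, 13, 40), np.full(12, 18.0)])
        v = _logistic(ages, 1.0, 2.0, 6.0, 1.2) * rng.lognormal(0, 0.1, ages.size)
        fit = fit_logistic_trajectory(ages, v)
        curve = fit.predict(np.linspace(3, 18, 100))
        assert np.all(np.diff(curve) <= 1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_trajectory([3, 4, 5], [1, 1, 1])


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(31)
    ages = np.concatenate([rng.uniform(3, 13, 40), np.full(20, 18.0)])
    v = _logistic(ages, 1.1, 1.4, 5.2, 0.8) * rng.lognormal(-0.03, 0.25, ages.size)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(ages.size)],
            "age_years": ages,
            "threshold_gap_arcmin": v,
        }
    )


class TestBootstrapBand:
    def test_band_brackets_point_estimate(self, cohort):
        fit = bootstrap_trajectory(cohort, n_boot=200, seed=5)
        centre = fit.predict(fit.eval_ages)
        assert np.all(fit.band_low <= centre + 1e-9)
        assert np.all(fit.band_high >= centre - 1e-9)
        assert fit.n_boot == 200

    def test_default_n_boot_is_1000(self, cohort):
        import inspect

        assert inspect.signature(bootstrap_trajectory).parameters["n_boot"].default == 1000

    def test_seeded_runs_identical(self, cohort):
        a = bootstrap_trajectory(cohort, n_boot=50, seed=9)
        b = bootstrap_trajectory(cohort, n_boot=50, seed=9)
        np.testing.assert_array_equal(a.band_low, b.band_low)
        np.testing.assert_array_equal(a.band_high, b.band_high)

    def test_band_shrinks_with_cohort_size(self):
        """Quadrupling the cohort narrows the median band width."""

        def band_width(n_children, seed):
            rng = np.random.default_rng(seed)
            ages = np.concatenate([rng.uniform(3, 13, n_children), np.full(n_children // 2, 18.0)])
            v = _logistic(ages, 1.1, 1.4, 5.2, 0.8) * rng.lognormal(-0.03, 0.25, ages.size)
            df = pd.DataFrame(
                {
                    "participant_id": [f"P{i}" for i in range(ages.size)],
                    "age_years": ages,
                    "threshold_gap_arcmin": v,
                }
            )
            fit = bootstrap_trajectory(df, n_boot=150, seed=seed)
            return np.median(fit.band_high - fit.band_low)

        small = np.median([band_width(24, s) for s in range(3)])
        large = np.median([band_width(96, s) for s in range(3)])
        assert large < small


class TestContrasts:
    def test_df_is_pooled_form(self):
        rng = np.random.default_rng(0)
        r = contrast_vs_adults(rng.normal(2, 0.5, 10), rng.normal(1, 0.5, 30))
        assert r.df == 38

    def test_identical_groups_null(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        r = contrast_vs_adults(vals, vals)
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_toy_sets_match_brute_force(self):
        """3-vs-3 toy data agree with a from-scratch pooled-variance t and
        Cohen's d, and with an independent library implementation."""
        child = [2.0, 2.5, 3.0]
        adult = [1.0, 1.2, 1.4]
        r = contrast_vs_adults(child, adult)

        m1, m2 = np.mean(child), np.mean(adult)
        s1, s2 = np.var(child, ddof=1), np.var(adult, ddof=1)
        sp = np.sqrt((2 * s1 + 2 * s2) / 4)
        t_hand = (m1 - m2) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert r.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert r.df == 4
        assert r.cohens_d == pytest.approx((m1 - m2) / sp, rel=1e-12)

        import pingouin as pg

        tt = pg.ttest(child, adult, correction=False)
        assert r.t_statistic == pytest.approx(float(tt["T"].iloc[0]), rel=1e-9)
        assert r.p_value == pytest.approx(float(tt["p_val"].iloc[0]), rel=1e-9)
        assert r.cohens_d == pytest.approx(float(tt["cohen_d"].iloc[0]), rel=1e-9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            contrast_vs_adults([1.0, 1.0], [1.0, 1.0])

    def test_age_bin_assignment(self):
        assert assign_age_bin(3.2) == "3-4"
        assert assign_age_bin(6.9) == "5-6"
        assert assign_age_bin(12.9) == "11-12"
        assert assign_age_bin(25.0) == "adult"
        with pytest.raises(ValueError):
            assign_age_bin(1.0)

    def test_group_table_structure(self):
        rng = np.random.default_rng(1)
        ages = np.concatenate([rng.uniform(3, 13, 50), rng.uniform(18, 38, 30)])
        df = pd.DataFrame(
            {"age_years": ages, "threshold_gap_arcmin": rng.lognormal(0, 0.3, 80)}
        )
        table = contrasts_by_group(df)
        assert set(table["group"]) == {"3-4", "5-6", "7-8", "9-10", "11-12"}
        assert (table["df"] == table["n_child"] + table["n_adult"] - 2).all()


class TestPoolMeta:
    def _study(self, rng, n=30, scale=1.0):
        ages = np.concatenate([rng.uniform(3, 13, n), np.full(8, 20.0)])
        v = scale * _logistic(np.minimum(ages, 18), 1.0, 1.5, 5.5, 1.0)
        return pd.DataFrame({"age_years": ages, "value": v * rng.lognormal(0, 0.1, ages.size)})

    def test_single_study_bin_mean(self):
        df = pd.DataFrame({"age_years": [4.0, 20.0, 21.0], "value": [3.0, 1.0, 2.0]})
        pooled, _ = pool_meta({"only": df})
        assert pooled.loc[pooled.age_bin == "3-4", "value"].tolist() == [3.0]
        assert pooled.loc[pooled.age_bin == "adult", "value"].mean() == pytest.approx(1.5)

    def test_duplicate_studies_change_n_not_means(self):
        rng = np.random.default_rng(7)
        s = self._study(rng)
        pooled1, _ = pool_meta({"a": s})
        pooled2, _ = pool_meta({"a": s, "b": s.copy()})
        m1 = pooled1.groupby("age_bin")["value"].mean()
        m2 = pooled2.groupby("age_bin")["value"].mean()
        pd.testing.assert_series_equal(m1, m2)
        assert len(pooled2) == 2 * len(pooled1)

    def test_one_value_per_study_variant(self):
        rng = np.random.default_rng(8)
        s = self._study(rng)
        pooled, _ = pool_meta({"a": s}, one_value_per_study=True)
        assert pooled.groupby("age_bin").size().le(1).all()

    def test_reference_calibrated_studies_reproduce_pattern(self):
        """Thirteen synthetic studies whose age-binned values follow the
        reference crowding trajectory pool into bins significantly above the
        adults at 3-4 and 5-6 but not from 7-8 on."""
        from crowddev.observer import DEFAULT_FLANKED_SAME, true_threshold_at_age

        rng = np.random.default_rng(42)
        mid_ages = np.array([4.0, 6.0, 8.0, 10.0, 12.0, 20.0])
        truth = true_threshold_at_age(np.minimum(mid_ages, 18.0), DEFAULT_FLANKED_SAME)
        datasets = {
            f"s{i}": pd.DataFrame(
                {"age_years": mid_ages, "value": truth * rng.lognormal(0, 0.2, mid_ages.size)}
            )
            for i in range(13)
        }
        _, contrasts = pool_meta(datasets)
        c = contrasts.set_index("age_bin")
        assert c.loc["3-4", "p"] < 0.05
        assert c.loc["5-6", "p"] < 0.05
        for label in ("7-8", "9-10", "11-12"):
            assert c.loc[label, "p"] > 0.05
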