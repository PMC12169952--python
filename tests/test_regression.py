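"""Restricted cubic splines, percentile contrasts and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from dietcost import regression as rg


def textbook_rcs(x, knots):
    """Independent evaluation of the restricted cubic spline basis."""
    x = np.asarray(x, dtype=float)
    t = np.sort(np.asarray(knots, dtype=float))
    k = len(t)
    out = [x]
    for j in range(k - 2):
        d = lambda a: np.where(x > a, (x - a) ** 3, 0.0)
        term = (
            d(t[j])
            - d(t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + d(t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / (t[k - 1] - t[0]) ** 2
        out.append(term)
    return np.column_stack(out)


class TestRcsBasis:
    def test_three_knots_two_columns(self):
        basis = rg.rcs_basis(np.linspace(0, 10, 7), [2, 5, 8])
        assert basis.shape == (7, 2)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-5, 15, 100)
        knots = [1.0, 4.0, 7.5, 12.0]
        np.testing.assert_allclose(
            rg.rcs_basis(x, knots), textbook_rcs(x, knots), atol=1e-10
        )

    def test_exactly_linear_beyond_boundary_knots(self):
        knots = [2.0, 5.0, 8.0, 11.0]
        for tail in (np.linspace(-20, 1.9, 50), np.linspace(11.1, 40, 50)):
            basis = rg.rcs_basis(tail, knots)
            # second differences of every column vanish on a uniform grid
            second = np.diff(basis, n=2, axis=0)
            np.testing.assert_allclose(second, 0.0, atol=1e-8)

    def test_too_few_or_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            rg.rcs_basis([1.0], [1, 2])
        with pytest.raises(ValueError):
            rg.rcs_basis([1.0], [1, 2, 2])


class TestWeightedQuantile:
    def test_equal_weights_match_interpolated_quantile(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5001)
        for q in (5, 25, 50, 75, 95):
            assert rg.weighted_quantile(x, q) == pytest.approx(
                np.percentile(x, q), abs=0.01
            )

    def test_weight_replication_equivalence(self):
        x = np.array([1.0, 2.0, 5.0])
        w = np.array([1.0, 2.0, 1.0])
        expanded = np.array([1.0, 2.0, 2.0, 5.0])
        assert rg.weighted_quantile(x, 50, w) == pytest.approx(
            rg.weighted_quantile(expanded, 50), abs=1e-9
        )


def linear_population(n=400, slope=0.5, seed=0, noise=0.0, energy_coupled=False):
    rng = np.random.default_rng(seed)
    score = rng.uniform(0, 60, n)
    energy = rng.uniform(1800, 3200, n)
    cost = 2.0 + slope * score + noise * rng.standard_normal(n)
    if energy_coupled:
        cost = cost + 0.002 * (energy - 2500)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "score": score,
            "cost": cost,
            "energy": energy,
            "weight": rng.uniform(0.5, 2.0, n),
        }
    )


class TestFitAndContrast:
    def test_exact_linear_data_reproduces_slope_contrast(self):
        df = linear_population()
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=0)
        w = df["weight"].to_numpy()
        fit, knots, names = rg.fit_cost_model(
            df["cost"], df["score"], df["energy"], w, cfg
        )
        delta, x_lo, x_hi = rg.percentile_contrast(
            fit, knots, names, df["score"].to_numpy(), w, cfg
        )
        assert delta == pytest.approx(0.5 * (x_hi - x_lo), abs=1e-8)

    def test_weighted_fit_equals_replication_expanded_fit(self):
        df = linear_population(n=60, noise=1.0, seed=3)
        df["weight"] = np.array([1.0, 2.0, 3.0] * 20)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=0)
        fit_w, _, _ = rg.fit_cost_model(
            df["cost"], df["score"], df["energy"], df["weight"].to_numpy(), cfg
        )
        rep = df.loc[df.index.repeat(df["weight"].astype(int))]
        # same knots: percentile estimates differ slightly between the two
        # datasets, so fit the expanded data with the weighted knots
        X = rg.rcs_basis(
            rep["score"].to_numpy(),
            [rg.weighted_quantile(df["score"], p, df["weight"]) for p in cfg.knot_percentiles],
        )
        import statsmodels.api as sm

        fit_r = sm.OLS(rep["cost"].to_numpy(), sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit_w.params, fit_r.params, atol=1e-8)

    def test_energy_adjustment_leaves_energy_independent_truth_unchanged(self):
        df = linear_population(n=2000, noise=0.0, seed=4)
        w = df["weight"].to_numpy()
        deltas = {}
        for adjust in (False, True):
            cfg = rg.SplineConfig(energy_adjust=adjust, n_boot=0)
            fit, knots, names = rg.fit_cost_model(
                df["cost"], df["score"], df["energy"], w, cfg
            )
            deltas[adjust], *_ = rg.percentile_contrast(
                fit, knots, names, df["score"].to_numpy(), w, cfg, df["energy"].to_numpy()
            )
        assert deltas[True] == pytest.approx(deltas[False], abs=1e-6)

    def test_flat_curve_gives_zero_contrast(self):
        df = linear_population(slope=0.0)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=0)
        w = df["weight"].to_numpy()
        fit, knots, names = rg.fit_cost_model(df["cost"], df["score"], df["energy"], w, cfg)
        delta, *_ = rg.percentile_contrast(fit, knots, names, df["score"].to_numpy(), w, cfg)
        assert delta == pytest.approx(0.0, abs=1e-8)

    def test_monotone_curve_gives_positive_contrast(self):
        df = linear_population(noise=0.5, seed=5)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=0)
        w = df["weight"].to_numpy()
        fit, knots, names = rg.fit_cost_model(df["cost"], df["score"], df["energy"], w, cfg)
        delta, *_ = rg.percentile_contrast(fit, knots, names, df["score"].to_numpy(), w, cfg)
        assert delta > 0

    def test_hand_evaluated_spline_prediction(self):
        df = linear_population(noise=0.3, seed=6)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=0)
        w = df["weight"].to_numpy()
        fit, knots, names = rg.fit_cost_model(df["cost"], df["score"], df["energy"], w, cfg)
        x_lo = rg.weighted_quantile(df["score"].to_numpy(), 25, w)
        x_hi = rg.weighted_quantile(df["score"].to_numpy(), 75, w)
        basis = rg.rcs_basis(np.array([x_lo, x_hi]), knots)
        pred = np.column_stack([np.ones(2), basis]) @ fit.params
        delta, *_ = rg.percentile_contrast(fit, knots, names, df["score"].to_numpy(), w, cfg)
        assert delta == pytest.approx(pred[1] - pred[0], abs=1e-10)

    def test_affine_rescaling_invariance(self):
        """Rescaling the score (with knots following through the weighted
        percentiles) leaves the P75-P25 contrast unchanged."""
        df = linear_population(noise=0.4, seed=7)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=0)
        w = df["weight"].to_numpy()

        def contrast(scores):
            fit, knots, names = rg.fit_cost_model(df["cost"], scores, df["energy"], w, cfg)
            d, *_ = rg.percentile_contrast(fit, knots, names, np.asarray(scores), w, cfg)
            return d

        d1 = contrast(df["score"].to_numpy())
        d2 = contrast(3.0 * df["score"].to_numpy() + 7.0)
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_rank_deficiency_reported(self):
        df = linear_population(n=50)
        df["score"] = 1.0  # constant score duplicates the intercept
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=0, linear_only=True)
        with pytest.raises(ValueError, match="rank"):
            rg.fit_cost_model(df["cost"], df["score"], df["energy"], df["weight"], cfg)


class TestBootstrap:
    def test_degenerate_population_zero_se(self):
        """Every participant identical: resampling cannot change the fit."""
        rows = []
        for pid in range(30):
            rows.append({"participant_id": pid, "score": 10.0, "cost": 3.0, "energy": 2500.0, "weight": 1.0})
            rows.append({"participant_id": pid, "score": 40.0, "cost": 6.0, "energy": 2500.0, "weight": 1.0})
        df = pd.DataFrame(rows)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=20, seed=0, linear_only=True)
        res = rg.bootstrap_contrast(df, "score", cfg)
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.delta_cost == pytest.approx(3.0)  # slope 0.1 x IQR 30

    def test_fixed_seed_reproducible_ci(self):
        df = linear_population(n=150, noise=1.0, seed=8)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=30, seed=42)
        a = rg.bootstrap_contrast(df, "score", cfg)
        b = rg.bootstrap_contrast(df, "score", cfg)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_degenerate_score_skipped_not_raised(self):
        df = linear_population(n=50)
        df["score"] = 5.0
        cfg = rg.SplineConfig(n_boot=5, seed=0)
        res = rg.bootstrap_contrast(df, "score", cfg)
        assert res.skipped is not None and np.isnan(res.delta_cost)

    def test_ci_brackets_point_estimate(self):
        df = linear_population(n=200, noise=2.0, seed=9)
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=40, seed=1)
        res = rg.bootstrap_contrast(df, "score", cfg)
        assert res.ci_low <= res.delta_cost <= res.ci_high


class TestSubgroups:
    def cohort_and_data(self):
        df = linear_population(n=300, noise=1.0, seed=10)
        cohort = pd.DataFrame(
            {
                "participant_id": df["participant_id"],
                "sex": np.where(df["participant_id"] % 2 == 0, "M", "F"),
                "group_of_one": "all",
            }
        )
        return cohort, df

    def test_single_level_grouping_equals_overall(self):
        cohort, df = self.cohort_and_data()
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=10, seed=2)
        overall = rg.bootstrap_contrast(df, "score", cfg)
        table = rg.subgroup_contrasts(df, "score", cfg, cohort, groupings=("group_of_one",))
        assert table.loc[0, "delta_cost"] == pytest.approx(overall.delta_cost, abs=1e-9)

    def test_all_groupings_emitted_with_n(self):
        cohort, df = self.cohort_and_data()
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=5, seed=3)
        table = rg.subgroup_contrasts(df, "score", cfg, cohort, groupings=("sex",))
        assert set(table["level"]) == {"M", "F"}
        assert (table["n"] == 150).all()

    def test_identical_subgroups_agree_within_mc_error(self):
        """Two subgroups drawn from the same linear population share the
        same true contrast."""
        cohort, df = self.cohort_and_data()
        cfg = rg.SplineConfig(energy_adjust=False, n_boot=20, seed=4)
        table = rg.subgroup_contrasts(df, "score", cfg, cohort, groupings=("sex",)).set_index("level")
        diff = abs(table.loc["M", "delta_cost"] - table.loc["F", "delta_cost"])
        pooled_se = np.hypot(table.loc["M", "se"], table.loc["F", "se"])
        assert diff < 3 * pooled_se + 0.5
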