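"""Measurement-error model: classification, transforms, fit and simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from dietcost import measurement_error as me


class TestClassifyEpisodic:
    def recalls(self, rows):
        return pd.DataFrame(
            rows, columns=["participant_id", "recall_index", "food_group", "amount_kg"]
        )

    def test_universally_consumed_food_is_daily(self):
        rec = self.recalls([(p, 1, "bread", 0.1) for p in range(20)])
        episodic, daily = me.classify_episodic(rec)
        assert daily == ["bread"] and episodic == []

    def test_exact_ten_percent_boundary_is_episodic(self):
        rows = [(p, 1, "fish", 0.0 if p < 2 else 0.1) for p in range(20)]
        episodic, daily = me.classify_episodic(self.recalls(rows))
        assert episodic == ["fish"]

    def test_below_threshold_is_daily(self):
        rows = [(p, 1, "milk", 0.0 if p < 1 else 0.1) for p in range(20)]
        episodic, daily = me.classify_episodic(self.recalls(rows))
        assert daily == ["milk"]

    def test_sparse_food_episodic_with_high_probability(self):
        """p_consumer*p_day = 0.85 -> ~15% zeros on recall 1; with n=1000
        the binomial tail below the 10% threshold is negligible."""
        rng = np.random.default_rng(0)
        rows = [
            (p, 1, "treat", 0.1 if rng.random() < 0.85 else 0.0) for p in range(1000)
        ]
        episodic, _ = me.classify_episodic(self.recalls(rows))
        assert episodic == ["treat"]

    def test_weighted_fraction_used(self):
        rows = [(0, 1, "x", 0.0)] + [(p, 1, "x", 0.1) for p in range(1, 10)]
        weights = pd.Series({0: 10.0, **{p: 1.0 for p in range(1, 10)}})
        episodic, _ = me.classify_episodic(self.recalls(rows), weights)
        assert episodic == ["x"]  # weighted zero share 10/19 >= 0.10


class TestBackTransform:
    def test_lognormal_mean_exact(self):
        assert me._backtransform_mean(1.0, 0.25, 0.0) == pytest.approx(
            np.exp(1.0 + 0.125)
        )

    def test_identity_transform_mean(self):
        # lambda=1: g(x)=x-1, so E[g^-1(m+e)] = m+1 for centred e
        assert me._backtransform_mean(2.0, 0.3, 1.0) == pytest.approx(3.0, rel=1e-6)

    def test_quadrature_matches_taylor_at_small_variance(self):
        q = me._backtransform_mean(1.0, 1e-4, 0.4, "quadrature")
        t = me._backtransform_mean(1.0, 1e-4, 0.4, "taylor")
        assert q == pytest.approx(t, rel=1e-4)

    def test_quadrature_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        m, var, lam = 0.8, 0.3, 0.3
        e = m + np.sqrt(var) * rng.standard_normal(400_000)
        mc = np.power(np.maximum(lam * e + 1, 0.0), 1 / lam).mean()
        assert me._backtransform_mean(m, var, lam) == pytest.approx(mc, rel=0.005)

    def test_lambda_selection_prefers_log_for_lognormal(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 0.6, 3000))
        lam = me._select_lambda(x, (0.0, 0.25, 0.5, 0.75, 1.0))
        assert lam == 0.0


def model_free_recalls(n=150, r=4, sd_within=0.0, seed=0):
    """Daily-variable recalls with controllable within-person noise."""
    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(n), r)
    person = np.exp(rng.normal(-1.0, 0.5, n))
    amt = person[pid] * np.exp(
        sd_within * rng.standard_normal(n * r) - sd_within**2 / 2
    )
    wide = pd.DataFrame(
        {
            "participant_id": pid,
            "recall_index": np.tile(np.arange(1, r + 1), n),
            "weekend": np.tile([False, True, False, True], n)[: n * r],
            "food": amt,
            "energy": np.exp(7.8 + 0.2 * rng.standard_normal(n * r)),
            "cost": np.exp(2.3 + 0.2 * rng.standard_normal(n * r)),
        }
    )
    cohort = pd.DataFrame(
        {"participant_id": np.arange(n), "balancing_weight": np.ones(n)}
    )
    return wide, cohort, person


class TestFitAndSimulate:
    def spec(self, **kw):
        base = dict(
            episodic_vars=[], daily_vars=["food", "energy", "cost"],
            covariates=(), strata=None,
            n_iter=800, n_burn=400, thin=2, seed=1, n_pseudo=50,
        )
        base.update(kw)
        return me.MEModelSpec(**base)

    def test_zero_within_variance_recovers_person_means(self):
        """With no day-to-day noise in a daily variable, pseudo-individuals
        collapse onto the observed person means."""
        wide, cohort, person = model_free_recalls(sd_within=0.0)
        fitted = me.fit(self.spec(), wide, cohort)
        pseudo = me.simulate_usual(fitted, cohort, seed=3)
        pm = pseudo.groupby("participant_id")["food"].mean()
        np.testing.assert_allclose(pm.to_numpy(), person, rtol=0.05)
        block = fitted.strata["all"][0]
        k = block.parts.index(("food", "amount"))
        assert block.sigma_e_mean[k, k] < 0.05  # posterior within-variance -> 0

    def test_shrinkage_ordering(self):
        wide, cohort, _ = model_free_recalls(sd_within=0.6, seed=4)
        fitted = me.fit(self.spec(seed=2), wide, cohort)
        pseudo = me.simulate_usual(fitted, cohort, seed=5)
        v_usual = pseudo["food"].var()
        v_means = wide.groupby("participant_id")["food"].mean().var()
        v_single = wide["food"].var()
        assert v_usual <= v_means <= v_single

    def test_fit_deterministic_under_seed(self):
        wide, cohort, _ = model_free_recalls(n=60, seed=6)
        spec = self.spec(n_iter=300, n_burn=150)
        a = me.fit(spec, wide, cohort)
        b = me.fit(spec, wide, cohort)
        np.testing.assert_array_equal(
            a.strata["all"][0].u_draws, b.strata["all"][0].u_draws
        )

    def test_seed_stability_of_variance_components(self):
        """Two chains with different seeds agree on the variance
        components within Monte Carlo error."""
        wide, cohort, _ = model_free_recalls(n=150, sd_within=0.5, seed=7)
        a = me.fit(self.spec(seed=11, n_iter=1200, n_burn=600), wide, cohort)
        b = me.fit(self.spec(seed=12, n_iter=1200, n_burn=600), wide, cohort)
        da = np.diag(a.strata["all"][0].sigma_u_mean)
        db = np.diag(b.strata["all"][0].sigma_u_mean)
        np.testing.assert_allclose(da, db, rtol=0.2, atol=0.02)

    def test_variables_classified_twice_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            me.MEModelSpec(episodic_vars=["a"], daily_vars=["a", "energy", "cost"])

    def test_cost_forced_daily(self):
        with pytest.raises(ValueError, match="daily"):
            me.MEModelSpec(episodic_vars=["cost"], daily_vars=["energy"])

    def test_small_stratum_rejected(self):
        wide, cohort, _ = model_free_recalls(n=10)
        with pytest.raises(ValueError, match="fewer"):
            me.fit(self.spec(min_stratum=30), wide, cohort)


class TestUsualSummaries:
    def pseudo(self):
        return pd.DataFrame(
            {
                "participant_id": [0, 0, 1, 1],
                "pseudo_index": [0, 1, 0, 1],
                "food": [1.0, 2.0, 3.0, 4.0],
                "weight": [0.5, 0.5, 1.0, 1.0],
            }
        )

    def test_identical_pseudo_individuals_flat_percentiles(self):
        df = self.pseudo().assign(food=2.0)
        out = me.usual_summaries(df, ["food"])
        assert out.loc[0, "p5"] == out.loc[0, "p95"] == pytest.approx(2.0)

    def test_matches_bruteforce_weighted_percentiles(self):
        from dietcost.regression import weighted_quantile

        df = self.pseudo()
        out = me.usual_summaries(df, ["food"], percentiles=(50,))
        brute = weighted_quantile(
            df["food"].to_numpy(), 50, df["weight"].to_numpy()
        )
        assert out.loc[0, "p50"] == pytest.approx(brute)
        assert out.loc[0, "mean"] == pytest.approx(
            np.average(df["food"], weights=df["weight"])
        )

    def test_mean_invariant_to_row_permutation(self):
        df = self.pseudo()
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = me.usual_summaries(df, ["food"])
        b = me.usual_summaries(shuffled, ["food"])
        assert a.loc[0, "mean"] == pytest.approx(b.loc[0, "mean"])


class TestRecallsToWide:
    def test_pivot_and_merge(self):
        recalls = pd.DataFrame(
            {
                "participant_id": [1, 1, 1, 1],
                "recall_index": [1, 1, 2, 2],
                "weekend": [True, True, False, False],
                "food_group": ["a", "b", "a", "b"],
                "amount_kg": [0.1, 0.2, 0.0, 0.4],
                "energy_kcal": [50, 100, 0, 200],
            }
        )
        costs = pd.DataFrame(
            {
                "participant_id": [1, 1],
                "recall_index": [1, 2],
                "cost": [1.5, 2.0],
                "energy_kcal": [150.0, 200.0],
            }
        )
        wide = me.recalls_to_wide(recalls, costs)
        assert len(wide) == 2
        row1 = wide[wide["recall_index"] == 1].iloc[0]
        assert row1["a"] == 0.1 and row1["b"] == 0.2
        assert row1["energy"] == 150.0 and row1["cost"] == 1.5
        assert bool(row1["weekend"]) is True
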