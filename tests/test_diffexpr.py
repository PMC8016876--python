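"""Model fits against independent oracles, routing, and consensus logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txaging.diffexpr import (
    RegressionFit,
    consensus,
    fit_hurdle,
    fit_linear,
    fit_nb,
    fit_count_family,
    fits_to_frame,
    run_diffexpr,
    top_k,
)
from txaging.normalize import NormalizedMatrix
from txaging.simulate import SimConfig, simulate_counts


def _ols_oracle(y, X):
    """Closed-form OLS via the normal equations, with t-based Wald p."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


class TestFitLinear:
    def test_noiseless_line_exact_slope(self):
        ages = np.arange(20.0, 100.0, 10.0)
        sexes = np.array([0, 1] * 4, dtype=float)
        y = 0.1 * ages
        fit = fit_linear(y, ages, sexes)
        assert fit.beta_age == pytest.approx(0.1, abs=1e-12)
        assert fit.converged

    def test_constant_response(self):
        ages = np.arange(20.0, 100.0, 10.0)
        fit = fit_linear(np.full(8, 3.0), ages, np.array([0, 1] * 4, float))
        assert fit.beta_age == 0.0
        assert fit.p_wald == 1.0

    def test_matches_normal_equations_oracle(self):
        """8-sample fixture agrees with closed-form OLS to 1e-8."""
        rng = np.random.default_rng(99)
        ages = np.arange(20.0, 100.0, 10.0)
        sexes = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        y = 1.0 + 0.05 * ages + 0.3 * sexes + rng.normal(0, 0.5, 8)
        X = np.column_stack([np.ones(8), ages, sexes])
        beta, se, p = _ols_oracle(y, X)
        fit = fit_linear(y, ages, sexes)
        assert fit.beta_age == pytest.approx(beta[1], abs=1e-8)
        assert fit.se_age == pytest.approx(se[1], abs=1e-8)
        assert fit.p_wald == pytest.approx(p[1], abs=1e-8)

    def test_rank_deficient_design_flagged(self):
        ages = np.full(10, 50.0)  # constant age
        fit = fit_linear(np.arange(10.0), ages, np.zeros(10))
        assert not fit.converged
        assert "rank" in fit.exclusion_reason

    def test_sentinel_samples_excluded(self):
        ages = np.arange(20.0, 80.0, 5.0)
        y = 0.1 * ages
        y[0] = -np.inf  # zero-count sentinel
        sexes = (np.arange(len(ages)) % 2).astype(float)
        fit = fit_linear(y, ages, sexes)
        assert fit.beta_age == pytest.approx(0.1, abs=1e-10)


class TestFitNb:
    def test_binary_covariate_log_ratio(self):
        """With a binary age covariate the slope is the log mean ratio."""
        rng = np.random.default_rng(1)
        n = 2000
        grp = np.repeat([0.0, 1.0], n // 2)
        mu = np.where(grp == 1, 40.0, 20.0)
        k = 20.0
        y = rng.negative_binomial(k, k / (k + mu))
        assert (y > 0).all()  # P(zero) ~ 1e-6 at these parameters
        sexes = np.tile([0.0, 1.0], n // 2)
        fit = fit_nb(y, grp, sexes)
        ratio = np.log(y[grp == 1].mean() / y[grp == 0].mean())
        assert fit.beta_age == pytest.approx(np.log(2), abs=0.05)
        assert fit.beta_age == pytest.approx(ratio, abs=0.05)

    def test_constant_counts_zero_slope(self):
        ages = np.arange(20.0, 80.0, 2.0)
        fit = fit_nb(np.full(30, 50), ages, (np.arange(30) % 2).astype(float))
        assert fit.beta_age == pytest.approx(0.0, abs=1e-6)
        assert fit.p_wald == 1.0

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            fit_nb(np.array([0, 1, 2]), np.arange(3.0), np.zeros(3))

    def test_parameter_recovery_with_generator_truth(self):
        """Estimates fall within 2 SE of the generating slope >=95% of runs."""
        hits = tot = 0
        for rep in range(25):
            cfg = SimConfig(
                n_genes=40, n_samples=300, frac_age_assoc=0.1,
                beta_age_effect=0.03, frac_positive=0.5,
                baseline_mean_range=(200.0, 200.0),
                frac_structural_zero_genes=0.0, seed=1000 + rep,
            )
            cm, smp, truth = simulate_counts(cfg)
            ages, sexes = smp["age"].to_numpy(), smp["sex"].to_numpy()
            for g in truth.genes.index[truth.genes["true_beta_age"] != 0]:
                y = cm.counts.loc[g].to_numpy()
                if (y == 0).any():
                    continue
                fit = fit_nb(y, ages, sexes)
                hits += abs(fit.beta_age - truth.genes.loc[g, "true_beta_age"]) <= 2 * fit.se_age
                tot += 1
        assert tot >= 90
        assert hits / tot >= 0.9  # 2-SE Wald coverage, allowing MC noise


class TestFitHurdle:
    def test_count_component_recovers_trend_with_independent_zeros(self):
        rng = np.random.default_rng(3)
        n = 300
        ages = rng.uniform(22, 83, n)
        sexes = (np.arange(n) % 2).astype(float)
        k, b = 10.0, 0.03
        mu = 200 * np.exp(b * (ages - 52.5))
        y = rng.negative_binomial(k, k / (k + mu))
        y[rng.random(n) < 0.3] = 0  # zeros independent of age
        fit = fit_hurdle(y, ages, sexes)
        assert fit.converged
        assert abs(fit.beta_age - b) <= 2 * fit.se_age

    def test_zero_component_matches_2x2_log_odds(self):
        """Binary age: the logit age coefficient is the table log odds ratio."""
        young = np.zeros(10)
        old = np.ones(10)
        ages = np.concatenate([young, old])
        sexes = np.tile([0.0, 1.0], 10)
        # young: 2/10 zero; old: 8/10 zero -> OR of being POSITIVE = (8/2)/(2/8)
        y = np.concatenate(
            [np.r_[np.zeros(2), np.full(8, 50)], np.r_[np.zeros(8), np.full(2, 50)]]
        ).astype(int)
        fit = fit_hurdle(y, ages, sexes)
        table_log_or = np.log((2 / 8) / (8 / 2))  # odds of nonzero, old vs young
        assert np.sign(fit.zero_beta_age) == np.sign(table_log_or)
        assert fit.zero_beta_age == pytest.approx(table_log_or, abs=0.3)

    def test_refuses_without_zeros(self):
        with pytest.raises(ValueError):
            fit_hurdle(np.array([1, 2, 3, 4, 5]), np.arange(5.0), np.zeros(5))

    def test_too_few_positives_excluded(self):
        y = np.array([0] * 20 + [5, 6, 7])
        fit = fit_hurdle(y, np.arange(23.0), np.zeros(23))
        assert not fit.converged
        assert "positive observations" in fit.exclusion_reason


class TestRouting:
    def test_partition_by_zero_presence(self, small_dataset):
        """Every gene goes to exactly one family, decided by zeros alone."""
        _, cm, samples, _ = small_dataset
        from txaging.normalize import to_cpb

        cpb = to_cpb(cm)
        ages = samples["age"].to_numpy()
        sexes = samples["sex"].to_numpy()
        sub = cpb.values.index[:40]
        fits = fit_count_family(cpb, ages, sexes, feature_ids=sub)
        for fit in fits:
            has_zero = (cpb.values.loc[fit.feature_id] == 0).any()
            assert fit.model == ("zanb" if has_zero else "nb")


class TestConsensus:
    def _mk(self, fid, model, beta, p):
        return RegressionFit(feature_id=fid, model=model, beta_age=beta,
                             se_age=0.1, p_wald=p, converged=True)

    def test_one_family_significant_excluded(self):
        lin = [self._mk("g", "linear", 0.02, 0.005)]
        cnt = [self._mk("g", "nb", 0.02, 0.5)]
        out = consensus(lin, cnt)
        assert not out.loc["g", "in_consensus"]

    def test_both_significant_same_sign_included_up(self):
        lin = [self._mk("g", "linear", 0.02, 0.005)]
        cnt = [self._mk("g", "nb", 0.03, 0.005)]
        out = consensus(lin, cnt)
        assert out.loc["g", "in_consensus"]
        assert out.loc["g", "direction"] == "up"

    def test_sign_disagreement_excluded(self):
        lin = [self._mk("g", "linear", 0.02, 0.005)]
        cnt = [self._mk("g", "nb", -0.03, 0.005)]
        out = consensus(lin, cnt)
        assert not out.loc["g", "in_consensus"]

    def test_single_family_feature_not_eligible(self):
        lin = [self._mk("a", "linear", 0.02, 0.001)]
        cnt = [self._mk("b", "nb", 0.02, 0.001)]
        out = consensus(lin, cnt)
        assert not out["in_consensus"].any()
        assert (out["note"] == "present in one family only").all()

    def test_consensus_subset_of_each_family(self, small_dataset):
        _, cm, samples, _ = small_dataset
        res = run_diffexpr(cm, samples)
        cons = res.consensus
        in_c = cons[cons["in_consensus"]]
        assert in_c["significant_linear"].all()
        assert in_c["significant_nb_family"].all()


class TestTopK:
    def test_tie_breaking_order(self):
        df = fits_to_frame(
            [
                RegressionFit("b", "linear", beta_age=0.5, p_wald=0.01, converged=True),
                RegressionFit("a", "linear", beta_age=0.5, p_wald=0.01, converged=True),
                RegressionFit("c", "linear", beta_age=0.9, p_wald=0.01, converged=True),
                RegressionFit("d", "linear", beta_age=0.1, p_wald=0.001, converged=True),
            ]
        )
        out = top_k(df, k=4)
        assert list(out.index) == ["d", "c", "a", "b"]


class TestPipeline:
    def test_power_and_direction_on_known_effects(self):
        """Strong true effects at n=53 reach consensus with the right sign."""
        cfg = SimConfig(
            n_genes=400, n_samples=53, frac_age_assoc=0.1,
            beta_age_effect=0.02, frac_positive=0.9,
            baseline_mean_range=(200.0, 200.0),
            frac_structural_zero_genes=0.0, seed=7,
        )
        cm, samples, truth = simulate_counts(cfg)
        res = run_diffexpr(cm, samples)
        tp = truth.genes.index[truth.genes["true_beta_age"] != 0]
        cons = res.consensus
        power = cons.loc[cons.index.intersection(tp), "in_consensus"].mean()
        assert power >= 0.5
        hit = cons[cons["in_consensus"]].index.intersection(tp)
        sign_ok = (
            np.sign(cons.loc[hit, "beta_age_linear"])
            == np.sign(truth.genes.loc[hit, "true_beta_age"])
        ).mean()
        assert sign_ok >= 0.95

    def test_exclusions_logged_with_reasons(self, small_dataset):
        _, cm, samples, _ = small_dataset
        res = run_diffexpr(cm, samples)
        assert set(res.exclusions.columns) == {"feature_id", "branch", "reason"}
        assert (res.exclusions["reason"] != "").all()
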