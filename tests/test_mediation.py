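"""Mediation engine: OLS oracle, effect decomposition, bootstrap contracts."""

import numpy as np
import pandas as pd
import pytest

from orthomibg.mediation import (
    EFFECT_LABELS,
    MediationModel,
    mediate,
    ols_fit,
    standardize_effects,
)


class TestOlsFit:
    def test_exact_linear_fit(self):
        x = np.arange(5.0)
        coef, se, sigma2 = ols_fit(x, 3 * x + 1)
        assert coef == pytest.approx([1.0, 3.0])
        assert sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_duplicated_column_raises_naming_it(self):
        X = np.column_stack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(X, np.arange(6.0), names=["x", "x_dup"])

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        coef, se, sigma2 = ols_fit(X, y)
        Xd = np.column_stack([np.ones(20), X])
        beta_oracle = np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y
        assert coef == pytest.approx(beta_oracle, abs=1e-8)
        resid = y - Xd @ beta_oracle
        se_oracle = np.sqrt(np.diag(np.linalg.inv(Xd.T @ Xd)) * (resid @ resid) / 20)
        assert se == pytest.approx(se_oracle, abs=1e-8)

    def test_matches_statsmodels_up_to_variance_convention(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        coef, se, _ = ols_fit(X, y, ml_variance=False)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert coef == pytest.approx(fit.params, abs=1e-10)
        assert se == pytest.approx(fit.bse, abs=1e-10)

    def test_needs_more_rows_than_columns(self):
        with pytest.raises(ValueError, match="rows"):
            ols_fit(np.eye(3), np.ones(3))


class TestStandardizedEffects:
    def test_prestandardized_betas_equal_estimates(self):
        betas = standardize_effects(0.3, -0.2, 0.1, 1.0, 1.0, 1.0)
        assert betas["a_to_b"] == pytest.approx(0.3)
        assert betas["b_to_c"] == pytest.approx(-0.2)
        assert betas["direct"] == pytest.approx(0.1)
        assert betas["indirect"] == pytest.approx(-0.06)
        assert betas["total"] == pytest.approx(0.04)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="mediator"):
            standardize_effects(1, 1, 1, 1.0, 0.0, 1.0)

    def test_outcome_rescaling_equivariance(self, mediation_frame):
        r1 = mediate(mediation_frame, "a", "b", "c", n_boot=1, seed=0)
        doubled = mediation_frame.assign(c=2.0 * mediation_frame["c"])
        r2 = mediate(doubled, "a", "b", "c", n_boot=1, seed=0)
        assert r2["direct"].estimate == pytest.approx(2 * r1["direct"].estimate)
        for label in EFFECT_LABELS:
            assert r2[label].beta == pytest.approx(r1[label].beta)


class TestMediate:
    def test_decomposition_identity_machine_precision(self, mediation_frame):
        res = mediate(mediation_frame, "a", "b", "c", n_boot=1, seed=0)
        assert res["total"].estimate == pytest.approx(
            res["direct"].estimate + res["indirect"].estimate, abs=1e-10
        )
        assert res["indirect"].estimate == pytest.approx(
            res["a_to_b"].estimate * res["b_to_c"].estimate, abs=1e-10
        )
        assert res["indirect"].beta == pytest.approx(
            res["a_to_b"].beta * res["b_to_c"].beta, abs=1e-12
        )
        assert res["total"].beta == pytest.approx(
            res["direct"].beta + res["indirect"].beta, abs=1e-12
        )

    def test_total_equals_auxiliary_regression(self, mediation_frame):
        """total = coefficient of a in c ~ a + covariates, exactly."""
        res = mediate(mediation_frame, "a", "b", "c", n_boot=1, seed=0)
        X = mediation_frame[["a", "age", "duration"]].to_numpy()
        coef, _, _ = ols_fit(X, mediation_frame["c"].to_numpy())
        assert res["total"].estimate == pytest.approx(coef[1], abs=1e-10)

    def test_centering_invariance(self, mediation_frame):
        res1 = mediate(mediation_frame, "a", "b", "c", n_boot=50, seed=3)
        shifted = mediation_frame + np.array([100.0, -50.0, 7.0, 30.0, 2.0])
        res2 = mediate(shifted, "a", "b", "c", n_boot=50, seed=3)
        for label in EFFECT_LABELS:
            for f in ("estimate", "se", "beta", "ci_low", "ci_high"):
                assert getattr(res2[label], f) == pytest.approx(
                    getattr(res1[label], f), abs=1e-8
                )

    def test_null_mediator_gives_null_paths(self, rng):
        n = 2000
        a = rng.normal(size=n)
        df = pd.DataFrame({
            "a": a,
            "b": rng.normal(size=n),  # independent of everything
            "c": -0.4 * a + rng.normal(0, 0.5, n),
            "age": rng.normal(70, 9, n),
            "duration": rng.normal(1, 1, n),
        })
        res = mediate(df, "a", "b", "c", n_boot=200, seed=5)
        assert abs(res["a_to_b"].estimate) < 3 * res["a_to_b"].se
        assert abs(res["indirect"].estimate) < 0.02
        assert res["indirect"].ci_low <= 0 <= res["indirect"].ci_high

    def test_sobel_se_formula(self, mediation_frame):
        res = mediate(mediation_frame, "a", "b", "c", n_boot=1, seed=0)
        expected = np.sqrt(
            res["b_to_c"].estimate ** 2 * res["a_to_b"].se ** 2
            + res["a_to_b"].estimate ** 2 * res["b_to_c"].se ** 2
        )
        assert res["indirect"].se == pytest.approx(expected, abs=1e-12)
        assert res["indirect"].z == pytest.approx(
            res["indirect"].estimate / res["indirect"].se
        )

    def test_listwise_deletion_recorded(self, mediation_frame):
        df = mediation_frame.copy()
        df.loc[df.index[:7], "b"] = np.nan
        res = mediate(df, "a", "b", "c", n_boot=1, seed=0)
        assert res.n_used == len(df) - 7

    def test_degenerate_variable_rejected(self, mediation_frame):
        df = mediation_frame.assign(b=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            mediate(df, "a", "b", "c", n_boot=1, seed=0)

    def test_duplicate_roles_rejected(self, mediation_frame):
        with pytest.raises(ValueError, match="distinct"):
            mediate(mediation_frame, "a", "a", "c", n_boot=1, seed=0)


class TestBootstrap:
    def test_noiseless_data_zero_width_ci(self, rng):
        n = 60
        a = rng.normal(size=n)
        b = 2.0 * a + rng.normal(size=n)
        c = 1.0 * a + 0.5 * b  # exactly linear, no noise
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        res = mediate(df, "a", "b", "c", covariates=(), n_boot=100, seed=9)
        # the exactly-linear outcome equation is reproduced identically in
        # every resample; paths through the noisy b ~ a equation still vary
        for label in ("direct", "b_to_c"):
            assert res[label].ci_high - res[label].ci_low == pytest.approx(0, abs=1e-9)
        assert res["a_to_b"].ci_high > res["a_to_b"].ci_low

    def test_same_seed_same_cis(self, mediation_frame):
        r1 = mediate(mediation_frame, "a", "b", "c", n_boot=200, seed=17)
        r2 = mediate(mediation_frame, "a", "b", "c", n_boot=200, seed=17)
        for label in EFFECT_LABELS:
            assert r1[label].ci_low == r2[label].ci_low
            assert r1[label].ci_high == r2[label].ci_high

    def test_different_seed_different_cis(self, mediation_frame):
        r1 = mediate(mediation_frame, "a", "b", "c", n_boot=200, seed=17)
        r2 = mediate(mediation_frame, "a", "b", "c", n_boot=200, seed=18)
        assert r1["indirect"].ci_low != r2["indirect"].ci_low

    def test_chunking_does_not_change_cis(self, mediation_frame):
        r1 = mediate(mediation_frame, "a", "b", "c", n_boot=100, seed=4, boot_chunk=7)
        r2 = mediate(mediation_frame, "a", "b", "c", n_boot=100, seed=4, boot_chunk=100)
        for label in EFFECT_LABELS:
            assert r1[label].ci_low == r2[label].ci_low

    def test_sobel_and_bootstrap_agree_on_clear_settings(self, rng):
        n = 3000
        a = rng.normal(size=n)
        # clearly non-null indirect path
        b = 1.0 * a + rng.normal(0, 0.5, n)
        c = 0.8 * b + 0.3 * a + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        res = mediate(df, "a", "b", "c", covariates=(), n_boot=300, seed=1)
        assert abs(res["indirect"].z) > 3
        assert not res["indirect"].ci_low <= 0 <= res["indirect"].ci_high
        # clearly null indirect path
        df_null = df.assign(b=rng.normal(size=n))
        res0 = mediate(df_null, "a", "b", "c", covariates=(), n_boot=300, seed=1)
        assert abs(res0["indirect"].z) < 3
        assert res0["indirect"].ci_low <= 0 <= res0["indirect"].ci_high


def test_parameter_recovery_improves_with_n():
    """Recovered paths concentrate on the generating truth as n grows:
    RMSE over replicate cohorts shrinks, and at n=5000 the mean recovered
    a->b and a->c paths are within 5% of truth."""
    from orthomibg.simulate import SimulationParams, generate_cohort

    truth = {"a_to_b": -11.665, "direct": -0.441}
    seeds = range(30, 40)
    rmse, mean_est = {}, {}
    for n in (200, 5000):
        ests = {k: [] for k in truth}
        for s in seeds:
            cohort, _ = generate_cohort(
                SimulationParams(n_patients=n), seed=s, include_tilt=False
            )
            res = mediate(cohort, "delayed_hm", "delta_sbp_min_target",
                          "latent_burden", n_boot=1, seed=s)
            for k in truth:
                ests[k].append(res[k].estimate)
        rmse[n] = {k: np.sqrt(np.mean((np.array(v) - truth[k]) ** 2))
                   for k, v in ests.items()}
        mean_est[n] = {k: np.mean(v) for k, v in ests.items()}
    for k in truth:
        assert rmse[5000][k] < rmse[200][k]
        assert mean_est[5000][k] == pytest.approx(truth[k], rel=0.05)
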