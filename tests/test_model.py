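import itertools

import numpy as np
import pytest
from scipy import linalg, stats

from conftest import make_toy_trial
from metareg.config import ModelConfig
from metareg.data import AnalysisDataset, ArmRecord, ComparisonObservation, TrialRecord
from metareg.indicators import (
    INTERVENTION_INDICATORS,
    TIME_INDICATORS,
    TRIAL_INDICATORS,
)
from metareg.model import (
    Design,
    build_design,
    fit,
    log_likelihood,
    random_effect_structure,
    summarize,
    trial_blocks,
    within_trial_covariance,
)
from metareg.simulate import GeneratorConfig, generate


class TestBuildDesign:
    def test_all_zero_control_referenced_row(self):
        ds = make_toy_trial(n_active=1, categories=("short",),
                            trial_vals={"age_12_18": 0, "high_income": 0,
                                        "mixed_ses": 0})
        design = build_design(ds, center=False)
        row = design.X[0]
        assert row[0] == 1.0  # intercept
        nonzero = [design.columns[j] for j in np.nonzero(row)[0] if j > 0]
        assert nonzero == ["participation"]  # the mechanism indicator only

    def test_active_vs_active_identical_arms_gives_zero_row(self):
        ds = make_toy_trial(n_active=2, categories=("short",), with_control=False)
        # make both arms identical
        a2 = ds.arms["T1a2"]
        ds.arms["T1a2"] = ArmRecord(
            arm_id="T1a2", trial_id="T1", is_control=False,
            indicators=dict(ds.arms["T1a1"].indicators),
        )
        design = build_design(ds, center=False)
        np.testing.assert_array_equal(design.X[0], np.zeros(design.p))

    def test_active_referenced_rows_zero_for_upper_levels(self, small_dataset):
        ds, _ = small_dataset
        design = build_design(ds, interactions=[("age_12_18", "electronic")])
        upper = [design.column_index(c) for c in
                 ["intercept", *TRIAL_INDICATORS, *TIME_INDICATORS]]
        active = design.X[design.is_active_ref]
        assert len(active) > 0
        np.testing.assert_array_equal(active[:, upper], 0.0)

    def test_centred_columns_have_zero_mean_over_control_rows(self, small_dataset):
        ds, _ = small_dataset
        design = build_design(ds, center=True)
        ctrl = ~design.is_active_ref
        if ctrl.all():
            means = design.X[:, 1:].mean(axis=0)
            np.testing.assert_allclose(means, 0.0, atol=1e-12)

    def test_centering_record_decentring_identity(self, small_dataset):
        ds, _ = small_dataset
        dc = build_design(ds, center=True)
        du = build_design(ds, center=False)
        theta = np.arange(1.0, dc.p + 1.0) / 10
        # predictions on control-referenced rows must agree after de-centring
        pred_c = dc.X @ theta
        theta_u = theta.copy()
        theta_u[0] = dc.decenter_intercept(theta)
        pred_u = du.X @ theta_u
        np.testing.assert_allclose(pred_c, pred_u, atol=1e-10)

    def test_interaction_of_unknown_indicator_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(KeyError, match="dropped_thing"):
            build_design(ds, interactions=[("age_12_18", "dropped_thing")])


class TestWithinTrialCovariance:
    def test_single_observation(self):
        ds = make_toy_trial(n_active=1, categories=("short",), ses=0.3)
        R = within_trial_covariance(ds.observations, 0.8)
        np.testing.assert_allclose(R, [[0.09]])

    def test_same_comparison_two_times(self):
        ds = make_toy_trial(n_active=1, categories=("short", "medium"),
                            ses=(0.1, 0.2))
        R = within_trial_covariance(ds.observations, 0.8)
        assert R[0, 1] == pytest.approx(0.8 * 0.1 * 0.2)  # = 0.016

    def test_sensitivity_correlation_honoured(self):
        ds = make_toy_trial(n_active=1, categories=("short", "medium"),
                            ses=(0.1, 0.2))
        R = within_trial_covariance(ds.observations, 0.95)
        assert R[0, 1] == pytest.approx(0.95 * 0.1 * 0.2)

    def test_shared_reference_arm_correlation(self):
        ds = make_toy_trial(n_active=2, categories=("short",), ses=(0.1, 0.3))
        R = within_trial_covariance(ds.observations, 0.8, rho_arm=0.5)
        assert R[0, 1] == pytest.approx(0.5 * 0.1 * 0.3)

    def test_blocks_positive_definite(self, small_dataset):
        ds, _ = small_dataset
        for b in trial_blocks(ds, ModelConfig()):
            assert np.linalg.eigvalsh(b.R)[0] > 0


class TestRandomEffectStructure:
    def test_control_referenced_variance_and_covariance(self):
        ds = make_toy_trial(n_active=2, categories=("short", "medium"))
        controls = {"T1c"}
        C = random_effect_structure(ds.observations, controls)
        # Var = tau^2 -> unit diagonal; Cov = tau^2/2 across distinct effects
        np.testing.assert_allclose(np.diag(C), 1.0)
        off = C[~np.eye(len(C), dtype=bool)]
        np.testing.assert_allclose(off, 0.5)

    def test_active_referenced_variance(self):
        ds = make_toy_trial(n_active=2, categories=("short",), with_control=False)
        C = random_effect_structure(ds.observations, set())
        # u_a - u_b has variance tau^2 + tau^2 - 2 tau^2/2 = tau^2
        np.testing.assert_allclose(C, [[1.0]])


class TestLogLikelihood:
    def test_point_mass_at_mean(self):
        ds = make_toy_trial(n_active=1, categories=("short",), ses=0.25, md=0.1)
        design = build_design(ds, center=False)
        blocks = trial_blocks(ds, ModelConfig())
        y = np.array([0.1])
        theta = np.zeros(design.p)
        theta[0] = 0.1
        theta[design.column_index("participation")] = 0.0
        # mean = y: log density is -0.5 log(2 pi se^2)
        ll = log_likelihood(y, design.X, theta, 0.0, blocks)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * 0.25**2))

    @pytest.mark.parametrize("with_control", [True, False])
    def test_explicit_marginalisation_oracle(self, with_control):
        """Blockwise marginal likelihood equals direct Gauss-Hermite
        integration of the random effects on a 2-arm, 2-time toy trial."""
        ds = make_toy_trial(
            n_active=2, categories=("short", "medium"),
            ses=(0.3, 0.35, 0.4, 0.45), with_control=with_control,
        )
        cfg = ModelConfig(rho_time=0.8, rho_arm=0.5)
        design = build_design(ds, center=False)
        blocks = trial_blocks(ds, cfg)
        (block,) = blocks
        rng = np.random.default_rng(3)
        y = rng.normal(0.0, 0.2, size=len(ds.observations))
        theta = rng.normal(0.0, 0.05, size=design.p)
        tau = 0.2

        ll_block = log_likelihood(y, design.X, theta, tau, blocks)

        # oracle: integrate over u per (arm, category) with
        # Sigma_u = tau^2/2 (I + J), y | u ~ N(X theta + Z u, R)
        controls = {a.arm_id for a in ds.arms.values() if a.is_control}
        keys: list[tuple[str, str]] = []
        for o in ds.observations:
            for aid in (o.arm_id, o.reference_arm_id):
                if aid not in controls and (aid, o.followup_category) not in keys:
                    keys.append((aid, o.followup_category))
        Z = np.zeros((len(ds.observations), len(keys)))
        for i, o in enumerate(ds.observations):
            Z[i, keys.index((o.arm_id, o.followup_category))] += 1
            if o.reference_arm_id not in controls:
                Z[i, keys.index((o.reference_arm_id, o.followup_category))] -= 1
        q = len(keys)
        Su = tau**2 / 2 * (np.eye(q) + np.ones((q, q)))
        S = np.linalg.cholesky(Su)
        r = y - design.X @ theta
        x, w = np.polynomial.hermite.hermgauss(30)
        grids = np.array(list(itertools.product(x, repeat=q)))
        logwts = np.sum(
            np.log(np.array(list(itertools.product(w, repeat=q)))), axis=1
        )
        U = (S @ (np.sqrt(2.0) * grids.T)).T
        cf = linalg.cho_factor(block.R, lower=True)
        resid = r[None, :] - U @ Z.T
        quad = np.einsum("ij,ij->i", resid, linalg.cho_solve(cf, resid.T).T)
        logdet = 2 * np.sum(np.log(np.diag(cf[0])))
        logdens = -0.5 * (quad + len(r) * np.log(2 * np.pi) + logdet)
        logterms = logwts + logdens - q / 2 * np.log(np.pi)
        m = logterms.max()
        ll_oracle = m + np.log(np.sum(np.exp(logterms - m)))

        assert ll_block == pytest.approx(ll_oracle, abs=1e-8)

    def test_doubling_ses_changes_density_by_jacobian(self):
        """At zero residual and tau=0, scaling all SEs by c shifts the log
        density by -n log c (the Gaussian normalisation term)."""
        ds1 = make_toy_trial(n_active=1, categories=("short", "medium"),
                             ses=(0.1, 0.2), md=0.0)
        ds2 = make_toy_trial(n_active=1, categories=("short", "medium"),
                             ses=(0.2, 0.4), md=0.0)
        cfg = ModelConfig()
        theta = np.zeros(build_design(ds1, center=False).p)
        y = np.zeros(2)
        ll1 = log_likelihood(y, build_design(ds1, center=False).X, theta, 0.0,
                             trial_blocks(ds1, cfg))
        ll2 = log_likelihood(y, build_design(ds2, center=False).X, theta, 0.0,
                             trial_blocks(ds2, cfg))
        assert ll1 - ll2 == pytest.approx(2 * np.log(2.0))


class TestSummarize:
    def test_half_negative_samples(self):
        out = summarize({"x": np.array([-1.0, -2.0, 3.0, 4.0])})
        assert out.loc["x", "p_lt0"] == 0.5
        assert out.loc["x", "p_gt0"] == 0.5

    def test_all_negative_samples(self):
        out = summarize({"x": -np.abs(np.random.default_rng(0).normal(size=50))})
        assert out.loc["x", "p_lt0"] == 1.0

    def test_exact_zeros_counted_to_neither_side(self):
        out = summarize({"x": np.array([-1.0, 0.0, 0.0, 1.0])})
        assert out.loc["x", "p_lt0"] == 0.25
        assert out.loc["x", "p_gt0"] == 0.25

    def test_large_sample_normal_interval(self):
        z = np.random.default_rng(1).standard_normal(200_000)
        out = summarize({"z": z})
        assert out.loc["z", "ci_low"] == pytest.approx(-1.96, abs=0.02)
        assert out.loc["z", "ci_high"] == pytest.approx(1.96, abs=0.02)


def _mc_se(result, name):
    s = result.samples(name)
    ess = float(result.diagnostics.loc[name, "ess"])
    return s.std(ddof=1) / np.sqrt(max(ess, 1.0))


class TestFit:
    def test_recovers_planted_parameters(self, small_dataset, small_config):
        ds, truth = small_dataset
        res = fit(ds, small_config)
        want = truth.on_design(res.design)
        summ = res.summary()
        for name in ["intercept", "pa_only", "age_12_18", "medium"]:
            post_mean = summ.loc[name, "mean"]
            post_sd = summ.loc[name, "sd"]
            assert abs(post_mean - want[name]) < 3.5 * post_sd, name
        assert abs(summ.loc["tau", "mean"] - truth.tau) < 3.5 * summ.loc["tau", "sd"]

    def test_fixed_effects_equals_random_effects_at_tau_zero(
        self, small_dataset
    ):
        ds, _ = small_dataset
        fe = fit(ds, ModelConfig(seed=5, chains=2, draws=500, warmup=300,
                                 effects_mode="fixed"))
        # random-effects machinery with the heterogeneity prior collapsed
        re0 = fit(ds, ModelConfig(seed=6, chains=2, draws=500, warmup=300,
                                  tau_upper=1e-8))
        for name in ["intercept", "pa_only", "home", "medium"]:
            tol = 4 * np.hypot(_mc_se(fe, name), _mc_se(re0, name))
            assert abs(
                fe.summary().loc[name, "mean"] - re0.summary().loc[name, "mean"]
            ) < tol, name

    def test_centring_invariance(self, small_dataset):
        ds, _ = small_dataset
        a = fit(ds, ModelConfig(seed=8, chains=2, draws=500, warmup=300,
                                center=True))
        b = fit(ds, ModelConfig(seed=9, chains=2, draws=500, warmup=300,
                                center=False))
        sa, sb = a.summary(), b.summary()
        for name in ["pa_only", "home", "age_12_18", "medium", "tau"]:
            tol = 4 * np.hypot(_mc_se(a, name), _mc_se(b, name))
            assert abs(sa.loc[name, "mean"] - sb.loc[name, "mean"]) < tol, name
        # centred intercept = uncentred intercept + sum(coef * mean)
        shift = float(
            sb[~sb.index.isin(["intercept", "tau"])]["mean"].to_numpy()
            @ a.design.centering[1:]
        )
        tol = 4 * np.hypot(_mc_se(a, "intercept"), _mc_se(b, "intercept"))
        assert abs(
            sa.loc["intercept", "mean"] - (sb.loc["intercept", "mean"] + shift)
        ) < tol

    def test_intercept_only_matches_textbook_meta_analysis(self):
        """With an intercept-only design on control-referenced single
        follow-ups, the fit reduces to a standard Bayesian random-effects
        meta-analysis; compare with deterministic quadrature."""
        rng = np.random.default_rng(12)
        n = 30
        ses = rng.uniform(0.05, 0.2, n)
        mu_true, tau_true = -0.1, 0.08
        y = rng.normal(mu_true, np.sqrt(ses**2 + tau_true**2))
        trials, arms, obs = {}, {}, []
        from conftest import make_indicators

        for i in range(n):
            tid, aid, cid = f"T{i}", f"T{i}a", f"T{i}c"
            trials[tid] = TrialRecord(trial_id=tid, age_12_18=0, high_income=0,
                                      mixed_ses=0, arm_ids=(aid, cid))
            arms[aid] = ArmRecord(arm_id=aid, trial_id=tid, is_control=False,
                                  indicators=make_indicators())
            arms[cid] = ArmRecord(arm_id=cid, trial_id=tid, is_control=True)
            obs.append(ComparisonObservation(
                trial_id=tid, arm_id=aid, reference_arm_id=cid,
                followup_weeks=20.0, followup_category="short", rob_high=0,
                md=float(y[i]), se=float(ses[i]), scale="zbmi",
            ))
        ds = AnalysisDataset(trials=trials, arms=arms, observations=obs)
        ds.validate()

        design = Design(
            X=np.ones((n, 1)), columns=["intercept"],
            centering=np.zeros(1), is_active_ref=np.zeros(n, bool),
            interactions=[],
        )
        cfg = ModelConfig(seed=4, chains=2, draws=1500, warmup=500)
        res = fit(ds, cfg, design=design)

        # quadrature oracle: alpha | tau conjugate, tau on a fine grid
        prior_sd = cfg.prior_coef_sd
        taus = np.linspace(0, cfg.tau_upper, 4001)
        log_post = np.empty_like(taus)
        post_mean_alpha = np.empty_like(taus)
        for k, t in enumerate(taus):
            v = ses**2 + t**2
            prec = np.sum(1 / v) + 1 / prior_sd**2
            mean = np.sum(y / v) / prec
            # log marginal of y given tau (alpha integrated out)
            log_post[k] = (
                -0.5 * np.sum(np.log(2 * np.pi * v))
                - 0.5 * np.sum(y**2 / v)
                + 0.5 * mean**2 * prec
                - 0.5 * np.log(prior_sd**2 * prec)
            )
            post_mean_alpha[k] = mean
        wts = np.exp(log_post - log_post.max())
        wts /= wts.sum()
        alpha_oracle = float(np.sum(wts * post_mean_alpha))
        tau_oracle = float(np.sum(wts * taus))

        assert res.summary().loc["intercept", "mean"] == pytest.approx(
            alpha_oracle, abs=4 * _mc_se(res, "intercept")
        )
        assert res.summary().loc["tau", "mean"] == pytest.approx(
            tau_oracle, abs=4 * _mc_se(res, "tau")
        )

    def test_deterministic_given_seed(self, small_dataset):
        ds, _ = small_dataset
        cfg = ModelConfig(seed=13, chains=1, draws=50, warmup=20)
        a = fit(ds, cfg)
        b = fit(ds, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.tau, b.tau)

    def test_convergence_diagnostics_reported(self, small_dataset, small_config):
        ds, _ = small_dataset
        res = fit(ds, small_config)
        assert {"rhat", "ess"} <= set(res.diagnostics.columns)
        assert res.converged
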