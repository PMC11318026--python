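"""Mixed-model fitting: quadrature accuracy, oracles, tests and contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from shellrank.design import ModelSpec, build_design
from shellrank.errors import NestingError, SchemaError
from shellrank.glmm import (
    GLMMFit,
    agq_marginal_loglik,
    contrast,
    fit_glmm,
    lrt,
    predict_conditional,
    vif,
    wald_contrasts,
)
from shellrank.recovery import child_seed
from shellrank.simulate import DEFAULT_BETA_GEN, OCCUPANCY_SPEC, SyntheticConfig, generate_table

from conftest import toy_glmm_data

TOY_SPEC = ModelSpec("y", ["x", "b"], group="group_id")


def brute_force_loglik(X, y, g, beta, sigma, n_points=10001):
    """Trapezoid integration of the marginal likelihood over u per group."""
    eta0 = X @ beta
    total = 0.0
    for grp in range(int(g.max()) + 1):
        idx = g == grp
        u = np.linspace(-8.0 * sigma, 8.0 * sigma, n_points)
        ll = np.array(
            [(y[idx] * (eta0[idx] + ui) - np.logaddexp(0.0, eta0[idx] + ui)).sum() for ui in u]
        )
        dens = ll - 0.5 * u**2 / sigma**2 - np.log(sigma * np.sqrt(2.0 * np.pi))
        w = np.full(n_points, u[1] - u[0])
        w[0] /= 2.0
        w[-1] /= 2.0
        total += logsumexp(dens + np.log(w))
    return float(total)


class TestMarginalLikelihood:
    def test_agq_matches_brute_force_on_toy(self):
        """15-node adaptive quadrature equals a 10,001-point trapezoid
        integral of the same marginal likelihood to 1e-6."""
        df = toy_glmm_data()
        d = build_design(TOY_SPEC, df)
        beta = np.array([-0.5, 0.8, 0.4])
        for sigma in (0.3, 0.7, 1.5):
            ll_agq = agq_marginal_loglik(d.X, d.y, d.groups, beta, sigma, n_nodes=15)
            ll_brute = brute_force_loglik(d.X, d.y, d.groups, beta, sigma)
            assert abs(ll_agq - ll_brute) < 1e-6

    def test_node_count_stability_on_default_data(self, default_table, occupancy_fit):
        shells, _ = default_table
        d = build_design(OCCUPANCY_SPEC, shells)
        lls = [
            agq_marginal_loglik(d.X, d.y, d.groups, occupancy_fit.beta, occupancy_fit.sigma, n)
            for n in (15, 25)
        ]
        assert abs(lls[0] - lls[1]) < 1e-4


class TestFit:
    def test_sigma_zero_collapses_to_plain_logistic(self):
        """With uninformative group labels the GLMM equals IRLS logistic."""
        config = SyntheticConfig(sigma_group=0.0)
        shells, _ = generate_table(config, seed=8)
        fit = fit_glmm(OCCUPANCY_SPEC, shells)
        assert fit.sigma < 0.05
        d = build_design(OCCUPANCY_SPEC, shells)
        oracle = sm.GLM(d.y, d.X, family=sm.families.Binomial()).fit()  # IRLS
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-3)

    def test_covariate_shift_moves_only_intercept(self):
        """Adding a constant to an unscaled covariate is a pure
        reparameterization of the intercept."""
        df = toy_glmm_data(seed=12, n_groups=8, per_group=20)
        fit1 = fit_glmm(TOY_SPEC, df)
        shifted = df.copy()
        shifted["x"] = shifted["x"] + 5.0
        fit2 = fit_glmm(TOY_SPEC, shifted)
        np.testing.assert_allclose(fit1.beta[1:], fit2.beta[1:], atol=1e-6)
        assert abs((fit1.beta[0] - 5.0 * fit1.beta[1]) - fit2.beta[0]) < 1e-6

    def test_separation_warns(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=60),
                "b": 0.0,
                "group_id": np.repeat(list("abc"), 20),
            }
        )
        df["y"] = (df["x"] > 0).astype(int)
        with pytest.warns(RuntimeWarning, match="separation"):
            fit_glmm(ModelSpec("y", ["x"], group="group_id"), df)

    def test_recovers_generating_slopes(self, glmm_recovery_study):
        """Replicate-mean estimates sit within two Monte-Carlo standard
        errors of the generating coefficients (unbounded fits excluded)."""
        study = glmm_recovery_study
        means, mc_se = study.means(), study.mc_se()
        truth = {
            "intactness_pct_s": DEFAULT_BETA_GEN["intactness_pct_s"],
            "entrance_cm_s": DEFAULT_BETA_GEN["entrance_cm_s"],
            "intactness_pct_s:location[surface]": DEFAULT_BETA_GEN[
                "intactness_pct_s:location[surface]"
            ],
            "crab": DEFAULT_BETA_GEN["crab"],
        }
        for term, target in truth.items():
            assert abs(means[term] - target) <= 2.0 * mc_se[term], term


class TestPredict:
    def _manual_fit(self, beta, u, columns, spec):
        p = len(beta)
        return GLMMFit(
            spec=spec,
            columns=columns,
            beta=np.asarray(beta, float),
            se=np.zeros(p),
            vcov=np.zeros((p, p)),
            sigma=0.5,
            u_modes=np.asarray(u, float),
            group_levels=["a"],
            factor_levels={},
            loglik=0.0,
            converged=True,
            n_obs=1,
            n_groups=1,
            n_nodes=15,
            n_params=p + 1,
        )

    def test_null_model_predicts_half(self):
        spec = ModelSpec("y", ["x"], group="group_id")
        fit = self._manual_fit([0.0, 0.0], [0.0], ["(Intercept)", "x"], spec)
        df = pd.DataFrame({"x": [0.3, -2.0, 5.0], "group_id": ["a"] * 3})
        np.testing.assert_allclose(predict_conditional(fit, df), 0.5)

    def test_hand_evaluated_inverse_logit(self):
        spec = ModelSpec("y", ["x"], group="group_id")
        fit = self._manual_fit([0.0, 1.0], [0.5], ["(Intercept)", "x"], spec)
        df = pd.DataFrame({"x": [1.0], "group_id": ["a"]})
        assert predict_conditional(fit, df)[0] == pytest.approx(expit(1.5), abs=1e-4)

    def test_unseen_group_rejected(self, occupancy_fit, default_table):
        shells, _ = default_table
        alien = shells.head(3).copy()
        alien["group_id"] = "G99"
        from shellrank.errors import ValidationError

        with pytest.raises(ValidationError, match="G99"):
            predict_conditional(occupancy_fit, alien)

    def test_predictions_inside_unit_interval_and_monotone(
        self, occupancy_fit, default_table
    ):
        shells, _ = default_table
        p = predict_conditional(occupancy_fit, shells)
        assert np.all((p > 0.0) & (p < 1.0))
        # raising intactness raises the prediction wherever its total
        # slope (main effect + interaction) is positive
        bumped = shells.copy()
        bumped["intactness_pct_s"] = bumped["intactness_pct_s"] + 0.5
        p2 = predict_conditional(occupancy_fit, bumped)
        slope = occupancy_fit.coef["intactness_pct_s"]
        inter = occupancy_fit.coef["intactness_pct_s:location[surface]"]
        if slope > 0 and slope + inter > 0:
            assert np.all(p2 > p)


class TestLRT:
    def test_model_against_itself(self, occupancy_fit):
        res = lrt(occupancy_fit, occupancy_fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_non_nested_rejected(self):
        df = toy_glmm_data(seed=3, n_groups=4, per_group=15)
        full = fit_glmm(ModelSpec("y", ["x"], group="group_id"), df)
        other = fit_glmm(ModelSpec("y", ["b"], group="group_id"), df)
        with pytest.raises(NestingError):
            lrt(full, other)

    def test_statistic_matches_independently_maximized_logliks(self):
        """2*(difference of trapezoid-oracle maximized logliks) within 1e-4."""
        df = toy_glmm_data(seed=21, n_groups=4, per_group=12)
        full = fit_glmm(TOY_SPEC, df)
        reduced = fit_glmm(TOY_SPEC.drop_term("b"), df)
        observed = lrt(full, reduced).statistic

        def maximize(spec):
            d = build_design(spec, df)

            def nll(theta):
                beta, sigma = theta[:-1], np.exp(theta[-1])
                return -brute_force_loglik(d.X, d.y, d.groups, beta, sigma, n_points=2001)

            x0 = np.append(np.zeros(d.p), np.log(0.5))
            res = minimize(
                nll,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
            )
            return -res.fun

        oracle = 2.0 * (maximize(TOY_SPEC) - maximize(TOY_SPEC.drop_term("b")))
        assert abs(observed - oracle) < 1e-4

    def test_power_to_detect_generating_interaction(self):
        """The interaction LRT rejects far more often than alpha on data
        generated with a real interaction. At the default conditions the
        interaction SE is ~0.30, so the analytic power at effect 0.66 is
        ~55-65%; assert a conservative floor well above alpha = 0.05."""
        base = ModelSpec(
            OCCUPANCY_SPEC.response,
            [t for t in OCCUPANCY_SPEC.fixed if ":" not in t],
            group=OCCUPANCY_SPEC.group,
        )
        hits = 0
        n_reps = 100
        for r in range(n_reps):
            shells, _ = generate_table(seed=child_seed(2024, r))
            full = fit_glmm(OCCUPANCY_SPEC, shells, compute_se=False)
            reduced = fit_glmm(base, shells, compute_se=False)
            if lrt(full, reduced).p_value < 0.05:
                hits += 1
        assert hits / n_reps >= 0.35


class TestContrasts:
    def test_saturated_two_level_matches_cell_log_odds(self):
        """With groups orthogonal to the factor the contrast equals the
        difference of hand-computed cell log-odds."""
        rows = []
        for grp in range(6):
            for lvl, occ in (("A", [1, 1, 0, 0, 0]), ("B", [1, 1, 1, 1, 0])):
                for y in occ:
                    rows.append({"group_id": f"g{grp}", "member_type": lvl, "y": y})
        df = pd.DataFrame(rows)
        fit = fit_glmm(
            ModelSpec("y", ["member_type"], group="group_id", references={"member_type": "A"}),
            df,
        )
        res = contrast(fit, "member_type", "B", "A")
        hand = np.log((4 / 5) / (1 / 5)) - np.log((2 / 5) / (3 / 5))
        assert res["estimate"] == pytest.approx(hand, abs=1e-3)

    def test_self_contrast_is_null(self, default_table):
        shells, _ = default_table
        fit = fit_glmm(ModelSpec("occupied", ["location"], group="group_id"), shells)
        res = contrast(fit, "location", "surface", "surface")
        assert res["estimate"] == 0.0 and np.isnan(res["z"]) and np.isnan(res["p"])

    def test_all_pairs_enumerated(self, default_table):
        shells, _ = default_table
        fit = fit_glmm(ModelSpec("occupied", ["location"], group="group_id"), shells)
        tab = wald_contrasts(fit, "location")
        assert len(tab) == 1  # 2 choose 2 pairs
        with pytest.raises(SchemaError):
            wald_contrasts(fit, "entrance_cm_s")


class TestVIF:
    def test_orthogonal_design_unit_gvif(self):
        rng = np.random.default_rng(5)
        n = 4000
        df = pd.DataFrame({"y": rng.integers(0, 2, n), "x1": rng.normal(size=n)})
        df["x2"] = rng.normal(size=n)
        out = vif(ModelSpec("y", ["x1", "x2"]), df)
        assert out["x1"] == pytest.approx(1.0, abs=0.01)

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(6)
        n = 6000
        x1 = rng.normal(size=n)
        x2 = 0.8 * x1 + np.sqrt(1 - 0.64) * rng.normal(size=n)
        df = pd.DataFrame({"y": rng.integers(0, 2, n), "x1": x1, "x2": x2})
        out = vif(ModelSpec("y", ["x1", "x2"]), df)
        assert out["x1"] == pytest.approx(1.0 / (1.0 - 0.8**2), rel=0.02)

    def test_perfect_collinearity_aliased(self):
        from shellrank.errors import AliasingError

        df = pd.DataFrame({"y": [0, 1, 0, 1], "x1": [1.0, 2.0, 3.0, 4.0]})
        df["x2"] = df["x1"]
        with pytest.raises(AliasingError):
            vif(ModelSpec("y", ["x1", "x2"]), df)
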