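"""Association models: chi-square screening, the multinomial Newton-Raphson
fitter (cross-checked against an independently coded binary IRLS and against
statsmodels' MNLogit), backward elimination and VIF diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cfmkit.models import (
    backward_eliminate,
    build_design_matrix,
    chisq_screen,
    fit_multinomial,
    lr_test_block,
    or_table,
    vif,
)


def irls_binary_logit(X: np.ndarray, y: np.ndarray, tol=1e-12, max_iter=60):
    """Independent binary-logistic IRLS fit used as an oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        delta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (y - p))
        beta = beta + delta
        if np.abs(delta).max() < tol:
            break
    return beta


def _binary_frame(a, b, c, d):
    """2x2 layout: exposure x outcome cell counts (a,b,c,d)."""
    return pd.DataFrame(
        {
            "x": ["e"] * (a + b) + ["u"] * (c + d),
            "y": ["1"] * a + ["0"] * b + ["1"] * c + ["0"] * d,
        }
    )


class TestChisqScreen:
    def test_identical_proportions_give_zero(self):
        df = _binary_frame(10, 10, 10, 10)
        stat, dof, p = chisq_screen(df, "x", "y")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 1 and p == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # (30,10 / 10,30): every expected count is 20, X^2 = 4 * 100/20 = 20
        df = _binary_frame(30, 10, 10, 30)
        stat, dof, p = chisq_screen(df, "x", "y")
        assert stat == pytest.approx(20.0, abs=1e-9)
        assert dof == 1

    def test_three_by_two_matches_brute_force_expected_counts(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "x": rng.choice(["a", "b", "c"], 300),
                "y": rng.choice(["0", "1"], 300),
            }
        )
        stat, dof, _ = chisq_screen(df, "x", "y")
        obs = pd.crosstab(df["x"], df["y"]).to_numpy().astype(float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-9)
        assert dof == 2

    def test_degenerate_table_rejected(self):
        df = pd.DataFrame({"x": ["a"] * 10, "y": ["0", "1"] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            chisq_screen(df, "x", "y")


class TestFitMultinomial:
    def test_null_covariate_gives_unit_odds_ratio(self):
        df = _binary_frame(20, 20, 30, 30)
        dm = build_design_matrix(df, ["x"])
        fit = fit_multinomial(dm, df["y"], "0")
        assert fit.converged
        assert np.exp(fit.coefficients[0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_cross_product_ratio_recovered_exactly(self):
        # cells (10,20,5,40): OR = (10*40)/(20*5) = 4
        df = _binary_frame(10, 20, 5, 40)
        dm = build_design_matrix(df, ["x"], reference_levels={"x": "u"})
        fit = fit_multinomial(dm, df["y"], "0")
        assert np.exp(fit.coefficients[0, 1]) == pytest.approx(4.0, abs=1e-8)

    def test_binary_reduction_equals_independent_irls(self):
        rng = np.random.default_rng(21)
        n = 800
        df = pd.DataFrame(
            {
                "x1": rng.choice(["a", "b"], n),
                "x2": rng.choice(["p", "q", "r"], n),
            }
        )
        eta = -0.4 + 0.8 * (df["x1"] == "b") - 0.5 * (df["x2"] == "q")
        df["y"] = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "1", "0")
        dm = build_design_matrix(df, ["x1", "x2"])
        fit = fit_multinomial(dm, df["y"], "0")
        beta_oracle = irls_binary_logit(dm.X, (df["y"] == "1").to_numpy(float))
        np.testing.assert_allclose(fit.coefficients[0], beta_oracle, atol=1e-8)

    def test_three_level_outcome_matches_statsmodels_mnlogit(self):
        rng = np.random.default_rng(33)
        n = 1500
        x = rng.choice([0.0, 1.0], n)
        lin1 = -0.2 + 0.9 * x
        lin2 = -1.0 + 0.4 * x
        denom = 1 + np.exp(lin1) + np.exp(lin2)
        u = rng.random(n)
        p1 = np.exp(lin1) / denom
        p2 = np.exp(lin2) / denom
        y = np.where(u < p1, "b", np.where(u < p1 + p2, "c", "a"))
        df = pd.DataFrame({"x": np.where(x > 0, "yes", "no"), "y": y})
        dm = build_design_matrix(df, ["x"])
        fit = fit_multinomial(dm, df["y"], "a")

        sm_fit = sm.MNLogit(
            pd.Categorical(df["y"], categories=["a", "b", "c"]).codes,
            sm.add_constant((df["x"] == "yes").astype(float)),
        ).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, sm_fit.params.T, atol=1e-6)

    def test_planted_coefficients_recovered_within_three_se(self):
        rng = np.random.default_rng(99)
        n = 20_000
        x = rng.choice([0.0, 1.0], n)
        truth = {"b": (-0.5, 0.7), "c": (-1.2, -0.4)}
        lin = {k: a + b * x for k, (a, b) in truth.items()}
        denom = 1 + sum(np.exp(v) for v in lin.values())
        u = rng.random(n)
        pb = np.exp(lin["b"]) / denom
        pc = np.exp(lin["c"]) / denom
        y = np.where(u < pb, "b", np.where(u < pb + pc, "c", "a"))
        df = pd.DataFrame({"x": np.where(x > 0, "yes", "no"), "y": y})
        dm = build_design_matrix(df, ["x"])
        fit = fit_multinomial(dm, df["y"], "a")
        se = fit.standard_errors()
        for k, level in enumerate(fit.outcome_levels[1:]):
            for j, true_val in enumerate(truth[level]):
                assert abs(fit.coefficients[k, j] - true_val) < 3 * se[k, j]

    def test_loglik_nondecreasing_and_convergence_reported(self):
        df = _binary_frame(12, 18, 25, 45)
        dm = build_design_matrix(df, ["x"])
        fit = fit_multinomial(dm, df["y"], "0")
        assert fit.converged and fit.n_iterations <= 100
        assert np.isfinite(fit.loglik)

    def test_separation_triggers_flagged_ridge_fallback(self):
        df = _binary_frame(30, 0, 0, 30)  # perfectly separated
        dm = build_design_matrix(df, ["x"])
        fit = fit_multinomial(dm, df["y"], "0")
        assert fit.separation_flag
        assert fit.ridge > 0


class TestBackwardElimination:
    @staticmethod
    def _simulate(rng, n, beta_strong):
        x_null = rng.choice(["a", "b"], n)
        x_strong = rng.choice(["no", "yes"], n)
        eta = -1.0 + beta_strong * (x_strong == "yes")
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "1", "0")
        return pd.DataFrame({"x_null": x_null, "x_strong": x_strong, "y": y})

    def test_null_removed_strong_retained(self):
        rng = np.random.default_rng(4)
        df = self._simulate(rng, 20_000, np.log(2.5))
        fit = backward_eliminate(df, "y", ["x_null", "x_strong"], ref_outcome="0")
        assert fit.retained_covariates == ["x_strong"]
        assert fit.eliminated[0][0] == "x_null"

    def test_all_strong_covariates_survive(self):
        rng = np.random.default_rng(6)
        n = 8000
        x1 = rng.choice(["a", "b"], n)
        x2 = rng.choice(["no", "yes"], n)
        eta = -0.5 + 0.8 * (x1 == "b") + 0.7 * (x2 == "yes")
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "1", "0")
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        fit = backward_eliminate(df, "y", ["x1", "x2"], ref_outcome="0")
        assert sorted(fit.retained_covariates) == ["x1", "x2"]
        assert fit.eliminated == []

    def test_empty_covariate_list_gives_intercept_only(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.choice(["0", "1"], 100)})
        fit = backward_eliminate(df, "y", [], ref_outcome="0")
        assert fit.retained_covariates == []
        assert fit.design.p == 1

    def test_lr_test_block_df_counts_levels_times_equations(self):
        rng = np.random.default_rng(10)
        n = 600
        df = pd.DataFrame(
            {
                "x": rng.choice(["p", "q", "r"], n),   # 2 dummies
                "y": rng.choice(["a", "b", "c"], n),   # 2 equations
            }
        )
        dm = build_design_matrix(df, ["x"])
        fit = fit_multinomial(dm, df["y"], "a")
        _, dof, p = lr_test_block(fit, df["y"], "x")
        assert dof == 4
        assert 0.0 <= p <= 1.0


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self):
        rng = np.random.default_rng(12)
        n = 4000
        df = pd.DataFrame(
            {
                "x1": rng.choice(["a", "b"], n),
                "x2": rng.choice(["c", "d"], n),
            }
        )
        dm = build_design_matrix(df, ["x1", "x2"])
        for v in vif(dm).values():
            assert v == pytest.approx(1.0, abs=0.05)

    def test_duplicated_column_flagged_infinite(self):
        import cfmkit.models as m

        rng = np.random.default_rng(13)
        x = rng.choice([0.0, 1.0], 200)
        dm = m.DesignMatrix(
            X=np.column_stack([np.ones(200), x, x]),
            columns=["intercept", "x", "x_copy"],
            covariate_blocks={"x": [1], "x_copy": [2]},
            reference_levels={"x": "0", "x_copy": "0"},
        )
        assert np.isinf(vif(dm)["x"])

    def test_constructed_r2_three_quarters_gives_vif_four(self):
        import cfmkit.models as m

        rng = np.random.default_rng(14)
        n = 50_000
        x1 = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        x2 = x1 + noise * np.sqrt(1 / 3)   # R^2 = var(x1)/var(x2) = 0.75
        dm = m.DesignMatrix(
            X=np.column_stack([np.ones(n), x1, x2]),
            columns=["intercept", "x1", "x2"],
            covariate_blocks={"x1": [1], "x2": [2]},
            reference_levels={},
        )
        assert vif(dm)["x2"] == pytest.approx(4.0, abs=0.2)

    def test_invariant_to_column_scaling(self):
        import cfmkit.models as m

        rng = np.random.default_rng(15)
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = 0.6 * x1 + rng.standard_normal(n)
        base = np.column_stack([np.ones(n), x1, x2])
        scaled = base.copy()
        scaled[:, 2] *= 100.0
        kw = dict(columns=["intercept", "x1", "x2"],
                  covariate_blocks={"x1": [1], "x2": [2]}, reference_levels={})
        v1 = vif(m.DesignMatrix(X=base, **kw))
        v2 = vif(m.DesignMatrix(X=scaled, **kw))
        assert v1["x2"] == pytest.approx(v2["x2"], rel=1e-9)


class TestOrTable:
    def test_reference_rows_and_planted_effect(self):
        rng = np.random.default_rng(16)
        n = 12_000
        x = rng.choice(["no", "yes"], n)
        eta = -1.0 + np.log(2.0) * (x == "yes")
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), "1", "0")
        df = pd.DataFrame({"x": x, "y": y})
        dm = build_design_matrix(df, ["x"])
        fit = fit_multinomial(dm, df["y"], "0")
        table = or_table({"m": fit})
        ref = table[table["is_reference"]]
        assert (ref["or_value"] == 1.0).all()
        assert ref["ci_low"].isna().all()
        row = table[(table["level"] == "yes")].iloc[0]
        assert row["significant"]
        # planted OR 2.0 within 3 SE on the log scale
        se_log = (np.log(row["ci_high"]) - np.log(row["or_value"])) / 1.959963984540054
        assert abs(np.log(row["or_value"]) - np.log(2.0)) < 3 * se_log

    def test_wald_coverage_near_nominal(self):
        # ~95% of Wald CIs should cover a planted coefficient
        rng = np.random.default_rng(17)
        n, reps, hits = 5000, 120, 0
        beta = 0.5
        for _ in range(reps):
            x = rng.choice([0.0, 1.0], n)
            eta = -0.8 + beta * x
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            X = np.column_stack([np.ones(n), x])
            b = irls_binary_logit(X, y)
            p = 1 / (1 + np.exp(-(X @ b)))
            cov = np.linalg.inv(X.T @ (X * (p * (1 - p))[:, None]))
            se = np.sqrt(cov[1, 1])
            hits += abs(b[1] - beta) < 1.959963984540054 * se
        assert 0.90 <= hits / reps <= 0.99
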