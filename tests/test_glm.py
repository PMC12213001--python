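"""GLM fitting, backward AIC selection, type-3 tests and adjusted D²."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sinupath import GLMSpec, backward_select, fit_glm, type3_anova
from sinupath.errors import AliasedTermError, ConfigError
from sinupath.glm import (
    adjusted_d2_value,
    build_design,
    model_report,
    significance_band,
)
from sinupath.groupstats import one_way_anova
from sinupath.simulate import simulate_glm_responses


def covariate_frame(rng, n):
    return pd.DataFrame({
        "FEMU": rng.normal(0, 1, n),
        "STER": rng.normal(0, 1, n),
        "PGI": rng.normal(0, 1, n),
        "PYRU": rng.normal(0, 1, n),
        "LOC": rng.choice(["POC", "PELIS", "ISB", "VST"], n),
        "SEX": rng.choice(["male", "female"], n),
    })


class TestFitGLM:
    def test_gaussian_intercept_only(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        fit = fit_glm(GLMSpec("y", "gaussian", ()), data)
        assert fit.params["Intercept"] == pytest.approx(2.0)
        assert fit.deviance == pytest.approx(2.0)  # residual SS
        assert fit.d2 == 0.0 and fit.adj_d2 == 0.0

    def test_poisson_intercept_only(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        fit = fit_glm(GLMSpec("y", "poisson", ()), data)
        assert fit.params["Intercept"] == pytest.approx(np.log(2.0))

    def test_gaussian_matches_normal_equations(self, rng):
        # oracle: closed-form least squares
        data = covariate_frame(rng, 60)
        data["y"] = 1.0 + 2.0 * data["FEMU"] + rng.normal(0, 0.5, 60)
        fit = fit_glm(GLMSpec("y", "gaussian", ("FEMU",)), data)
        X = np.column_stack([np.ones(60), data["FEMU"]])
        beta = np.linalg.solve(X.T @ X, X.T @ data["y"])
        assert fit.params["Intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params["FEMU"] == pytest.approx(beta[1], abs=1e-10)

    def test_aic_identity(self, rng):
        data = covariate_frame(rng, 50)
        data["y"] = rng.normal(0, 1, 50)
        for family in ("gaussian",):
            fit = fit_glm(GLMSpec("y", family, ("FEMU", "LOC")), data)
            assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.p_params)

    def test_sum_to_zero_contrasts(self, rng):
        data = covariate_frame(rng, 80)
        design = build_design(data, ("LOC",))
        # each contrast column sums to zero over a balanced replication of levels
        levels = sorted(data["LOC"].unique())
        one_each = pd.DataFrame({"LOC": levels})
        d1 = build_design(one_each, ("LOC",))
        assert np.allclose(d1.X[:, 1:].sum(axis=0), 0.0)
        assert design.X.shape[1] == 4  # intercept + 3 contrasts

    def test_rank_deficiency_names_terms(self, rng):
        data = covariate_frame(rng, 40)
        data["PGI"] = 2.0 * data["FEMU"]
        with pytest.raises(AliasedTermError, match="FEMU|PGI"):
            fit_glm(GLMSpec("FEMU", "gaussian", ("FEMU", "PGI")), data.assign(y=1.0))

    def test_poisson_negative_response_rejected(self):
        data = pd.DataFrame({"y": [-1.0, 2.0, 3.0]})
        with pytest.raises(ConfigError):
            fit_glm(GLMSpec("y", "poisson", ()), data)


class TestAdjustedD2:
    def test_formula_case(self):
        assert adjusted_d2_value(0.5, n=48, p=5) == pytest.approx(
            1 - (47 / 43) * 0.5)

    def test_perfect_fit(self):
        assert adjusted_d2_value(1.0, n=10, p=3) == 1.0

    def test_undefined_when_saturated(self):
        with pytest.raises(ConfigError):
            adjusted_d2_value(0.5, n=5, p=5)


class TestBackwardSelect:
    def test_minimal_model_unchanged(self, rng):
        data = covariate_frame(rng, 150)
        data["y"] = 3.0 * data["FEMU"] + rng.normal(0, 0.3, 150)
        fit = backward_select(GLMSpec("y", "gaussian", ("FEMU",)), data)
        assert fit.spec.terms == ("FEMU",)

    def test_marginality_protects_main_effects(self, rng):
        data = covariate_frame(rng, 200)
        rng2 = np.random.default_rng(7)
        design = build_design(data, ("LOC", "FEMU", "LOC:FEMU"))
        X = pd.DataFrame(design.X, columns=design.columns)
        # strong interaction, null main effects
        data["y"] = simulate_glm_responses(
            X, {"Intercept": 1.0, "LOC[S.ISB]:FEMU": 2.0}, "gaussian", 1.0, rng2)
        fit = backward_select(
            GLMSpec("y", "gaussian", ("LOC", "FEMU", "LOC:FEMU")), data)
        if "LOC:FEMU" in fit.spec.terms:
            assert {"LOC", "FEMU"} <= set(fit.spec.terms)

    def test_no_marginality_mode_can_drop_main(self, rng):
        spec = GLMSpec("y", "gaussian", ("LOC", "FEMU", "LOC:FEMU"),
                       enforce_marginality=False)
        assert set(spec.droppable_terms()) == {"LOC", "FEMU", "LOC:FEMU"}

    def test_pure_noise_prunes_to_near_empty_model(self):
        """Under the null each term survives AIC deletion with probability
        P(chi2_1 > 2) ~ 0.157, so the modal outcome is the intercept-only
        model and on average fewer than one noise term survives."""
        wins, kept_terms = 0, 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            data = covariate_frame(rng, 120)
            data["y"] = rng.normal(0, 1, 120)
            fit = backward_select(
                GLMSpec("y", "gaussian", ("FEMU", "STER", "PGI", "PYRU")), data)
            wins += fit.spec.terms == ()
            kept_terms += len(fit.spec.terms)
        assert wins >= 12  # theory: ~0.5 * n_rep
        assert kept_terms / n_rep < 1.5  # theory: ~0.63

    def test_nested_aic_bound(self, rng):
        # the supermodel's likelihood is at least the submodel's
        data = covariate_frame(rng, 100)
        data["y"] = data["FEMU"] + rng.normal(0, 1, 100)
        full = fit_glm(GLMSpec("y", "gaussian", ("FEMU", "STER")), data)
        sub = fit_glm(GLMSpec("y", "gaussian", ("FEMU",)), data)
        assert sub.aic >= full.aic - 2 * 1  # one dropped parameter


class TestType3:
    def test_balanced_single_factor_equals_anova_f(self, rng):
        data = pd.DataFrame({
            "LOC": np.repeat(["POC", "VST"], 15),
            "SEX": ["male"] * 30,
            "y": rng.normal(0, 1, 30) + np.repeat([0.0, 1.0], 15),
        })
        fit = fit_glm(GLMSpec("y", "gaussian", ("LOC",)), data)
        table = type3_anova(fit, data)
        ref = one_way_anova(data["y"], data["LOC"])
        row = table.set_index("term").loc["LOC"]
        assert row["stat"] == pytest.approx(ref.F)
        assert row["p"] == pytest.approx(ref.p_value)

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            data = covariate_frame(rng, 100)
            data["y"] = data["FEMU"] * 1.0 + rng.normal(0, 1, 100)
            fit = fit_glm(GLMSpec("y", "gaussian", ("FEMU", "STER")), data)
            table = type3_anova(fit, data).set_index("term")
            pvals.append(table.loc["STER", "p"])  # STER truly null
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_p_invariant_to_covariate_rescaling(self, rng):
        data = covariate_frame(rng, 80)
        data["y"] = data["FEMU"] + rng.normal(0, 1, 80)
        t1 = type3_anova(fit_glm(GLMSpec("y", "gaussian", ("FEMU", "STER")), data),
                         data).set_index("term")["p"]
        data2 = data.assign(FEMU=100 * data["FEMU"] + 3, STER=0.1 * data["STER"])
        t2 = type3_anova(fit_glm(GLMSpec("y", "gaussian", ("FEMU", "STER")), data2),
                         data2).set_index("term")["p"]
        pd.testing.assert_series_equal(t1, t2, atol=1e-9, rtol=0)

    def test_bands(self):
        assert significance_band(0.0005) == "***"
        assert significance_band(0.005) == "**"
        assert significance_band(0.03) == "*"
        assert significance_band(0.07) == "•"
        assert significance_band(0.5) == ""


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstR:
    def test_type3_and_aic_match_r(self, tmp_path, rng):
        """car::Anova(type=3) with sum contrasts and stats::AIC as oracle."""
        data = covariate_frame(rng, 60)
        data["y"] = (1.0 + 0.8 * data["FEMU"]
                     + (data["LOC"] == "POC") * 1.2 + rng.normal(0, 1, 60))
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            d <- read.csv("{csv}")
            d$LOC <- factor(d$LOC); d$SEX <- factor(d$SEX)
            options(contrasts = c("contr.sum", "contr.poly"))
            m <- lm(y ~ LOC + SEX + FEMU, data = d)
            a <- car::Anova(m, type = 3)
            cat(AIC(m), a["LOC", "F value"], a["LOC", "Pr(>F)"],
                a["FEMU", "F value"], a["FEMU", "Pr(>F)"], sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r_aic, r_f_loc, r_p_loc, r_f_femu, r_p_femu = map(
            float, out.stdout.strip().split("\n"))
        fit = fit_glm(GLMSpec("y", "gaussian", ("LOC", "SEX", "FEMU")), data)
        table = type3_anova(fit, data).set_index("term")
        assert fit.aic == pytest.approx(r_aic, rel=1e-6)
        assert table.loc["LOC", "stat"] == pytest.approx(r_f_loc, rel=1e-6)
        assert table.loc["LOC", "p"] == pytest.approx(r_p_loc, rel=1e-5)
        assert table.loc["FEMU", "stat"] == pytest.approx(r_f_femu, rel=1e-6)
        assert table.loc["FEMU", "p"] == pytest.approx(r_p_femu, rel=1e-5)


class TestModelReport:
    def test_grid_and_long_table_consistent(self, rng):
        data = covariate_frame(rng, 90)
        data["length_m"] = 1 + data["FEMU"] + rng.normal(0, 1, 90)
        data["TE"] = rng.poisson(3.0, 90).astype(float)
        grid, long_table, fits = model_report(
            data, responses=["length_m", "TE"],
            full_terms=("LOC", "SEX", "FEMU"))
        assert set(grid.columns) == {"length_m", "TE"}
        assert fits["TE"].spec.family == "poisson"
        kept = long_table.query("response == 'length_m'")["term"].tolist()
        assert all(grid.loc[t, "length_m"] != "—" for t in kept)
        assert (long_table["adj_D2"] <= long_table["D2"] + 1e-12).all()
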