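"""zcpLMM engine: design assembly, estimation, inference, model comparison."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from fixdur.lmm import (
    FEATURE_TERMS,
    FULL_FIXED_TERMS,
    ModelSpec,
    build_design,
    compare_models,
    count_random_params,
    feature_only_spec,
    fit_zcplmm,
    fixed_effect_tests,
    full_zcp_spec,
    log_duration,
    nonfeature_spec,
    r2_lmm,
    reduce_random_structure,
    standardize,
)


def crossed_data(seed=42, ns=12, ni=20, reps=2, sd_subj=0.5, sd_item=0.3,
                 sd_slope=0.2, sd_e=0.4):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(ns):
        for i in range(ni):
            for _ in range(reps):
                rows.append((f"s{s:02d}", f"i{i:02d}", rng.normal(), rng.normal()))
    df = pd.DataFrame(rows, columns=["subj", "item", "x1", "x2"])
    us = rng.normal(0, sd_subj, ns)
    ui = rng.normal(0, sd_item, ni)
    ss = rng.normal(0, sd_slope, ns)
    sc = df["subj"].str[1:].astype(int)
    ic = df["item"].str[1:].astype(int)
    df["y"] = (
        2.0 + 0.5 * df.x1 - 0.3 * df.x2 + us[sc] + ui[ic] + ss[sc] * df.x1
        + rng.normal(0, sd_e, len(df))
    )
    return df


SPEC2 = ModelSpec(
    fixed_terms=("1", "x1", "x2"), random={"subj": ("1", "x1"), "item": ("1",)}
)


class TestTransforms:
    def test_standardize_matches_formula_oracle(self, rng):
        x = rng.normal(3, 2.5, 200)
        z, mean, sd = standardize(x)
        np.testing.assert_allclose(z, (x - x.mean()) / x.std(ddof=1), atol=1e-12)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_standardize_idempotent_up_to_fp(self):
        z, _, _ = standardize([1.0, 2.0, 3.0])
        z2, mean, sd = standardize(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(1.0, abs=1e-12)

    def test_standardize_rejects_constant(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(np.ones(10))

    def test_log_duration(self):
        assert log_duration(1.0) == 0.0
        assert log_duration(np.e) == pytest.approx(1.0)
        d = np.array([53.0, 250.0, 999.0])
        np.testing.assert_allclose(np.exp(log_duration(d)), d)
        with pytest.raises(ValueError):
            log_duration(0.0)


class TestSpecsAndCounting:
    def test_full_model_has_23_fixed_effects(self):
        assert len(FULL_FIXED_TERMS) == 23
        assert len(FEATURE_TERMS) == 15

    def test_parameter_counting_formulas(self):
        # 23 terms: 23 variances + 253 correlations = 276 per factor;
        # two factors plus two extra intercepts = 554 maximal parameters
        assert count_random_params(23, "maximal") == 276
        assert count_random_params(23, "maximal") - 23 == 253
        assert 2 * count_random_params(23, "maximal") + 2 == 554
        assert count_random_params(1, "maximal") == 1
        assert count_random_params(23, "zero_correlation") == 23

    def test_full_zcp_spec_has_48_components(self):
        assert full_zcp_spec().n_components == 48

    def test_reduction_removes_17_components(self):
        spec = full_zcp_spec()
        red = reduce_random_structure(spec)
        assert red.n_components == 31
        assert spec.n_components - red.n_components == 17
        # idempotent
        assert reduce_random_structure(red).n_components == 31
        # by-subject feature slopes gone, by-item feature slopes retained
        assert not set(red.random["subject_id"]) & set(FEATURE_TERMS)
        assert set(FEATURE_TERMS) <= set(red.random["scene_id"])
        assert "sacc_amp_prev_sq" not in red.random["scene_id"]

    def test_partial_model_specs(self):
        red = reduce_random_structure(full_zcp_spec())
        nf = nonfeature_spec(red)
        assert len(nf.fixed_terms) == 8
        assert nf.n_components == 16
        fo = feature_only_spec(red)
        assert len(fo.fixed_terms) == 16


class TestBuildDesign:
    def test_full_spec_yields_23_columns(self, rng):
        n = 60
        df = pd.DataFrame(
            {t: rng.normal(size=n) for t in FULL_FIXED_TERMS if "_sq" not in t and t != "1"}
        )
        df["log_duration"] = rng.normal(5.5, 0.4, n)
        df["subject_id"] = rng.choice(["a", "b", "c"], n)
        df["scene_id"] = rng.choice([f"sc{i}" for i in range(6)], n)
        spec = ModelSpec(
            fixed_terms=tuple(FULL_FIXED_TERMS),
            random={"subject_id": ("1",), "scene_id": ("1",)},
        )
        dm = build_design(df, spec)
        assert dm.X.shape == (n, 23)
        # quadratic columns are elementwise squares of the linear columns
        j_lin = dm.fixed_names.index("sacc_amp_prev")
        j_sq = dm.fixed_names.index("sacc_amp_prev_sq")
        np.testing.assert_allclose(dm.X[:, j_sq], dm.X[:, j_lin] ** 2)

    def test_one_predictor_spec_yields_two_columns(self, rng):
        df = pd.DataFrame(
            {
                "contrast_curr": rng.normal(size=40),
                "log_duration": rng.normal(size=40),
                "subject_id": rng.choice(["a", "b"], 40),
            }
        )
        spec = ModelSpec(fixed_terms=("1", "contrast_curr"),
                         random={"subject_id": ("1", "contrast_curr")})
        dm = build_design(df, spec)
        assert dm.X.shape[1] == 2
        assert dm.Z.shape[1] == 4  # 2 components x 2 subjects

    def test_unknown_predictor_rejected(self, rng):
        df = pd.DataFrame({"log_duration": rng.normal(size=10),
                           "subject_id": ["a", "b"] * 5})
        spec = ModelSpec(fixed_terms=("1", "nope"), random={"subject_id": ("1",)})
        with pytest.raises(KeyError):
            build_design(df, spec)


class TestFitting:
    def test_noiseless_limit_recovers_ols_exactly(self):
        # all random variances zero, residual -> 0: the fit degenerates to
        # least squares on the fixed effects
        rng = np.random.default_rng(7)
        df = crossed_data(seed=7, sd_subj=0.0, sd_item=0.0, sd_slope=0.0, sd_e=1e-8)
        dm = build_design(df, SPEC2, response="y")
        fit = fit_zcplmm(dm, "REML")
        bols, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
        np.testing.assert_allclose(fit.b, bols, atol=1e-6)

    def test_balanced_one_way_matches_method_of_moments(self):
        rng = np.random.default_rng(3)
        g, m = 8, 10
        a = rng.normal(0, 0.7, g)
        rows = [(f"g{i}", 3.0 + a[i] + rng.normal(0, 0.5)) for i in range(g)
                for _ in range(m)]
        df = pd.DataFrame(rows, columns=["grp", "y"])
        spec = ModelSpec(fixed_terms=("1",), random={"grp": ("1",)})
        fit = fit_zcplmm(build_design(df, spec, response="y"), "REML")
        gm = df.groupby("grp")["y"].mean()
        msb = m * gm.var(ddof=1)
        msw = (
            df.groupby("grp")["y"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum()
            / (g * (m - 1))
        )
        assert fit.variance_components["grp:1"] == pytest.approx(
            (msb - msw) / m, rel=1e-4
        )
        assert fit.residual_var == pytest.approx(msw, rel=1e-4)

    def test_reml_and_ml_agree_on_b_for_balanced_orthogonal_design(self):
        # identical covariate pattern in every group: the GLS weights cancel
        # and the fixed effects are invariant to the estimation criterion
        rng = np.random.default_rng(11)
        g, m = 10, 8
        pattern = np.linspace(-1, 1, m)
        rows = []
        for i in range(g):
            u = rng.normal(0, 0.6)
            for j in range(m):
                rows.append((f"g{i}", pattern[j],
                             1.0 + 0.8 * pattern[j] + u + rng.normal(0, 0.3)))
        df = pd.DataFrame(rows, columns=["grp", "x", "y"])
        spec = ModelSpec(fixed_terms=("1", "x"), random={"grp": ("1",)})
        dm = build_design(df, spec, response="y")
        fit_reml = fit_zcplmm(dm, "REML")
        fit_ml = fit_zcplmm(dm, "ML")
        np.testing.assert_allclose(fit_reml.b, fit_ml.b, atol=1e-8)

    def test_variance_components_nonnegative_and_t_is_b_over_se(self):
        df = crossed_data(seed=5)
        fit = fit_zcplmm(build_design(df, SPEC2, response="y"), "REML")
        assert all(v >= 0 for v in fit.variance_components.values())
        np.testing.assert_allclose(fit.t, fit.b / fit.se)

    def test_too_few_observations_rejected(self):
        df = crossed_data(seed=1).head(3)
        with pytest.raises(ValueError):
            fit_zcplmm(build_design(df, SPEC2, response="y"))

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_against_lme4_oracle(self, tmp_path):
        """Independent cross-check: estimates, SEs, variance components and
        both criteria must match lme4 on a crossed zcpLMM."""
        df = crossed_data(seed=42)
        dm = build_design(df, SPEC2, response="y")
        reml = fit_zcplmm(dm, "REML")
        ml = fit_zcplmm(dm, "ML")
        csv = tmp_path / "crossed.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent(f"""
            library(lme4)
            df <- read.csv('{csv}')
            df$zx1 <- as.numeric(scale(df$x1)); df$zx2 <- as.numeric(scale(df$x2))
            m <- lmer(y ~ zx1 + zx2 + (1|subj) + (0+zx1|subj) + (1|item),
                      data=df, REML=TRUE)
            co <- summary(m)$coefficients
            vc <- as.data.frame(VarCorr(m))
            cat(co[,1], co[,2], vc$vcov, REMLcrit(m), deviance(refitML(m)), sep='\\n')
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        b_r, se_r = vals[0:3], vals[3:6]
        vc_r = vals[6:10]  # item:1, subj:x1, subj:1, residual (lme4 order)
        np.testing.assert_allclose(reml.b, b_r, rtol=1e-5)
        np.testing.assert_allclose(reml.se, se_r, rtol=1e-4)
        np.testing.assert_allclose(
            [reml.variance_components["item:1"],
             reml.variance_components["subj:x1"],
             reml.variance_components["subj:1"],
             reml.residual_var],
            vc_r, rtol=1e-3, atol=1e-6,
        )
        assert reml.deviance == pytest.approx(vals[10], abs=1e-3)
        assert ml.deviance == pytest.approx(vals[11], abs=1e-3)


class TestInference:
    def test_significance_labels(self):
        df = crossed_data(seed=13)
        fit = fit_zcplmm(build_design(df, SPEC2, response="y"), "REML")
        labels = fixed_effect_tests(fit)
        t = np.array([2.0, -1.7, 1.0])
        fit.b = t.copy()
        fit.se = np.ones(3)
        labels = fixed_effect_tests(fit)
        assert labels["label"].tolist() == [
            "significant", "marginal", "nonsignificant",
        ]

    def test_r2_pair_bounds_and_intercept_only_marginal_zero(self):
        df = crossed_data(seed=17)
        spec0 = ModelSpec(fixed_terms=("1",), random={"subj": ("1",), "item": ("1",)})
        fit = fit_zcplmm(build_design(df, spec0, response="y"), "REML")
        r2 = r2_lmm(fit)
        assert r2.marginal == pytest.approx(0.0, abs=1e-10)
        assert 0 <= r2.marginal <= r2.conditional <= 1

    def test_r2_random_intercepts_match_interceptonly_formula(self):
        # with intercept-only random effects the slope-aware formula
        # collapses to var(Xb) / (var(Xb) + sum of intercept variances +
        # residual variance)
        df = crossed_data(seed=19, sd_slope=0.0)
        spec = ModelSpec(fixed_terms=("1", "x1", "x2"),
                         random={"subj": ("1",), "item": ("1",)})
        dm = build_design(df, spec, response="y")
        fit = fit_zcplmm(dm, "REML")
        r2 = r2_lmm(fit)
        var_f = np.var(dm.X @ fit.b)
        var_r = (fit.variance_components["subj:1"]
                 + fit.variance_components["item:1"])
        total = var_f + var_r + fit.residual_var
        assert r2.marginal == pytest.approx(var_f / total, rel=1e-10)
        assert r2.conditional == pytest.approx((var_f + var_r) / total, rel=1e-10)

    def test_all_variances_zero_marginal_equals_conditional(self):
        df = crossed_data(seed=23, sd_subj=0.0, sd_item=0.0, sd_slope=0.0)
        fit = fit_zcplmm(build_design(df, SPEC2, response="y"), "REML")
        r2 = r2_lmm(fit)
        assert r2.conditional - r2.marginal < 0.02


class TestModelComparison:
    def test_identical_models_give_zero_chi2_zero_df(self):
        df = crossed_data(seed=29)
        dm = build_design(df, SPEC2, response="y")
        fit = fit_zcplmm(dm, "ML")
        cmp = compare_models(fit, fit)
        assert cmp.lrt_chi2 == 0.0 and cmp.df == 0
        assert cmp.bic_full == cmp.bic_reduced

    def test_reml_fits_rejected(self):
        df = crossed_data(seed=29)
        dm = build_design(df, SPEC2, response="y")
        fit = fit_zcplmm(dm, "REML")
        with pytest.raises(ValueError, match="ML"):
            compare_models(fit, fit)

    def test_full_vs_nonfeature_df_is_30(self):
        # the final (reduced) model vs. the oculomotor-only partial model:
        # 15 fixed feature terms + 15 by-item feature slopes
        full = reduce_random_structure(full_zcp_spec())
        red = nonfeature_spec(full)
        df_param = (len(full.fixed_terms) + full.n_components) - (
            len(red.fixed_terms) + red.n_components
        )
        assert df_param == 30

    def test_nested_fit_comparison_detects_real_effect(self):
        df = crossed_data(seed=31)
        full_spec = SPEC2
        red_spec = ModelSpec(fixed_terms=("1", "x2"), random={"subj": ("1",),
                                                              "item": ("1",)})
        dm_full = build_design(df, full_spec, response="y")
        dm_red = build_design(df, red_spec, response="y")
        cmp = compare_models(
            fit_zcplmm(dm_full, "ML"), fit_zcplmm(dm_red, "ML")
        )
        assert cmp.df == 2  # one fixed effect + one variance component
        assert cmp.lrt_chi2 > 10
        assert cmp.p < 0.001
        assert cmp.bic_full < cmp.bic_reduced

    def test_null_lrt_is_approximately_chi2(self):
        # under a true null (x1 has no fixed effect and no slope), the LRT
        # statistic over replicates matches its chi-square reference
        rng = np.random.default_rng(0)
        red_spec = ModelSpec(fixed_terms=("1", "x2"),
                             random={"subj": ("1",), "item": ("1",)})
        stats = []
        for rep in range(40):
            df = crossed_data(seed=1000 + rep, ns=8, ni=10, reps=1,
                              sd_slope=0.0)
            df["y"] = df["y"] - 0.5 * df["x1"]  # remove the x1 effect
            dm_full = build_design(df, SPEC2, response="y")
            dm_red = build_design(df, red_spec, response="y")
            cmp = compare_models(
                fit_zcplmm(dm_full, "ML"), fit_zcplmm(dm_red, "ML")
            )
            stats.append(cmp.lrt_chi2)
        stats = np.array(stats)
        # df=2, but one parameter (the slope variance) sits on the boundary,
        # so the statistic is stochastically below chi2(2): mean <= 2
        assert 0.5 < stats.mean() < 2.6
        assert (stats > 5.99).mean() < 0.15  # nominal 5% cutoff not inflated
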