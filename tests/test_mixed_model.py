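"""Mixed-model estimation: oracle equivalence, LRT, structure selection.

The independent oracles are (i) explicit ordinary-least-squares linear
algebra on balanced single-experiment data and (ii) statsmodels
MixedLM with a plant random intercept, which is mathematically
identical to a compound-symmetry residual covariance.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
import statsmodels.api as sm

from episcreen import (
    compute_rosette_areas,
    estimate_repeatability,
    fit_leaf_model,
    fit_rosette_model,
    lr_test_gxe,
    null_screen_config,
    select_covariance_structure,
    simulate_screen,
)
from episcreen.covariance import cs_matrix

from conftest import make_rosettes


def ols_oracle(rosettes):
    """Brute-force GLS-free computation: cell-means OLS by hand."""
    y = np.log2(rosettes["rosette_area_mm2"].to_numpy(float))
    gcats = sorted(rosettes["genotype"].unique())
    X = (rosettes["genotype"].to_numpy()[:, None]
         == np.array(gcats, object)).astype(float)
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    df = len(y) - len(gcats)
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    return gcats, beta, cov


class TestRosetteModel:
    def test_noise_free_lsmeans_equal_group_means(self):
        ros = make_rosettes({("a", "E1"): [100.0] * 4,
                             ("b", "E1"): [120.0] * 4})
        fit = fit_rosette_model(ros)
        assert fit.lsmeans["a"] == pytest.approx(np.log2(100.0), abs=1e-12)
        assert fit.lsmeans["b"] == pytest.approx(np.log2(120.0), abs=1e-12)
        assert fit.variance_components["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_single_experiment_matches_ols_oracle(self, rng):
        ros = make_rosettes({
            (g, "E1"): rng.lognormal(np.log(100), 0.2, size=12)
            for g in ["a", "b", "c", "d"]})
        gcats, beta, cov = ols_oracle(ros)
        fit = fit_rosette_model(ros)
        np.testing.assert_allclose(fit.lsmeans[gcats].to_numpy(), beta,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.fixed_cov, cov, atol=1e-8)
        assert fit.structure is None and not fit.gxe_included

    def test_multi_experiment_uses_random_intercept(self, tiny_screen):
        _, ds = tiny_screen
        ros = compute_rosette_areas(ds)
        fit = fit_rosette_model(ros, gxe="off")
        assert fit.variance_components["experiment"] >= 0.0
        assert fit.n_used == len(ros)
        # LS-mean covariance is symmetric PSD
        V = fit.fixed_cov
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > -1e-12

    def test_absent_genotype_raises_naming_it(self, tiny_screen):
        _, ds = tiny_screen
        ros = compute_rosette_areas(ds)
        with pytest.raises(ValueError, match="ghost"):
            fit_rosette_model(ros, genotypes=["WT", "ghost"])

    def test_experiment_relabeling_invariance(self, tiny_screen):
        _, ds = tiny_screen
        ros = compute_rosette_areas(ds)
        fit1 = fit_rosette_model(ros, gxe="off")
        relabeled = ros.assign(
            experiment=ros["experiment"].map(
                {"E1": "Z9", "E2": "A0", "E3": "M5"}))
        fit2 = fit_rosette_model(relabeled, gxe="off")
        np.testing.assert_allclose(fit1.lsmeans.to_numpy(),
                                   fit2.lsmeans.to_numpy(), atol=1e-6)


class TestGxELrt:
    def test_single_experiment_not_testable(self):
        ros = make_rosettes({("a", "E1"): [100, 101, 99, 98],
                             ("b", "E1"): [120, 119, 121, 122]})
        res = lr_test_gxe(ros)
        assert not res.testable and not res.include_term
        assert res.p_value == 1.0

    def test_statistic_zero_gives_p_one(self):
        # chi2(1) reference points
        assert stats.chi2.sf(0.0, 1) == 1.0
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_null_gxe_rarely_included(self):
        # sigma2_gxe = 0: boundary chi2(1) test is conservative
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            cfg = null_screen_config(1, seed=300 + i, outlier_rate=0.0)
            ds = simulate_screen(cfg)
            ros = compute_rosette_areas(ds)
            res = lr_test_gxe(ros)
            assert res.statistic >= 0.0
            hits += res.include_term
        assert hits / n_rep <= 0.125  # 3 sigma above the nominal 0.05

    def test_large_gxe_detected(self):
        cfg = null_screen_config(1, seed=77, sigma2_gxe=0.05,
                                 n_experiments=4, outlier_rate=0.0)
        ds = simulate_screen(cfg)
        res = lr_test_gxe(compute_rosette_areas(ds))
        assert res.include_term


class TestLeafModel:
    def test_balanced_lsmeans_equal_cell_means(self, single_experiment_screen):
        _, ds = single_experiment_screen
        fit = fit_leaf_model(ds.measurements, structure="CS")
        cell = (ds.measurements.assign(y=np.log2(ds.measurements["area_mm2"]))
                .groupby(["genotype", "leaf"])["y"].mean())
        np.testing.assert_allclose(fit.lsmeans.to_numpy(),
                                   cell[fit.lsmeans.index].to_numpy(),
                                   atol=1e-10)

    def test_cs_matches_mixedlm_plant_intercept_oracle(
            self, single_experiment_screen):
        # CS residual covariance == plant random intercept + iid noise
        _, ds = single_experiment_screen
        fit = fit_leaf_model(ds.measurements, structure="CS")
        df = ds.measurements.assign(y=np.log2(ds.measurements["area_mm2"]))
        df["cell"] = (df["genotype"].astype(str) + ":"
                      + df["leaf"].astype(str))
        oracle = sm.MixedLM.from_formula(
            "y ~ 0 + C(cell)", groups="plant_id", re_formula="1",
            data=df).fit(reml=True)
        s2_plant = float(oracle.cov_re.iloc[0, 0])
        s2_res = float(oracle.scale)
        sigma = fit.variance_components["residual_cov"]
        assert sigma[0, 0] == pytest.approx(s2_plant + s2_res, rel=1e-3)
        assert sigma[0, 1] == pytest.approx(s2_plant, rel=1e-2, abs=1e-5)
        assert fit.loglik == pytest.approx(float(oracle.llf), abs=1e-3)

    def test_un_loglik_at_least_cs(self, single_experiment_screen):
        # model nesting under a common mean model
        _, ds = single_experiment_screen
        cs = fit_leaf_model(ds.measurements, structure="CS", reml=False)
        un = fit_leaf_model(ds.measurements, structure="UN", reml=False)
        assert un.loglik >= cs.loglik - 1e-6

    def test_unknown_structure_and_too_few_plants(self, single_experiment_screen):
        _, ds = single_experiment_screen
        with pytest.raises(ValueError, match="unknown covariance structure"):
            fit_leaf_model(ds.measurements, structure="XYZ")
        few = ds.measurements[
            ds.measurements["plant_id"].isin(
                ds.measurements["plant_id"].unique()[:4])]
        with pytest.raises(ValueError, match="simpler structure"):
            fit_leaf_model(few, structure="UN")

    def test_missing_leaves_still_fit(self):
        cfg = null_screen_config(
            1, seed=33, n_experiments=1, n_plants=30, sigma2_experiment=0.0,
            outlier_rate=0.0,
            leaf_emergence_probs=np.array([1, 1, 1, 1, 0.9, 0.8, 0.7]))
        ds = simulate_screen(cfg)
        fit = fit_leaf_model(ds.measurements, structure="CS")
        assert fit.n_used == len(
            ds.measurements[ds.measurements["leaf"] <= 6])
        assert len(fit.lsmeans) == 4 * 7


class TestStructureSelection:
    def test_cs_truth_prefers_cs_over_un(self):
        cfg = null_screen_config(
            1, seed=51, n_experiments=1, n_plants=40, sigma2_experiment=0.0,
            leaf_residual_cov=cs_matrix(0.05, 0.5, 7), outlier_rate=0.0,
            leaf_emergence_probs=np.ones(7))
        ds = simulate_screen(cfg)
        tag, table = select_covariance_structure(ds.measurements)
        assert tag == "CS"
        assert set(table.index) == {"CS", "AR1", "TOEP", "UN"}
        assert (table["n_params"] == [2, 2, 7, 28]).all()

    def test_tie_breaks_towards_fewer_parameters(self, monkeypatch):
        import episcreen.mixed_model as mm

        cfg = null_screen_config(1, seed=52, n_experiments=1, n_plants=15,
                                 sigma2_experiment=0.0, outlier_rate=0.0,
                                 leaf_emergence_probs=np.ones(7))
        ds = simulate_screen(cfg)

        real_fit = mm._StructuredLMM.fit

        def tied_fit(self):
            out = real_fit(self)
            out.aic = -1234.5  # synthetic exact tie
            return out

        monkeypatch.setattr(mm._StructuredLMM, "fit", tied_fit)
        tag, table = select_covariance_structure(ds.measurements)
        assert tag == "CS"


class TestRepeatability:
    def test_requires_crossed_design(self):
        ros = make_rosettes({("a", "E1"): [100, 101, 102]})
        with pytest.raises(ValueError):
            estimate_repeatability(ros)

    def test_no_genotype_variance_gives_h2_near_zero(self, rng):
        areas = {}
        for g in [f"g{i}" for i in range(12)]:
            for e in ["E1", "E2", "E3"]:
                areas[(g, e)] = rng.lognormal(np.log(100), 0.15, size=12)
        res = estimate_repeatability(make_rosettes(areas))
        assert 0.0 <= res.h2 <= 0.05

    def test_h2_bounded(self, tiny_screen):
        _, ds = tiny_screen
        res = estimate_repeatability(compute_rosette_areas(ds))
        assert 0.0 <= res.h2 <= 1.0
        assert set(res.component_estimates) >= {"genotype", "experiment",
                                                "gxe", "residual"}
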