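"""EXPni identities, Wald contrasts, BH correction and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from episcreen import (
    bh_adjust,
    compute_expni,
    compute_rosette_areas,
    epistasis_contrast,
    fit_rosette_model,
    null_screen_config,
    percent_ratios,
    simulate_screen,
)
from episcreen.epistasis import (
    ScreenSettings,
    classify_combination,
    classify_records,
    run_screen,
)
from episcreen.ingest import filter_outliers


class TestExpni:
    def test_controls_equal_to_wt_predict_wt(self):
        assert compute_expni(5.0, 5.0, 5.0) == 5.0

    def test_log_scale_arithmetic(self):
        assert compute_expni(6.0, 7.0, 5.0) == 8.0

    def test_natural_scale_identity(self):
        # areas 120, 130, 100 mm^2 -> EXPni area (120*130)/100 = 156 mm^2
        out = compute_expni(np.log2(120), np.log2(130), np.log2(100))
        assert 2.0 ** out == pytest.approx(156.0, rel=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            compute_expni(np.nan, 1.0, 1.0)
        with pytest.raises(ValueError):
            compute_expni(np.inf, 1.0, 1.0)


def bh_oracle(p):
    """Independent brute-force step-up implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.01]), [0.01])

    def test_closed_form_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_ceiling(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=80))
    def test_matches_brute_force_oracle(self, pvals):
        q = bh_adjust(pvals)
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=30), st.randoms(use_true_random=False))
    def test_order_preserving_under_permutation(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = bh_adjust(pvals)
        q_perm = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)


@pytest.fixture(scope="module")
def fitted_combo():
    cfg = null_screen_config(1, seed=101, n_experiments=1, n_plants=24,
                             sigma2_experiment=0.0, outlier_rate=0.0,
                             leaf_emergence_probs=np.ones(7))
    ds = simulate_screen(cfg)
    ros = compute_rosette_areas(ds)
    fit = fit_rosette_model(ros)
    return cfg, ds, ros, fit


class TestContrast:
    def test_matches_brute_force_ols_contrast(self, fitted_combo):
        cfg, ds, ros, fit = fitted_combo
        combo = cfg.design.iloc[0]
        res = epistasis_contrast(fit, combo)
        # oracle: explicit OLS algebra + normal reference
        y = np.log2(ros["rosette_area_mm2"].to_numpy())
        gcats = sorted(ros["genotype"].unique())
        X = (ros["genotype"].to_numpy()[:, None]
             == np.array(gcats, object)).astype(float)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        s2 = r @ r / (len(y) - len(gcats))
        cov = s2 * np.linalg.inv(X.T @ X)
        c = np.array([(g == combo["combo_id"]) + (g == combo["wt"])
                      - (g == combo["control1"]) - (g == combo["control2"])
                      for g in gcats], float)
        est = c @ beta
        se = np.sqrt(c @ cov @ c)
        p = 2 * stats.norm.sf(abs(est) / se)
        assert res.estimate == pytest.approx(est, abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_null_point_and_normal_quantile(self, fitted_combo):
        cfg, _, _, fit = fitted_combo
        combo = cfg.design.iloc[0]
        res = epistasis_contrast(fit, combo)
        # estimate exactly 1.96 SEs away -> p ~ 0.05 under the normal
        z = abs(res.estimate) / res.se
        assert res.p_value == pytest.approx(2 * stats.norm.sf(z), abs=1e-12)
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_missing_genotype_named(self, fitted_combo):
        cfg, _, _, fit = fitted_combo
        combo = cfg.design.iloc[0].copy()
        combo["control1"] = "ghost"
        with pytest.raises(KeyError, match="ghost"):
            epistasis_contrast(fit, combo)

    def test_percent_ratios_identities(self, fitted_combo):
        cfg, _, _, fit = fitted_combo
        combo = cfg.design.iloc[0]
        ratios = percent_ratios(fit, combo)
        res = epistasis_contrast(fit, combo)
        # C/E = 100 * 2**estimate to machine precision
        assert ratios["c_e"] == pytest.approx(100 * 2 ** res.estimate,
                                              rel=1e-14)
        # zero LS-mean difference -> 100%; one log2 unit -> 200%
        lsm = fit.lsmeans[combo["wt"]]
        assert 100 * 2 ** (lsm - lsm) == 100.0
        assert 100 * 2 ** 1.0 == 200.0

    def test_unit_change_invariance(self, fitted_combo):
        # measuring in cm^2 instead of mm^2 cancels in every contrast
        cfg, ds, ros, fit = fitted_combo
        combo = cfg.design.iloc[0]
        rescaled = ros.assign(rosette_area_mm2=ros["rosette_area_mm2"] / 100.0)
        fit2 = fit_rosette_model(rescaled)
        r1 = epistasis_contrast(fit, combo)
        r2 = epistasis_contrast(fit2, combo)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-9)
        p1 = percent_ratios(fit, combo)
        p2 = percent_ratios(fit2, combo)
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], rel=1e-9)


def _records(rows):
    base = {"observed_lsmean": 9.0, "expni": 9.0, "se": 0.1,
            "c_w": 110.0, "p1_w": 105.0, "p2_w": 104.0}
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        d.setdefault("c_e", 100 * 2 ** d["estimate"])
        out.append(d)
    return pd.DataFrame(out)


class TestClassification:
    def test_rule_instantiation(self):
        rec = _records([
            {"combo_id": "A", "trait": "rosette", "estimate": np.log2(1.2),
             "p_value": 0.0005},
            {"combo_id": "B", "trait": "rosette", "estimate": -0.2,
             "p_value": 0.001},
            {"combo_id": "C", "trait": "rosette", "estimate": 0.3,
             "p_value": 0.20},
        ])
        out = classify_records(rec, alpha=0.05).set_index("combo_id")
        assert out.loc["A", "label"] == "synergistic"
        assert out.loc["A", "strong_20pct_above_expni"]  # C/E ~ 120%
        assert out.loc["B", "label"] == "negative"
        assert out.loc["C", "label"] == "additive"

    def test_q_at_least_p_and_label_invariants(self):
        rec = _records([
            {"combo_id": c, "trait": "rosette", "estimate": e, "p_value": p}
            for c, e, p in [("A", 0.3, 0.01), ("B", -0.1, 0.04),
                            ("C", 0.2, 0.3), ("D", 0.05, 0.9)]])
        out = classify_records(rec, alpha=0.05)
        assert (out["q"] >= out["p_value"] - 1e-15).all()
        for _, r in out.iterrows():
            if r["label"] == "synergistic":
                assert r["q"] < 0.05 and r["estimate"] > 0
            elif r["label"] == "negative":
                assert r["q"] < 0.05 and r["estimate"] < 0

    def test_bold_flag_thresholds(self):
        rec = _records([
            {"combo_id": "A", "trait": "rosette", "estimate": 0.0,
             "p_value": 1.0, "c_w": 113.4, "p1_w": 106.0, "p2_w": 105.0},
        ])
        out = classify_records(rec)
        # C/P1 = 113.4/106 ~ 107%, C/P2 ~ 108% -> bold
        assert out.loc[0, "bold_5pct_above_both_controls"]
        rec2 = _records([
            {"combo_id": "A", "trait": "rosette", "estimate": 0.0,
             "p_value": 1.0, "c_w": 106.0, "p1_w": 105.0, "p2_w": 100.0},
        ])
        assert not classify_records(rec2).loc[
            0, "bold_5pct_above_both_controls"]

    def test_classify_combination_requires_rosette(self):
        rec = _records([{"combo_id": "A", "trait": "L1", "estimate": 0.1,
                         "p_value": 0.01}])
        with pytest.raises(ValueError, match="rosette"):
            classify_combination(rec)

    def test_classify_combination_uses_combo_family(self):
        rec = _records([
            {"combo_id": "A", "trait": t, "estimate": 0.2, "p_value": p}
            for t, p in [("rosette", 0.001), ("L0", 0.02), ("L1", 0.8)]])
        out = classify_combination(rec, alpha=0.05).set_index("trait")
        assert out.loc["rosette", "label"] == "synergistic"
        assert out.loc["L1", "label"] == "additive"


def test_null_contrast_p_values_are_uniform():
    """Under the null generative model the contrast p-value is uniform
    (Kolmogorov-Smirnov at 2000 simulated contrasts)."""
    rng = np.random.default_rng(987)
    genos = ["cross", "c1", "c2", "wt"]
    eff = {"cross": 0.30, "c1": 0.15, "c2": 0.15, "wt": 0.0}  # gamma = 0
    n = 12
    ps = []
    for _ in range(2000):
        rows = []
        for g in genos:
            y = 9.0 + eff[g] + rng.normal(0, 0.18, n)
            rows += [{"plant_id": f"{g}{k}", "genotype": g, "experiment": "E1",
                      "rosette_area_mm2": 2.0 ** v} for k, v in enumerate(y)]
        fit = fit_rosette_model(pd.DataFrame(rows))
        combo = {"combo_id": "cross", "control1": "c1", "control2": "c2",
                 "wt": "wt"}
        ps.append(epistasis_contrast(fit, combo).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRunScreen:
    def test_screen_shape_and_families(self):
        cfg = null_screen_config(5, seed=55, outlier_rate=0.0)
        ds = simulate_screen(cfg)
        res = run_screen(ds, ScreenSettings(traits="rosette"))
        ros = res.records[res.records["trait"] == "rosette"]
        assert len(ros) == 5
        assert ros["q_screen"].notna().all()
        assert (res.records.groupby("combo_id")["q_combo"].count() > 0).all()

    def test_gamma_recovered_in_estimate(self):
        gamma = np.log2(1.3)
        cfg = null_screen_config(2, seed=66, outlier_rate=0.0)
        combo = cfg.design.loc[0, "combo_id"]
        cfg.interaction_coeffs[combo][:] = gamma
        ds = simulate_screen(cfg)
        res = run_screen(ds, ScreenSettings(traits="rosette"))
        rec = res.records.set_index("combo_id")
        est = rec.loc[combo, "estimate"]
        se = rec.loc[combo, "se"]
        assert abs(est - gamma) < 4 * se
        assert rec.loc[combo, "label"] == "synergistic"

    def test_combination_without_data_skipped(self):
        cfg = null_screen_config(2, seed=67, outlier_rate=0.0)
        ds = simulate_screen(cfg)
        combo = cfg.design.loc[1, "combo_id"]
        ds.measurements = ds.measurements[
            ds.measurements["genotype"] != combo]
        res = run_screen(ds, ScreenSettings(traits="rosette"))
        assert [c for c, _ in res.skipped] == [combo]
        assert set(res.records["combo_id"]) == {cfg.design.loc[0, "combo_id"]}

    def test_leaf_traits_included_with_structure_selection(self):
        cfg = null_screen_config(1, seed=68, n_experiments=1, n_plants=20,
                                 sigma2_experiment=0.0, outlier_rate=0.0,
                                 leaf_emergence_probs=np.ones(7))
        ds = simulate_screen(cfg)
        res = run_screen(ds, ScreenSettings(traits="all"))
        traits = set(res.records["trait"])
        assert traits == {"rosette"} | {f"L{i}" for i in range(7)}
        combo = cfg.design.loc[0, "combo_id"]
        assert combo in res.structure_tables
        # C/E identity holds for every record
        rec = res.records
        np.testing.assert_allclose(rec["c_e"],
                                   100 * 2 ** rec["estimate"], rtol=1e-12)

    def test_outliers_removed_before_fitting(self):
        cfg = null_screen_config(1, seed=69, outlier_rate=0.15,
                                 outlier_shrink_factor=0.02)
        ds = simulate_screen(cfg)
        res = run_screen(ds, ScreenSettings(traits="rosette"))
        assert len(res.removed_outliers) > 0
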