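"""Calibration and recovery studies for the screening pipeline.

Self-contained simulation studies that exercise the full pipeline
against known ground truth: oracle equivalence of the mixed-model path
on balanced designs, EXPni back-transform identities, type-I error of
the null screen, recovery and confidence-interval coverage of injected
interaction coefficients, residual covariance structure recovery, and
repeatability estimation. They power both the reproducibility script
and the statistical test suite; each takes an explicit seed and
problem size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .covariance import cs_matrix
from .epistasis import (
    ScreenSettings,
    bh_adjust,
    compute_expni,
    epistasis_contrast,
    run_screen,
)
from .ingest import compute_rosette_areas
from .mixed_model import (
    estimate_repeatability,
    fit_rosette_model,
    select_covariance_structure,
)
from .synthetic_data import N_LEAF_TRAITS, null_screen_config, simulate_screen


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one base seed."""
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def ols_oracle_study(n_datasets: int = 50, seed: int = 0) -> dict:
    """Mixed-model path vs brute-force OLS on balanced one-experiment data.

    For each random dataset (4 genotypes, one experiment, equal plant
    counts) compares LS-means, the interaction contrast, its SE and
    p-value against explicit least-squares linear algebra. Returns the
    largest absolute discrepancy seen for each quantity.
    """
    worst = {"lsmeans": 0.0, "estimate": 0.0, "se": 0.0, "p_value": 0.0}
    for s in _spawn(seed, n_datasets):
        rng = np.random.default_rng(s)
        cfg = null_screen_config(
            1, seed=s, n_experiments=1,
            n_plants=int(rng.integers(6, 20)),
            sigma2_experiment=0.0,
            leaf_residual_cov=cs_matrix(float(rng.uniform(0.01, 0.08)),
                                        float(rng.uniform(0.0, 0.8)),
                                        N_LEAF_TRAITS),
            outlier_rate=0.0, leaf_emergence_probs=np.ones(N_LEAF_TRAITS))
        combo = cfg.design.iloc[0]
        cfg.interaction_coeffs[combo["combo_id"]][:] = rng.normal(0, 0.2)
        ds = simulate_screen(cfg)
        ros = compute_rosette_areas(ds)
        fit = fit_rosette_model(ros)
        res = epistasis_contrast(fit, combo)

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
        est, se = c @ beta, float(np.sqrt(c @ cov @ c))
        p = 2.0 * float(stats.norm.sf(abs(est) / se))
        worst["lsmeans"] = max(worst["lsmeans"], float(
            np.max(np.abs(fit.lsmeans[gcats].to_numpy() - beta))))
        worst["estimate"] = max(worst["estimate"], abs(res.estimate - est))
        worst["se"] = max(worst["se"], abs(res.se - se))
        worst["p_value"] = max(worst["p_value"], abs(res.p_value - p))
    return worst


def expni_identity_study(n: int = 1000, seed: int = 0) -> dict:
    """Machine-precision identities of EXPni and the C/E back-transform."""
    rng = np.random.default_rng(seed)
    a1, a2, aw = rng.uniform(10.0, 1000.0, size=(3, n))
    expni_log = np.array([compute_expni(np.log2(x), np.log2(y), np.log2(w))
                          for x, y, w in zip(a1, a2, aw)])
    err_natural = np.abs(2.0 ** expni_log - (a1 * a2) / aw) / ((a1 * a2) / aw)
    est = rng.normal(0.0, 0.5, size=n)
    ce = 100.0 * 2.0 ** est
    err_ce = np.abs(np.log2(ce / 100.0) - est)
    return {"natural_scale_max_rel_err": float(err_natural.max()),
            "c_over_e_max_log2_err": float(err_ce.max())}


def type_i_error_study(n_screens: int = 20, n_combinations: int = 60,
                       seed: int = 0) -> dict:
    """Null screens (gamma = 0) at the screen's scale (3 exp x 16 plants).

    Returns the pooled fraction of raw rosette interaction p-values
    below 0.05 and the mean Benjamini-Hochberg-significant fraction
    per screen.
    """
    raw, bh = [], []
    for s in _spawn(seed, n_screens):
        cfg = null_screen_config(n_combinations, seed=s)
        ds = simulate_screen(cfg)
        res = run_screen(ds, ScreenSettings(traits="rosette"))
        ros = res.records[res.records["trait"] == "rosette"]
        raw.append((ros["p_value"] < 0.05).to_numpy())
        bh.append(float((ros["q"] < 0.05).mean()))
    raw = np.concatenate(raw)
    return {"raw_fraction": float(raw.mean()),
            "bh_fraction": float(np.mean(bh)),
            "n_tests": int(raw.size)}


def gamma_recovery_study(n_screens: int = 50, gamma: float = np.log2(1.2),
                         n_injected: int = 10, n_combinations: int = 60,
                         seed: int = 0) -> dict:
    """Recovery of an injected interaction coefficient.

    Each replicate screen carries ``gamma`` in ``n_injected`` of its
    combinations; only those are analyzed (the estimate of one
    combination does not depend on the others). Returns the mean
    estimate with its Monte-Carlo standard error and the empirical
    coverage of the 95% Wald interval.
    """
    ests, covered, screen_means = [], [], []
    for s in _spawn(seed, n_screens):
        cfg = null_screen_config(n_combinations, seed=s)
        injected = cfg.design["combo_id"].iloc[:n_injected].tolist()
        for combo in injected:
            cfg.interaction_coeffs[combo][:] = gamma
        ds = simulate_screen(cfg)
        ds.design = ds.design[ds.design["combo_id"].isin(injected)]
        res = run_screen(ds, ScreenSettings(traits="rosette"))
        screen_means.append(float(res.records["estimate"].mean()))
        for _, r in res.records.iterrows():
            ests.append(r["estimate"])
            covered.append(abs(r["estimate"] - gamma) <= 1.959964 * r["se"])
    ests = np.asarray(ests)
    # contrasts within one screen share wild-type and control data, so the
    # Monte-Carlo SE of the overall mean comes from independent screen means
    screen_means = np.asarray(screen_means)
    return {
        "true_gamma": float(gamma),
        "mean_estimate": float(ests.mean()),
        "mc_se": float(screen_means.std(ddof=1) / np.sqrt(len(screen_means))),
        "coverage": float(np.mean(covered)),
        "n_contrasts": int(len(ests)),
    }


def heterogeneous_un_cov(seed: int = 0, m: int = N_LEAF_TRAITS) -> np.ndarray:
    """A strongly heterogeneous unstructured covariance (fixed given seed)."""
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(m, m)) * 0.08
    return B @ B.T + np.diag(rng.uniform(0.01, 0.15, size=m))


def structure_recovery_study(truth: str = "CS", n_replicates: int = 200,
                             n_plants: int = 30, seed: int = 0) -> dict:
    """How often AIC selection returns each structure under a known truth."""
    if truth == "CS":
        sigma = cs_matrix(0.05, 0.5, N_LEAF_TRAITS)
    elif truth == "UN":
        sigma = heterogeneous_un_cov(seed=12345)
    else:
        raise ValueError("truth must be 'CS' or 'UN'")
    counts: dict[str, int] = {}
    for s in _spawn(seed, n_replicates):
        cfg = null_screen_config(
            1, seed=s, n_experiments=1, n_plants=n_plants,
            sigma2_experiment=0.0, leaf_residual_cov=sigma,
            outlier_rate=0.0, leaf_emergence_probs=np.ones(N_LEAF_TRAITS))
        ds = simulate_screen(cfg)
        tag, _ = select_covariance_structure(ds.measurements)
        counts[tag] = counts.get(tag, 0) + 1
    frac = {t: counts.get(t, 0) / n_replicates
            for t in ("CS", "AR1", "TOEP", "UN")}
    return {"truth": truth, "selected_fractions": frac,
            "selected_truth_fraction": frac[truth]}


def simulate_rosette_components(n_genotypes: int, n_experiments: int,
                                n_plants: int, s2_g: float, s2_e: float,
                                s2_ge: float, s2_res: float,
                                seed: int = 0) -> pd.DataFrame:
    """Rosette table drawn from the variance-components model itself.

    ``log2 RA = mu + g + b_e + (ge) + eps`` with every term Gaussian —
    the exact generative model of the repeatability estimator, with
    genotype effects drawn from a population of variance ``s2_g``.
    """
    rng = np.random.default_rng(seed)
    mu = np.log2(500.0)
    g_eff = rng.normal(0, np.sqrt(s2_g), n_genotypes)
    b_e = rng.normal(0, np.sqrt(s2_e), n_experiments)
    ge = rng.normal(0, np.sqrt(s2_ge), (n_genotypes, n_experiments))
    rows = []
    for i in range(n_genotypes):
        for j in range(n_experiments):
            y = (mu + g_eff[i] + b_e[j] + ge[i, j]
                 + rng.normal(0, np.sqrt(s2_res), n_plants))
            for k, v in enumerate(y):
                rows.append({"plant_id": f"g{i}|e{j}|p{k}",
                             "genotype": f"g{i:03d}", "experiment": f"E{j}",
                             "rosette_area_mm2": 2.0 ** v})
    return pd.DataFrame(rows)


def repeatability_study(n_replicates: int = 5, n_genotypes: int = 100,
                        n_experiments: int = 3, n_plants: int = 6,
                        s2_g: float = 0.04, s2_res: float = 0.04,
                        seed: int = 0) -> dict:
    """Mean repeatability estimate when s2_G = s2_residual (truth 0.5)."""
    truth = s2_g / (s2_g + s2_res)
    h2s = []
    for s in _spawn(seed, n_replicates):
        ros = simulate_rosette_components(
            n_genotypes, n_experiments, n_plants,
            s2_g=s2_g, s2_e=0.01, s2_ge=0.0, s2_res=s2_res, seed=s)
        h2s.append(estimate_repeatability(ros).h2)
    return {"true_h2": float(truth), "mean_h2": float(np.mean(h2s)),
            "h2_estimates": [float(h) for h in h2s]}


def screen_summary_study(n_combinations: int = 61, n_synergistic: int = 10,
                         n_negative: int = 3, gamma: float = np.log2(1.25),
                         seed: int = 0) -> dict:
    """A full demonstration screen with known synergistic/negative truth."""
    cfg = null_screen_config(n_combinations, seed=seed)
    combos = cfg.design["combo_id"].tolist()
    for c in combos[:n_synergistic]:
        cfg.interaction_coeffs[c][:] = gamma
    for c in combos[n_synergistic:n_synergistic + n_negative]:
        cfg.interaction_coeffs[c][:] = -gamma
    ds = simulate_screen(cfg)
    res = run_screen(ds, ScreenSettings(traits="rosette"))
    ros = res.records[res.records["trait"] == "rosette"].set_index("combo_id")
    labels = ros["label"]
    return {
        "n_analyzed": int(len(ros)),
        "n_synergistic_detected": int((labels == "synergistic").sum()),
        "n_negative_detected": int((labels == "negative").sum()),
        "true_synergistic_recalled": int(
            (labels.loc[combos[:n_synergistic]] == "synergistic").sum()),
        "records": res.records,
        "design": ds.design,
    }
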