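"""EXPni computation, interaction testing, FDR control and classification.

A pairwise cross is compared to its expected-if-non-interacting value
(EXPni), the additive prediction on the log2 (i.e. multiplicative on
the natural) scale:

    log2(A_EXPni) = log2(A_control1) + log2(A_control2) - log2(A_wt)

The null hypothesis of no interaction is the LS-mean contrast

    log2(A_cross) - log2(A_control1) - log2(A_control2) + log2(A_wt) = 0

tested with a two-sided Wald test; Benjamini-Hochberg correction is
applied across combinations (screen family) and across traits within a
combination (combo family). A combination is *synergistic* when the
null is rejected at FDR alpha with a positive estimate, *negative*
with a negative estimate, and *additive* otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import ScreenDataset, compute_rosette_areas, filter_outliers
from .mixed_model import (
    MAX_LEAF,
    FitResult,
    fit_leaf_model,
    fit_rosette_model,
    select_covariance_structure,
)

log = logging.getLogger(__name__)

LABELS = ("synergistic", "additive", "negative")


@dataclass
class ContrastResult:
    """A single epistasis contrast on the log2 LS-mean scale."""

    estimate: float
    se: float
    p_value: float
    trait: str


@dataclass
class ScreenSettings:
    """Tunable settings for a full screen analysis.

    ``traits="all"`` runs the rosette model plus the per-leaf
    repeated-measures analysis (L0..L6); ``"rosette"`` runs the rosette
    family only. ``structure`` is a covariance tag or ``"auto"`` for
    AIC selection. ``fdr_scope`` chooses which Benjamini-Hochberg
    family provides the significance labels for leaf traits; the
    rosette label always comes from the screen-wide family when it is
    computed.
    """

    alpha: float = 0.05
    traits: str = "all"
    gxe: str = "auto"
    structure: str = "auto"
    outlier_k: float = 3.5
    reml: bool = True
    fdr_scope: str = "both"  # {"screen", "combo", "both"}


@dataclass
class ScreenResult:
    """Output of :func:`run_screen`: per-(combination, trait) records."""

    records: pd.DataFrame
    removed_outliers: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped: list = field(default_factory=list)
    structure_tables: dict = field(default_factory=dict)


def compute_expni(lsm_c1: float, lsm_c2: float, lsm_wt: float) -> float:
    """Expected-if-non-interacting LS-mean on the log2 scale.

    Returns ``lsm_c1 + lsm_c2 - lsm_wt``; on the natural scale this is
    (A1 * A2) / A_wt.
    """
    vals = np.array([lsm_c1, lsm_c2, lsm_wt], float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"EXPni inputs must be finite, got {vals}")
    return float(lsm_c1 + lsm_c2 - lsm_wt)


def _contrast_vector(fit: FitResult, combo, trait) -> np.ndarray:
    c = np.zeros(len(fit.lsmeans))
    for g, w in ((combo["combo_id"], 1.0), (combo["control1"], -1.0),
                 (combo["control2"], -1.0), (combo["wt"], 1.0)):
        _, pos = fit.lsmean(g, trait)
        c[pos] = w
    return c


def epistasis_contrast(fit: FitResult, combo, trait="rosette") -> ContrastResult:
    """Wald test of the interaction contrast (+1, -1, -1, +1).

    ``combo`` is a design-table row (mapping with combo_id, control1,
    control2, wt); ``trait`` is ``"rosette"`` or a leaf index. A
    missing genotype raises KeyError naming it.
    """
    c = _contrast_vector(fit, combo, trait)
    est = float(c @ fit.lsmeans.to_numpy())
    var = float(c @ fit.fixed_cov @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if est == 0.0 else 0.0  # degenerate noise-free data
    else:
        p = 2.0 * float(stats.norm.sf(abs(est) / se))
    return ContrastResult(estimate=est, se=se, p_value=p, trait=str(trait))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_ratios(fit: FitResult, combo, trait="rosette") -> dict:
    """Back-transformed percentage ratios for one combination and trait.

    Returns C/W, P1/W, P2/W (cross and controls vs wild type) and C/E
    (cross vs EXPni), each as ``100 * 2**(LS-mean difference)``. C/E is
    exactly ``100 * 2**estimate`` of the interaction contrast.
    """
    lsm = {g: fit.lsmean(g, trait)[0]
           for g in (combo["combo_id"], combo["control1"],
                     combo["control2"], combo["wt"])}
    wt = lsm[combo["wt"]]
    expni = compute_expni(lsm[combo["control1"]], lsm[combo["control2"]], wt)
    return {
        "c_w": 100.0 * 2.0 ** (lsm[combo["combo_id"]] - wt),
        "p1_w": 100.0 * 2.0 ** (lsm[combo["control1"]] - wt),
        "p2_w": 100.0 * 2.0 ** (lsm[combo["control2"]] - wt),
        "c_e": 100.0 * 2.0 ** (lsm[combo["combo_id"]] - expni),
    }


def classify_records(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign q-values, class labels and threshold flags to raw records.

    Adds ``q_screen`` (BH across combinations, rosette family),
    ``q_combo`` (BH across traits within each combination), ``q`` (the
    label-driving value: screen family for rosette rows, combo family
    for leaf rows), ``label`` and the three reporting flags. The C/E
    identity ``c_e == 100 * 2**estimate`` is relied upon throughout.
    """
    rec = records.copy()
    rec["q_screen"] = np.nan
    ros = rec["trait"] == "rosette"
    if ros.any():
        rec.loc[ros, "q_screen"] = bh_adjust(rec.loc[ros, "p_value"].to_numpy())
    rec["q_combo"] = np.nan
    for _, idx in rec.groupby("combo_id").indices.items():
        rec.iloc[idx, rec.columns.get_loc("q_combo")] = bh_adjust(
            rec.iloc[idx]["p_value"].to_numpy()
        )
    rec["q"] = np.where(ros, rec["q_screen"], rec["q_combo"])
    sig = rec["q"] < alpha
    rec["label"] = np.select(
        [sig & (rec["estimate"] > 0), sig & (rec["estimate"] < 0)],
        ["synergistic", "negative"], default="additive",
    )
    rec["exceeds_both_controls_and_wt"] = (
        (rec["c_w"] > rec["p1_w"]) & (rec["c_w"] > rec["p2_w"])
        & (rec["c_w"] > 100.0)
    )
    rec["bold_5pct_above_both_controls"] = (
        (100.0 * rec["c_w"] / rec["p1_w"] >= 105.0)
        & (100.0 * rec["c_w"] / rec["p2_w"] >= 105.0)
    )
    rec["strong_20pct_above_expni"] = rec["c_e"] >= 120.0
    return rec


def classify_combination(records: pd.DataFrame, alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Classify the traits of a single combination (combo FDR family)."""
    combos = records["combo_id"].unique()
    if len(combos) != 1:
        raise ValueError("classify_combination expects records of one combination")
    if not (records["trait"] == "rosette").any():
        raise ValueError(f"combination {combos[0]!r} lacks a rosette record")
    out = classify_records(records, alpha=alpha)
    # with a single combination the screen family is the rosette test alone;
    # label everything from the within-combination family
    out["q"] = out["q_combo"]
    sig = out["q"] < alpha
    out["label"] = np.select(
        [sig & (out["estimate"] > 0), sig & (out["estimate"] < 0)],
        ["synergistic", "negative"], default="additive",
    )
    return out


def _combo_records(fit: FitResult, combo, trait) -> dict:
    contrast = epistasis_contrast(fit, combo, trait)
    ratios = percent_ratios(fit, combo, trait)
    lsm_c = fit.lsmean(combo["combo_id"], trait)[0]
    expni = compute_expni(fit.lsmean(combo["control1"], trait)[0],
                          fit.lsmean(combo["control2"], trait)[0],
                          fit.lsmean(combo["wt"], trait)[0])
    return {
        "combo_id": combo["combo_id"],
        "trait": str(trait),
        "observed_lsmean": lsm_c,
        "expni": expni,
        "estimate": contrast.estimate,
        "se": contrast.se,
        "p_value": contrast.p_value,
        **ratios,
    }


def run_screen(dataset: ScreenDataset, settings: ScreenSettings | None = None
               ) -> ScreenResult:
    """Run the full epistasis screen on a validated dataset.

    Per combination: rosette areas are computed and outlier-filtered,
    the rosette mixed model is fit (genotype x experiment included by
    likelihood-ratio test), the interaction contrast is tested, and —
    with ``traits="all"`` — the leaf repeated-measures model is fit
    with AIC-selected residual covariance and per-leaf contrasts for
    L0..L6. BH correction is applied across combinations (rosette
    family) and within each combination across its traits.
    """
    settings = settings or ScreenSettings()
    rosettes = compute_rosette_areas(dataset)
    kept, removed = filter_outliers(rosettes, k=settings.outlier_k)
    kept_plants = set(kept["plant_id"])

    rows = []
    skipped = []
    structure_tables: dict = {}
    for _, combo in dataset.design.iterrows():
        genos = [combo["combo_id"], combo["control1"], combo["control2"],
                 combo["wt"]]
        sub = kept[kept["genotype"].isin(genos)]
        missing = [g for g in genos if g not in set(sub["genotype"])]
        if missing:
            skipped.append((combo["combo_id"],
                            f"no data for genotype(s) {missing}"))
            log.warning("skipping %s: no data for %s", combo["combo_id"], missing)
            continue
        fit_ros = fit_rosette_model(sub, genotypes=genos, gxe=settings.gxe,
                                    reml=settings.reml)
        rec = _combo_records(fit_ros, combo, "rosette")
        rec["structure"] = ""
        rec["gxe_included"] = fit_ros.gxe_included
        rows.append(rec)

        if settings.traits == "all":
            leaves = dataset.measurements[
                dataset.measurements["genotype"].isin(genos)
                & dataset.measurements["plant_id"].isin(kept_plants)
                & (dataset.measurements["leaf"] <= MAX_LEAF)
            ]
            if settings.structure == "auto":
                tag, table = select_covariance_structure(
                    leaves, gxe=settings.gxe, reml=settings.reml)
                structure_tables[combo["combo_id"]] = table
            else:
                tag = settings.structure
            fit_leaf = fit_leaf_model(leaves, structure=tag, gxe=settings.gxe,
                                      reml=settings.reml)
            for leaf in sorted({l for (_, l) in fit_leaf.lsmeans.index}):
                try:
                    rec = _combo_records(fit_leaf, combo, int(leaf))
                except KeyError:
                    continue  # a genotype lacks this leaf entirely
                rec["trait"] = f"L{int(leaf)}"
                rec["structure"] = tag
                rec["gxe_included"] = fit_leaf.gxe_included
                rows.append(rec)

    if not rows:
        raise RuntimeError("no combination could be analyzed")
    records = classify_records(pd.DataFrame(rows), alpha=settings.alpha)
    return ScreenResult(records=records, removed_outliers=removed,
                        skipped=skipped, structure_tables=structure_tables)
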