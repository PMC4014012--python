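"""Linear mixed models for rosette- and leaf-level log2 areas.

Two model families are fit:

* **Rosette model** — ``log2(rosette area) ~ genotype`` with a random
  experiment intercept and, when a likelihood-ratio test supports it,
  a genotype x experiment variance component. Delegated to
  :class:`statsmodels.regression.mixed_linear_model.MixedLM`. With a
  single experiment the random terms are dropped and the fit reduces
  to ordinary least squares.

* **Leaf repeated-measures model** — ``log2(leaf area) ~ genotype *
  leaf`` for traits L0..L6, with a structured residual covariance
  across the leaves of one plant (CS, AR(1), Toeplitz or unstructured)
  and the same random experiment terms. No installed package fits
  linear mixed models with structured within-subject residual
  covariance, so the (RE)ML machinery for this family is implemented
  here directly: the marginal covariance is assembled blockwise (per
  plant, or per experiment when random intercepts couple plants),
  fixed effects are profiled out by generalised least squares, and the
  covariance parameters are optimised numerically. Structures are
  compared by AIC computed from the REML likelihood, which is valid
  because all candidates share one fixed-effects mean model.

All genotype summaries are least-squares means (LS-means) on the log2
scale, with their covariance taken from the fixed-effects information
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .covariance import STRUCTURE_ORDER, get_structure

__all__ = [
    "FitResult",
    "LrtResult",
    "RepeatabilityResult",
    "fit_rosette_model",
    "lr_test_gxe",
    "fit_leaf_model",
    "select_covariance_structure",
    "estimate_repeatability",
]

MAX_LEAF = 6  # leaf traits L0..L6 enter the repeated-measures analysis

_LOG2PI = np.log(2.0 * np.pi)


class _quiet_boundary(warnings.catch_warnings):
    """Suppress statsmodels chatter expected at variance boundaries."""

    def __enter__(self):
        out = super().__enter__()
        warnings.simplefilter("ignore", ConvergenceWarning)
        for msg in (".*boundary.*", ".*covariance is singular.*",
                    ".*covariance matrix is singular.*"):
            warnings.filterwarnings("ignore", message=msg)
        return out


@dataclass
class FitResult:
    """Estimated LS-means with uncertainty and variance components.

    ``lsmeans`` is indexed by genotype (rosette fits) or by
    (genotype, leaf) (leaf fits); ``fixed_cov`` is the covariance of
    those estimates in the same order. ``variance_components`` holds
    the experiment / genotype-x-experiment variances plus either the
    scalar residual variance or the full residual covariance across
    leaf traits.
    """

    lsmeans: pd.Series
    fixed_cov: np.ndarray
    variance_components: dict
    loglik: float
    reml: bool
    aic: float
    structure: str | None
    gxe_included: bool
    n_used: int
    converged: bool = True

    def lsmean(self, genotype, trait="rosette") -> tuple[float, int]:
        """LS-mean and its position for a genotype (and leaf trait)."""
        key = genotype if trait == "rosette" else (genotype, int(trait))
        if key not in self.lsmeans.index:
            raise KeyError(f"no LS-mean for genotype {genotype!r}, trait {trait!r}")
        pos = self.lsmeans.index.get_loc(key)
        return float(self.lsmeans.iloc[pos]), pos


@dataclass
class LrtResult:
    """Likelihood-ratio test of a variance component (boundary-clamped)."""

    statistic: float
    df: int
    p_value: float
    include_term: bool
    testable: bool = True


@dataclass
class RepeatabilityResult:
    """Broad-sense heritability at the individual-plant level."""

    h2: float
    component_estimates: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rosette-level model (statsmodels MixedLM / OLS)

def _rosette_frame(rosettes: pd.DataFrame, genotypes=None) -> pd.DataFrame:
    df = rosettes.copy()
    if genotypes is not None:
        present = set(df["genotype"].unique())
        missing = [g for g in genotypes if g not in present]
        if missing:
            raise ValueError(f"genotype(s) absent from data: {', '.join(map(str, missing))}")
        df = df[df["genotype"].isin(set(genotypes))].copy()
    if df["genotype"].nunique() < 1:
        raise ValueError("no genotypes to fit")
    df["y"] = np.log2(df["rosette_area_mm2"].to_numpy(float))
    df["gxe_cell"] = df["genotype"].astype(str) + ":" + df["experiment"].astype(str)
    return df


def _genotype_design(df: pd.DataFrame) -> tuple[np.ndarray, list]:
    gcats = sorted(df["genotype"].unique())
    X = (df["genotype"].to_numpy()[:, None] == np.array(gcats, object)).astype(float)
    return X, gcats


def fit_rosette_model(rosettes: pd.DataFrame, genotypes=None, gxe="auto",
                      reml: bool = True) -> FitResult:
    """Fit the rosette mixed model and return genotype LS-means.

    Parameters
    ----------
    rosettes : DataFrame
        Columns ``plant_id, genotype, experiment, rosette_area_mm2``.
    genotypes : iterable, optional
        Restrict the fit to these genotypes; an absent genotype raises
        a ValueError naming it.
    gxe : {"auto", "on", "off"} or bool
        Whether to include the genotype x experiment variance
        component; ``"auto"`` decides by likelihood-ratio test at
        p < 0.05.
    reml : bool
        Restricted (default) or full maximum likelihood.
    """
    df = _rosette_frame(rosettes, genotypes)
    X, gcats = _genotype_design(df)
    n_exp = df["experiment"].nunique()

    if n_exp < 2:
        # single-experiment fallback: no experiment factor at all
        res = sm.OLS(df["y"].to_numpy(), X).fit()
        return FitResult(
            lsmeans=pd.Series(res.params, index=pd.Index(gcats, name="genotype")),
            fixed_cov=np.asarray(res.cov_params()),
            variance_components={"experiment": 0.0, "gxe": 0.0,
                                 "residual": float(res.scale)},
            loglik=float(res.llf),
            reml=False,
            aic=-2.0 * float(res.llf) + 2.0,
            structure=None,
            gxe_included=False,
            n_used=len(df),
            converged=True,
        )

    if gxe == "auto":
        include_gxe = lr_test_gxe(df).include_term
    else:
        include_gxe = gxe in (True, "on")

    res = _fit_mixedlm(df, include_gxe=include_gxe, reml=reml)
    k = len(gcats)
    vc = {
        "experiment": float(res.cov_re.iloc[0, 0]),
        "gxe": float(res.vcomp[0]) if include_gxe else 0.0,
        "residual": float(res.scale),
    }
    n_cov = 2 + int(include_gxe)  # experiment, residual (+ gxe)
    lsm = pd.Series(res.fe_params.to_numpy(),
                    index=pd.Index(gcats, name="genotype"))
    return FitResult(
        lsmeans=lsm,
        fixed_cov=np.asarray(res.cov_params())[:k, :k],
        variance_components=vc,
        loglik=float(res.llf),
        reml=reml,
        aic=-2.0 * float(res.llf) + 2.0 * n_cov,
        structure=None,
        gxe_included=include_gxe,
        n_used=len(df),
        converged=bool(res.converged),
    )


def _fit_mixedlm(df: pd.DataFrame, include_gxe: bool, reml: bool):
    vc = {"gxe": "0 + C(gxe_cell)"} if include_gxe else None
    model = sm.MixedLM.from_formula(
        "y ~ 0 + C(genotype)", groups="experiment", re_formula="1",
        vc_formula=vc, data=df,
    )
    with _quiet_boundary():
        try:
            res = model.fit(reml=reml, method="lbfgs", maxiter=200)
        except np.linalg.LinAlgError:
            res = None
        if res is None or not res.converged or not np.isfinite(res.llf):
            # gradient methods stall (or blow up) when a variance sits on
            # the boundary; Powell is slower but boundary-safe
            res = model.fit(reml=reml, method="powell", maxiter=1000)
    if not res.converged or not np.isfinite(res.llf):
        raise RuntimeError(
            "rosette mixed model did not converge "
            f"(n={len(df)}, gxe={include_gxe}); inspect the data"
        )
    return res


def lr_test_gxe(rosettes: pd.DataFrame, genotypes=None) -> LrtResult:
    """Likelihood-ratio test for the genotype x experiment component.

    Compares maximum-likelihood fits with and without the component;
    the statistic is clamped at zero and referred to chi-square with
    1 df, which is conservative at the variance boundary. With a
    single experiment the term is not testable and is excluded.
    """
    df = _rosette_frame(rosettes, genotypes)
    if df["experiment"].nunique() < 2:
        return LrtResult(statistic=0.0, df=1, p_value=1.0,
                         include_term=False, testable=False)
    ll_full = float(_fit_mixedlm(df, include_gxe=True, reml=False).llf)
    ll_red = float(_fit_mixedlm(df, include_gxe=False, reml=False).llf)
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    return LrtResult(statistic=stat, df=1, p_value=p,
                     include_term=p < 0.05, testable=True)


def estimate_repeatability(rosettes: pd.DataFrame) -> RepeatabilityResult:
    """Individual-level repeatability (broad-sense heritability).

    Refits the rosette model with genotype, experiment and genotype x
    experiment all as random terms and returns
    ``h2 = s2_G / (s2_G + s2_GE + s2_resid)``. The pure experiment
    (block) variance is excluded from the denominator; pass the
    components on if the alternative convention is wanted.
    """
    df = _rosette_frame(rosettes)
    if df["genotype"].nunique() < 2 or df["experiment"].nunique() < 2:
        raise ValueError("repeatability needs >= 2 genotypes and >= 2 experiments")
    df["_all"] = 1
    model = sm.MixedLM.from_formula(
        "y ~ 1", groups="_all", re_formula="0",
        vc_formula={
            "genotype": "0 + C(genotype)",
            "experiment": "0 + C(experiment)",
            "gxe": "0 + C(gxe_cell)",
        },
        data=df,
    )
    with _quiet_boundary():
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=300)
        except np.linalg.LinAlgError:
            res = None
        if res is None or not res.converged or not np.isfinite(res.llf):
            res = model.fit(reml=True, method="powell", maxiter=1000)
    if not res.converged or not np.isfinite(res.llf):
        raise RuntimeError("repeatability model did not converge")
    names = model.exog_vc.names
    comp = {name: float(v) for name, v in zip(names, res.vcomp)}
    comp["residual"] = float(res.scale)
    denom = comp["genotype"] + comp["gxe"] + comp["residual"]
    h2 = comp["genotype"] / denom if denom > 0 else 0.0
    return RepeatabilityResult(h2=float(np.clip(h2, 0.0, 1.0)),
                               component_estimates=comp)


# ---------------------------------------------------------------------------
# leaf-level repeated-measures model (structured residual covariance)

class _LeafData:
    """Pre-indexed leaf data: plants, observation patterns, design."""

    def __init__(self, measurements: pd.DataFrame, max_leaf: int = MAX_LEAF):
        df = measurements[measurements["leaf"] <= max_leaf].copy()
        if df.empty:
            raise ValueError("no leaf measurements in L0..L6")
        df["y"] = np.log2(df["area_mm2"].to_numpy(float))
        self.traits = np.array(sorted(df["leaf"].unique()))
        self.m = len(self.traits)
        tpos = {t: j for j, t in enumerate(self.traits)}
        df["tpos"] = df["leaf"].map(tpos)

        cells = sorted(
            df.groupby(["genotype", "leaf"]).groups.keys(),
            key=lambda gl: (str(gl[0]), gl[1]),
        )
        self.cells = cells
        self.cell_col = {gl: j for j, gl in enumerate(cells)}
        self.p = len(cells)
        self.n = len(df)
        self.experiments = sorted(df["experiment"].unique())

        # per plant: trait positions (sorted), y values, genotype, experiment
        self.plants = []
        for (pid, g, e), sub in df.sort_values("tpos").groupby(
                ["plant_id", "genotype", "experiment"], sort=False):
            self.plants.append((
                sub["tpos"].to_numpy(), sub["y"].to_numpy(float), g, e,
            ))
        self.df = df

    def empirical_residual_cov(self) -> np.ndarray:
        """Pairwise-complete covariance of residuals from cell means."""
        df = self.df
        resid = df["y"] - df.groupby(["genotype", "leaf"])["y"].transform("mean")
        wide = pd.DataFrame({
            "plant_id": df["plant_id"], "tpos": df["tpos"], "r": resid
        }).pivot(index="plant_id", columns="tpos", values="r")
        S = wide.cov(min_periods=2).to_numpy()
        bad = ~np.isfinite(S)
        if bad.any():
            S[bad] = 0.0
        d = np.diag(S).copy()
        d[d <= 0] = np.nanmean(d[d > 0]) if (d > 0).any() else 1e-2
        np.fill_diagonal(S, d)
        return S


class _StructuredLMM:
    """(RE)ML objective for the structured-residual leaf mixed model."""

    def __init__(self, data: _LeafData, structure_tag: str,
                 include_experiment: bool, include_gxe: bool, reml: bool):
        self.data = data
        self.struct = get_structure(structure_tag, data.m)
        self.include_experiment = include_experiment and len(data.experiments) > 1
        self.include_gxe = include_gxe and self.include_experiment
        self.reml = reml
        self._index_blocks()

    # -- indexing ------------------------------------------------------------

    def _index_blocks(self):
        """Group plants by (experiment, pattern, genotype) for vectorised
        blockwise likelihood evaluation.

        Plants are conditionally independent given the random experiment
        intercepts, so the residual part of the marginal covariance is
        block-diagonal per plant; the random-intercept part is low rank
        within an experiment and is handled by a Woodbury identity.
        """
        d = self.data
        groups: dict = {}
        for tposv, yv, g, e in d.plants:
            groups.setdefault((e, tuple(tposv), g), []).append(yv)
        # per experiment: list of (tpos, fixed cols, stacked Y, genotype idx)
        self.exp_groups: dict = {e: [] for e in d.experiments}
        self.gidx = {g: i for i, g in enumerate(
            sorted({g for (_, _, g) in groups}))}
        for (e, tpos, g), ys in groups.items():
            tposv = np.array(tpos)
            cols = np.array([d.cell_col[(g, d.traits[t])] for t in tposv])
            self.exp_groups[e].append((tposv, cols, np.vstack(ys),
                                       self.gidx[g]))

    def n_cov_params(self) -> int:
        return (self.struct.n_params() + int(self.include_experiment)
                + int(self.include_gxe))

    # -- likelihood ----------------------------------------------------------

    def _split(self, x):
        k = self.struct.n_params()
        sigma = self.struct.build(x[:k])
        i = k
        # floor keeps 1/s2 finite if the optimizer walks to the boundary
        s2e = max(float(np.exp(x[i])), 1e-250) if self.include_experiment else 0.0
        i += int(self.include_experiment)
        s2ge = max(float(np.exp(x[i])), 1e-250) if self.include_gxe else 0.0
        return sigma, s2e, s2ge

    def _gls_pieces(self, sigma, s2e, s2ge):
        """Accumulate X'V-1X, X'V-1y, y'V-1y and log|V| blockwise.

        The marginal covariance within an experiment is
        ``V_e = R_e + U_e G U_e'`` with ``R_e`` block-diagonal per plant
        (the structured residual) and ``U_e`` the low-rank design of the
        experiment / genotype-x-experiment intercepts; the inverse and
        determinant use the Woodbury / matrix-determinant identities, so
        every evaluation only factorises small per-pattern matrices.
        """
        d = self.data
        XtViX = np.zeros((d.p, d.p))
        XtViy = np.zeros(d.p)
        yty = 0.0
        logdet = 0.0
        n_geno = len(self.gidx)
        q = 1 + (n_geno if self.include_gxe else 0)
        chol_cache: dict = {}

        def _W(tposv):
            key = tuple(tposv)
            if key not in chol_cache:
                sub = sigma[np.ix_(tposv, tposv)]
                L = np.linalg.cholesky(sub)
                W = cho_solve((L, True), np.eye(len(tposv)))
                chol_cache[key] = (W, 2.0 * np.sum(np.log(np.diag(L))))
            return chol_cache[key]

        for e in d.experiments:
            if self.include_experiment:
                XtRiU = np.zeros((d.p, q))
                UtRiU = np.zeros((q, q))
                UtRiy = np.zeros(q)
            for tposv, cols, Y, gi in self.exp_groups[e]:
                W, ld = _W(tposv)
                n_g = Y.shape[0]
                ysum = Y.sum(axis=0)
                XtViX[np.ix_(cols, cols)] += n_g * W
                XtViy[cols] += W @ ysum
                yty += float(np.einsum("ij,pi,pj->", W, Y, Y))
                logdet += n_g * ld
                if self.include_experiment:
                    w1 = W.sum(axis=1)       # W @ ones
                    s = float(w1.sum())      # ones' W ones
                    wy = float(w1 @ ysum)
                    ucols = [0] + ([1 + gi] if self.include_gxe else [])
                    for a in ucols:
                        XtRiU[cols, a] += n_g * w1
                        UtRiy[a] += wy
                        for b in ucols:
                            UtRiU[a, b] += n_g * s
            if self.include_experiment:
                gdiag = np.full(q, s2ge)
                gdiag[0] = s2e
                M = UtRiU + np.diag(1.0 / gdiag)
                cfM = cho_factor(M)
                K = cho_solve(cfM, XtRiU.T)       # q x p
                XtViX -= XtRiU @ K
                ky = cho_solve(cfM, UtRiy)
                XtViy -= XtRiU @ ky
                yty -= float(UtRiy @ ky)
                logdet += (2.0 * np.sum(np.log(np.diag(cfM[0])))
                           + float(np.sum(np.log(gdiag))))
        return XtViX, XtViy, yty, logdet

    def loglik(self, x) -> float:
        sigma, s2e, s2ge = self._split(x)
        XtViX, XtViy, yty, logdet = self._gls_pieces(sigma, s2e, s2ge)
        cf = cho_factor(XtViX)
        beta = cho_solve(cf, XtViy)
        quad = yty - XtViy @ beta
        n, p = self.data.n, self.data.p
        if self.reml:
            ld_info = 2.0 * np.sum(np.log(np.diag(cf[0])))
            return -0.5 * ((n - p) * _LOG2PI + logdet + ld_info + quad)
        return -0.5 * (n * _LOG2PI + logdet + quad)

    def neg_loglik(self, x) -> float:
        try:
            return -self.loglik(x)
        except np.linalg.LinAlgError:
            return 1e10  # infeasible (non-PD) parameter point

    # -- fitting -------------------------------------------------------------

    def initial_params(self) -> np.ndarray:
        S = self.data.empirical_residual_cov()
        x0 = [self.struct.init(S)]
        vbar = float(np.mean(np.diag(S)))
        if self.include_experiment:
            x0.append([np.log(max(0.1 * vbar, 1e-6))])
        if self.include_gxe:
            x0.append([np.log(max(0.05 * vbar, 1e-6))])
        return np.concatenate(x0)

    def fit(self) -> "FitResult":
        if self.struct.tag == "UN" and len(self.data.plants) < self.data.m:
            raise ValueError(
                "unstructured covariance needs at least as many plants as "
                f"traits ({self.data.m}); use a simpler structure"
            )
        x0 = self.initial_params()
        res = optimize.minimize(self.neg_loglik, x0, method="L-BFGS-B",
                                options={"maxiter": 500})
        if (not res.success or res.fun >= 1e9):
            res2 = optimize.minimize(self.neg_loglik, x0, method="Nelder-Mead",
                                     options={"maxiter": 4000, "fatol": 1e-8,
                                              "xatol": 1e-6})
            if res2.fun < res.fun:
                res = res2
        if res.fun >= 1e9:
            raise RuntimeError(
                f"{self.struct.tag} leaf model did not reach a feasible fit "
                f"(status: {res.message})"
            )
        return self._result(res.x, float(-res.fun), bool(res.success))

    def _result(self, x, loglik, converged) -> FitResult:
        d = self.data
        sigma, s2e, s2ge = self._split(x)
        XtViX, XtViy, _, _ = self._gls_pieces(sigma, s2e, s2ge)
        cf = cho_factor(XtViX)
        beta = cho_solve(cf, XtViy)
        cov = cho_solve(cf, np.eye(d.p))
        index = pd.MultiIndex.from_tuples(d.cells, names=["genotype", "leaf"])
        n_cov = self.n_cov_params()
        return FitResult(
            lsmeans=pd.Series(beta, index=index),
            fixed_cov=cov,
            variance_components={
                "experiment": float(s2e),
                "gxe": float(s2ge),
                "residual_cov": sigma,
            },
            loglik=loglik,
            reml=self.reml,
            aic=-2.0 * loglik + 2.0 * n_cov,
            structure=self.struct.tag,
            gxe_included=self.include_gxe,
            n_used=d.n,
            converged=converged,
        )


def _resolve_leaf_gxe(data: _LeafData, gxe, reml: bool) -> bool:
    """Decide the genotype x experiment term for leaf fits.

    "auto" compares ML fits with/without the term under compound
    symmetry (the cheapest structure) by likelihood-ratio test.
    """
    if gxe in (False, "off") or len(data.experiments) < 2:
        return False
    if gxe in (True, "on"):
        return True
    full = _StructuredLMM(data, "CS", True, True, reml=False)
    red = _StructuredLMM(data, "CS", True, False, reml=False)
    ll_full = -full.neg_loglik(_safe_fit_x(full))
    ll_red = -red.neg_loglik(_safe_fit_x(red))
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    return stats.chi2.sf(stat, 1) < 0.05 if stat > 0 else False


def _safe_fit_x(model: _StructuredLMM) -> np.ndarray:
    res = optimize.minimize(model.neg_loglik, model.initial_params(),
                            method="L-BFGS-B", options={"maxiter": 500})
    return res.x


def fit_leaf_model(measurements: pd.DataFrame, structure: str = "UN",
                   gxe="auto", reml: bool = True,
                   max_leaf: int = MAX_LEAF) -> FitResult:
    """Fit the repeated-measures leaf model for traits L0..L6.

    ``measurements`` is the long leaf table (plant_id, genotype,
    experiment, leaf, area_mm2); leaves above ``max_leaf`` are ignored
    and plants with missing leaves contribute the leaves they have.
    Returns LS-means per (genotype, leaf) with their covariance.
    """
    data = _LeafData(measurements, max_leaf=max_leaf)
    include_exp = len(data.experiments) > 1
    include_gxe = _resolve_leaf_gxe(data, gxe, reml)
    model = _StructuredLMM(data, structure, include_exp, include_gxe, reml)
    return model.fit()


def select_covariance_structure(measurements: pd.DataFrame, gxe="off",
                                reml: bool = True, max_leaf: int = MAX_LEAF
                                ) -> tuple[str, pd.DataFrame]:
    """Choose the residual covariance structure by AIC.

    Fits CS, AR(1), Toeplitz and unstructured with the identical mean
    model and random terms, computes AIC from the (RE)ML likelihood and
    returns the minimiser plus the full AIC table. Ties break towards
    the structure with fewer parameters (CS < AR1 < TOEP < UN); a
    structure that fails to fit is recorded with NaN and skipped.
    """
    data = _LeafData(measurements, max_leaf=max_leaf)
    include_exp = len(data.experiments) > 1
    include_gxe = _resolve_leaf_gxe(data, gxe, reml)
    rows = []
    fits: dict[str, FitResult] = {}
    for tag in STRUCTURE_ORDER:
        model = _StructuredLMM(data, tag, include_exp, include_gxe, reml)
        try:
            fit = model.fit()
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            rows.append({"structure": tag, "n_params": model.n_cov_params(),
                         "loglik": np.nan, "aic": np.nan, "error": str(exc)})
            continue
        fits[tag] = fit
        rows.append({"structure": tag, "n_params": model.n_cov_params(),
                     "loglik": fit.loglik, "aic": fit.aic, "error": ""})
    table = pd.DataFrame(rows).set_index("structure")
    if not fits:
        raise RuntimeError("no covariance structure could be fit")
    aics = table["aic"]
    best = aics.idxmin()  # STRUCTURE_ORDER index order breaks exact ties
    for tag in STRUCTURE_ORDER:  # explicit tie-break towards fewer params
        if tag in fits and np.isclose(aics[tag], aics[best], rtol=0, atol=1e-9):
            best = tag
            break
    return best, table
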