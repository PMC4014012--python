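"""Synthetic screen generator with known genotype effects and epistasis.

The generative model mirrors the analysis model: for plant ``p`` of
genotype ``g`` in experiment ``e``, the vector of log2 leaf areas over
traits L0..L6 is

    y = mu + beta_g + gamma_g * [g is a cross] + b_e + c_{g,e} + eps

with ``mu`` the wild-type baseline per leaf, ``beta_g`` the genotype
effect (a cross inherits the sum of its two controls' effects),
``gamma_g`` the interaction (epistasis) term, ``b_e ~ N(0, s2_E)`` a
random experiment intercept, ``c_{g,e} ~ N(0, s2_GE)`` a genotype x
experiment intercept, and ``eps ~ MVN(0, Sigma)`` correlated residuals
across the leaves of one rosette. Areas are reported in mm^2 as
``2**y``. With ``gamma = 0`` the expected-if-non-interacting identity
holds exactly in expectation on the log2 scale, so every inference
stage has a recoverable ground truth.

Additional real-data features: leaves may be missing (not yet emerged
at harvest) according to per-leaf emergence probabilities, and a small
fraction of plants are germination-failure outliers whose whole
rosette is shrunk by a multiplicative factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariance import cs_matrix, psd_factor
from .ingest import DESIGN_COLUMNS, ScreenDataset

N_LEAF_TRAITS = 7  # L0 (cotyledons) .. L6

#: baseline wild-type mean areas per leaf trait at harvest, mm^2
DEFAULT_LEAF_AREAS_MM2 = (28.0, 80.0, 95.0, 110.0, 95.0, 70.0, 45.0)


@dataclass
class SimulationConfig:
    """Full parameterisation of the generative screen model.

    Parameters
    ----------
    leaf_means : array (7,)
        Baseline log2 areas (log2 mm^2) for traits L0..L6.
    genotype_effects : dict[str, array (7,)]
        Per single-line genotype, log2 effect per leaf. The wild type
        has effect 0 and must not appear here.
    interaction_coeffs : dict[str, array (7,)]
        Per combination (keyed by combo_id), log2 epistasis term per
        leaf; 0 means additive on the log scale.
    design : DataFrame
        Crossing design (combo_id, parent1, parent2, control1,
        control2, wt, maternal_parent, zygosity). Effects are keyed by
        the *control* genotypes; a cross's mean effect is the sum of
        its two controls' effects plus its interaction term.
    sigma2_experiment, sigma2_gxe : float
        Variances of the random experiment and genotype x experiment
        intercepts (log2 scale).
    leaf_residual_cov : array (7, 7)
        Residual covariance across leaf traits (log2 scale), symmetric
        positive definite.
    n_experiments, n_plants : int
        Experiments (repeats) and plants per genotype per experiment.
    leaf_emergence_probs : array (7,)
        Probability that a plant has each leaf at harvest.
    outlier_rate, outlier_shrink_factor : float
        Fraction of plants that failed germination, and the
        multiplicative factor applied to their areas (mm^2 scale).
    maternal_effect_sd : float
        Optional maternal-line intercept s.d. (log2 scale); 0 by
        default because the matched-direction control design cancels
        it.
    seed : int
        Base seed; identical configs with identical seeds give
        byte-identical datasets.
    """

    leaf_means: np.ndarray
    genotype_effects: dict[str, np.ndarray]
    interaction_coeffs: dict[str, np.ndarray]
    design: pd.DataFrame
    sigma2_experiment: float = 0.01
    sigma2_gxe: float = 0.0
    leaf_residual_cov: np.ndarray = field(
        default_factory=lambda: cs_matrix(0.04, 0.6, N_LEAF_TRAITS)
    )
    n_experiments: int = 3
    n_plants: int = 16
    leaf_emergence_probs: np.ndarray = field(
        default_factory=lambda: np.ones(N_LEAF_TRAITS)
    )
    outlier_rate: float = 0.0
    outlier_shrink_factor: float = 0.05
    maternal_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.leaf_means = np.asarray(self.leaf_means, float)
        self.leaf_residual_cov = np.asarray(self.leaf_residual_cov, float)
        self.leaf_emergence_probs = np.asarray(self.leaf_emergence_probs, float)
        self.genotype_effects = {
            g: np.broadcast_to(np.asarray(v, float), (N_LEAF_TRAITS,)).copy()
            for g, v in self.genotype_effects.items()
        }
        self.interaction_coeffs = {
            c: np.broadcast_to(np.asarray(v, float), (N_LEAF_TRAITS,)).copy()
            for c, v in self.interaction_coeffs.items()
        }

    def validate(self) -> None:
        if self.leaf_means.shape != (N_LEAF_TRAITS,):
            raise ValueError(f"leaf_means must have shape ({N_LEAF_TRAITS},)")
        if self.leaf_residual_cov.shape != (N_LEAF_TRAITS, N_LEAF_TRAITS):
            raise ValueError("leaf_residual_cov must be 7x7 (traits L0..L6)")
        psd_factor(self.leaf_residual_cov)  # symmetry + PSD (zero allowed)
        for name in ("sigma2_experiment", "sigma2_gxe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not ((self.leaf_emergence_probs >= 0) & (self.leaf_emergence_probs <= 1)).all():
            raise ValueError("leaf_emergence_probs must lie in [0, 1]")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if not 0 < self.outlier_shrink_factor <= 1:
            raise ValueError("outlier_shrink_factor must lie in (0, 1]")
        if self.n_plants < 2:
            raise ValueError("n_plants must be >= 2")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design missing column(s): {missing}")
        for _, row in self.design.iterrows():
            for col in ("control1", "control2"):
                if row[col] not in self.genotype_effects:
                    raise ValueError(
                        f"no genotype effect for control {row[col]!r} "
                        f"of combination {row['combo_id']!r}"
                    )
            if row["combo_id"] not in self.interaction_coeffs:
                raise ValueError(
                    f"no interaction coefficient for {row['combo_id']!r}"
                )

    # -- genotype bookkeeping ------------------------------------------------

    @property
    def wt_genotype(self) -> str:
        wt = set(self.design["wt"])
        if len(wt) != 1:
            raise ValueError(f"expected a single shared wild type, got {wt}")
        return wt.pop()

    def genotype_means(self) -> dict[str, np.ndarray]:
        """Expected log2 area per leaf for every genotype in the screen."""
        means = {self.wt_genotype: self.leaf_means.copy()}
        for g, beta in self.genotype_effects.items():
            means[g] = self.leaf_means + beta
        for _, row in self.design.iterrows():
            means[row["combo_id"]] = (
                self.leaf_means
                + self.genotype_effects[row["control1"]]
                + self.genotype_effects[row["control2"]]
                + self.interaction_coeffs[row["combo_id"]]
            )
        return means

    # -- (de)serialisation ---------------------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["leaf_means"] = self.leaf_means.tolist()
        data["leaf_residual_cov"] = self.leaf_residual_cov.tolist()
        data["leaf_emergence_probs"] = self.leaf_emergence_probs.tolist()
        data["genotype_effects"] = {g: v.tolist() for g, v in self.genotype_effects.items()}
        data["interaction_coeffs"] = {c: v.tolist() for c, v in self.interaction_coeffs.items()}
        data["design"] = self.design.to_dict(orient="records")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["design"] = pd.DataFrame(data["design"], columns=DESIGN_COLUMNS)
        return cls(**data)


def simulate_screen(config: SimulationConfig) -> ScreenDataset:
    """Draw one full screen dataset from the generative model.

    Deterministic given the config (including its seed). Returns a
    :class:`~episcreen.ingest.ScreenDataset` in the same long format the
    ingest module reads, with the design table attached.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    means = config.genotype_means()
    genotypes = sorted(means)
    chol = psd_factor(config.leaf_residual_cov)
    sd_e = np.sqrt(config.sigma2_experiment)
    sd_ge = np.sqrt(config.sigma2_gxe)

    b_e = rng.normal(0.0, sd_e, size=config.n_experiments)
    maternal = {}
    if config.maternal_effect_sd > 0:
        lines = sorted(config.genotype_effects)
        maternal = dict(zip(lines, rng.normal(0.0, config.maternal_effect_sd,
                                              size=len(lines))))
    mat_shift = _maternal_shifts(config, maternal) if maternal else {}

    frames = []
    leaves = np.arange(N_LEAF_TRAITS)
    for g in genotypes:
        mu_g = means[g] + mat_shift.get(g, 0.0)
        for e in range(config.n_experiments):
            n = config.n_plants
            c_ge = rng.normal(0.0, sd_ge) if sd_ge > 0 else 0.0
            eps = rng.standard_normal((n, N_LEAF_TRAITS)) @ chol.T
            y = mu_g + b_e[e] + c_ge + eps
            present = rng.random((n, N_LEAF_TRAITS)) < config.leaf_emergence_probs
            outlier = rng.random(n) < config.outlier_rate
            y[outlier] += np.log2(config.outlier_shrink_factor)
            plant_ids = [f"{g}|e{e + 1}|p{i + 1}" for i in range(n)]
            pi, li = np.nonzero(present)
            frames.append(pd.DataFrame({
                "plant_id": np.array(plant_ids, dtype=object)[pi],
                "genotype": g,
                "experiment": f"E{e + 1}",
                "leaf": leaves[li],
                "area_mm2": 2.0 ** y[pi, li],
            }))
    measurements = pd.concat(frames, ignore_index=True)
    return ScreenDataset(measurements=measurements, design=config.design.copy())


def _maternal_shifts(config, maternal):
    """Per-genotype shift from an optional maternal-line intercept.

    Each heterozygous genotype inherits the intercept of its maternal
    line; the matched-direction control design makes these cancel in
    the epistasis contrast, which is what the option exists to verify.
    """
    shifts = {}
    for _, row in config.design.iterrows():
        m = maternal.get(row["maternal_parent"], 0.0)
        shifts[row["combo_id"]] = m
        # the control whose cross used the same maternal line
        if row["maternal_parent"] == row["parent1"]:
            shifts[row["control1"]] = m
        else:
            shifts[row["control2"]] = m
    return shifts


def null_screen_config(n_combinations: int, seed: int = 0,
                       **overrides) -> SimulationConfig:
    """A screen-scale configuration with no epistasis (gamma = 0).

    Builds the smallest all-pairs design covering ``n_combinations``
    combinations among single transgenic lines, each line 5-25% above
    the wild type (drawn once from the seed), three experiments of 16
    plants per genotype, and realistic nuisance structure (experiment
    variance, correlated within-rosette residuals, occasional missing
    late leaves, rare germination failures). Keyword overrides replace
    any :class:`SimulationConfig` field, e.g.
    ``null_screen_config(60, interaction_coeffs=...)`` after editing.
    """
    if n_combinations < 1:
        raise ValueError("n_combinations must be >= 1")
    n_lines = 2
    while n_lines * (n_lines - 1) // 2 < n_combinations:
        n_lines += 1
    rng = np.random.default_rng(seed)
    lines = [f"L{i + 1:02d}" for i in range(n_lines)]
    controls = {ln: f"{ln}xWT" for ln in lines}
    # single heterozygous lines sit 5-25% above the wild type
    effects = {
        controls[ln]: np.full(N_LEAF_TRAITS,
                              rng.uniform(np.log2(1.05), np.log2(1.25)))
        for ln in lines
    }
    rows = []
    for p1, p2 in itertools.islice(itertools.combinations(lines, 2),
                                   n_combinations):
        rows.append({
            "combo_id": f"{p1}x{p2}",
            "parent1": p1,
            "parent2": p2,
            "control1": controls[p1],
            "control2": controls[p2],
            "wt": "WT",
            "maternal_parent": p1,
            "zygosity": "heterozygous",
        })
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    gamma = {r["combo_id"]: np.zeros(N_LEAF_TRAITS) for r in rows}
    defaults = dict(
        leaf_means=np.log2(DEFAULT_LEAF_AREAS_MM2),
        genotype_effects=effects,
        interaction_coeffs=gamma,
        design=design,
        sigma2_experiment=0.01,
        sigma2_gxe=0.0,
        leaf_residual_cov=cs_matrix(0.04, 0.6, N_LEAF_TRAITS),
        n_experiments=3,
        n_plants=16,
        leaf_emergence_probs=np.array([1, 1, 1, 1, 1, 0.97, 0.9]),
        outlier_rate=0.01,
        outlier_shrink_factor=0.05,
        seed=seed,
    )
    defaults.update(overrides)
    config = SimulationConfig(**defaults)
    config.validate()
    return config


def write_dataset(dataset: ScreenDataset, outdir) -> tuple[Path, Path]:
    """Write measurements.csv and design.csv in the schema ingest reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mpath = outdir / "measurements.csv"
    dpath = outdir / "design.csv"
    dataset.measurements.to_csv(mpath, index=False)
    dataset.design.to_csv(dpath, index=False)
    return mpath, dpath
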