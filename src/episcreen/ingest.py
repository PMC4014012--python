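"""Reading, validation and aggregation of leaf-area measurement tables.

The screen's raw unit of observation is one dissected leaf blade of one
plant at harvest (21 days after stratification), identified by a leaf
index (L0 = cotyledons, L1..Ln = rosette leaves) and measured in mm^2.
This module loads such long-format tables together with the crossing
design, derives per-plant rosette areas (the sum of all dissected
leaves) and removes germination-failure outliers with a one-sided
robust rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical measurement columns after schema mapping
MEASUREMENT_COLUMNS = ["plant_id", "genotype", "experiment", "leaf", "area_mm2"]

#: canonical design columns
DESIGN_COLUMNS = [
    "combo_id",
    "parent1",
    "parent2",
    "control1",
    "control2",
    "wt",
    "maternal_parent",
    "zygosity",
]

#: MAD -> standard-deviation consistency factor for Gaussian data
MAD_SCALE = 1.4826


class SchemaError(ValueError):
    """An input table lacks a required column or has an invalid design."""


@dataclass
class ScreenDataset:
    """A validated screen: leaf measurements plus the crossing design.

    Attributes
    ----------
    measurements : DataFrame
        Columns ``plant_id, genotype, experiment, leaf, area_mm2``; one
        row per (plant, leaf), area strictly positive.
    design : DataFrame
        Columns ``combo_id, parent1, parent2, control1, control2, wt,
        maternal_parent, zygosity``. ``combo_id`` is also the genotype
        identifier of the cross in ``measurements``.
    rejections : DataFrame
        Input rows that violated an invariant, with a ``reason`` column.
        Rows are reported, never silently dropped.
    """

    measurements: pd.DataFrame
    design: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=DESIGN_COLUMNS)
    )
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.measurements["genotype"].unique())

    def validate_design(self) -> list[str]:
        """Cross-check design against measurements; return violation messages."""
        problems: list[str] = []
        present = set(self.measurements["genotype"].unique())
        for _, row in self.design.iterrows():
            for col in ("combo_id", "control1", "control2", "wt"):
                if row[col] not in present:
                    problems.append(
                        f"combination {row['combo_id']}: genotype {row[col]!r} "
                        f"({col}) has no measurements"
                    )
            ids = [row["combo_id"], row["control1"], row["control2"], row["wt"],
                   row["parent1"], row["parent2"]]
            if len(set(ids)) < 5:
                problems.append(
                    f"combination {row['combo_id']}: genotype identifiers not distinct"
                )
            if row["maternal_parent"] not in (row["parent1"], row["parent2"]):
                problems.append(
                    f"combination {row['combo_id']}: maternal_parent "
                    f"{row['maternal_parent']!r} is neither parent"
                )
        counts = (
            self.measurements.groupby(["genotype", "experiment"])["plant_id"]
            .nunique()
        )
        for (g, e), n in counts.items():
            if n < 2:
                problems.append(
                    f"genotype {g!r} has {n} plant(s) in experiment {e!r}; "
                    "model fitting needs >= 2"
                )
        return problems

    def subset(self, genotypes) -> "ScreenDataset":
        keep = self.measurements["genotype"].isin(set(genotypes))
        return ScreenDataset(
            measurements=self.measurements.loc[keep].copy(),
            design=self.design,
            rejections=self.rejections,
        )


def load_measurements(path, schema: dict | None = None,
                      design_path=None, sep: str = ",") -> ScreenDataset:
    """Read a delimited measurement table into a validated ScreenDataset.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with one row per (plant, leaf).
    schema : dict, optional
        Mapping from file column names to the canonical names
        ``plant_id, genotype, experiment, leaf, area_mm2``.
    design_path : str, optional
        Crossing-design CSV (see :func:`load_design`).

    Rows with non-positive area, missing fields, or a duplicated
    (plant, leaf) key are moved to ``rejections`` with a reason.
    A missing required column raises :class:`SchemaError`.
    """
    raw = pd.read_csv(path, sep=sep)
    if schema:
        raw = raw.rename(columns=schema)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = raw[MEASUREMENT_COLUMNS].copy()

    reasons = pd.Series("", index=df.index, dtype=object)
    area = pd.to_numeric(df["area_mm2"], errors="coerce")
    leaf = pd.to_numeric(df["leaf"], errors="coerce")
    reasons[df[MEASUREMENT_COLUMNS].isna().any(axis=1)] = "missing field"
    reasons[area.isna() & (reasons == "")] = "non-numeric area"
    reasons[(area <= 0) & (reasons == "")] = "non-positive area"
    reasons[((leaf < 0) | (leaf != leaf.round())) & (reasons == "")] = (
        "invalid leaf index"
    )
    dup = df.duplicated(subset=["plant_id", "leaf"], keep="first")
    reasons[dup & (reasons == "")] = "duplicate (plant, leaf)"

    bad = reasons != ""
    rejections = df.loc[bad].assign(reason=reasons[bad])
    clean = df.loc[~bad].copy()
    clean["area_mm2"] = area[~bad]
    clean["leaf"] = leaf[~bad].astype(int)
    if len(rejections):
        log.warning("rejected %d of %d rows", len(rejections), len(df))

    design = load_design(design_path) if design_path is not None else pd.DataFrame(
        columns=DESIGN_COLUMNS
    )
    return ScreenDataset(measurements=clean.reset_index(drop=True),
                         design=design, rejections=rejections)


def load_design(path, sep: str = ",") -> pd.DataFrame:
    """Read the crossing-design table (combinations and their controls)."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"design table missing column(s): {', '.join(missing)}")
    for _, row in df.iterrows():
        if row["maternal_parent"] not in (row["parent1"], row["parent2"]):
            raise SchemaError(
                f"combination {row['combo_id']}: maternal_parent must be "
                "parent1 or parent2"
            )
    return df[DESIGN_COLUMNS].copy()


def compute_rosette_areas(dataset: ScreenDataset | pd.DataFrame) -> pd.DataFrame:
    """Per-plant rosette area: the sum of all measured leaf areas.

    Every measured leaf contributes, including indices above L6; leaves
    absent from the table (not yet emerged at harvest) contribute
    nothing. Returns one row per plant with columns ``plant_id,
    genotype, experiment, rosette_area_mm2``.
    """
    meas = dataset.measurements if isinstance(dataset, ScreenDataset) else dataset
    if meas.empty:
        warnings.warn("no measurements: empty rosette table")
        return pd.DataFrame(
            columns=["plant_id", "genotype", "experiment", "rosette_area_mm2"]
        )
    out = (
        meas.groupby(["plant_id", "genotype", "experiment"], as_index=False)[
            "area_mm2"
        ]
        .sum()
        .rename(columns={"area_mm2": "rosette_area_mm2"})
    )
    return out.sort_values("plant_id", ignore_index=True)


def filter_outliers(rosettes: pd.DataFrame, k: float = 3.5
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove germination-failure outliers, one-sided and per cell.

    Germination problems produce severely undersized plants, so within
    each genotype x experiment cell a plant is removed when its log2
    rosette area lies more than ``k`` robust scale units (median
    absolute deviation x 1.4826) *below* the cell median. Oversized
    plants are never removed. Cells with fewer than 3 plants, or with
    zero median absolute deviation, are left untouched (with a warning
    for small cells).

    Returns ``(kept, removed)``; ``removed`` carries a ``reason`` column.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if rosettes.empty:
        return rosettes.copy(), rosettes.assign(reason=pd.Series(dtype=object))

    logs = np.log2(rosettes["rosette_area_mm2"].to_numpy(float))
    drop = np.zeros(len(rosettes), dtype=bool)
    reason = np.empty(len(rosettes), dtype=object)
    for (g, e), idx in rosettes.groupby(["genotype", "experiment"]).indices.items():
        vals = logs[idx]
        if len(vals) < 3:
            warnings.warn(
                f"cell ({g}, {e}) has {len(vals)} plant(s); outlier rule skipped"
            )
            continue
        med = np.median(vals)
        scale = MAD_SCALE * np.median(np.abs(vals - med))
        if scale == 0.0:
            continue
        z = (med - vals) / scale  # positive when below the median
        flag = z > k
        drop[idx[flag]] = True
        for i in idx[flag]:
            reason[i] = (
                f"log2 rosette area {(med - logs[i]) / scale:.1f} robust units "
                f"below cell median (k={k})"
            )
    kept = rosettes.loc[~drop].reset_index(drop=True)
    removed = rosettes.loc[drop].assign(reason=reason[drop]).reset_index(drop=True)
    if len(removed):
        log.info("removed %d outlier plant(s)", len(removed))
    return kept, removed
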