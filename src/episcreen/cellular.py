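"""Cellular phenotyping: leaf area, cell number and cell area vs WT.

The cellular basis of a growth phenotype is resolved by measuring, on
a few replicate leaves (typically leaf 3, n = 3), the blade area and
the mean area of drawn abaxial epidermal cells; the epidermal cell
number follows as blade area / mean cell area. Each genotype is then
compared to the wild type as a percent difference per metric with a
small-sample Welch t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("blade_area", "cell_number", "cell_area")

REQUIRED_COLUMNS = ["genotype", "replicate", "blade_area_mm2",
                    "mean_cell_area_mm2"]


def derive_cell_number(blade_area: float, mean_cell_area: float) -> float:
    """Epidermal cell number: blade area divided by mean cell area."""
    if blade_area <= 0 or mean_cell_area <= 0:
        raise ValueError("areas must be positive")
    return blade_area / mean_cell_area


def load_cell_samples(path_or_df, sep: str = ",") -> pd.DataFrame:
    """Read/validate a cellular-measurement table and derive cell numbers."""
    df = (path_or_df.copy() if isinstance(path_or_df, pd.DataFrame)
          else pd.read_csv(path_or_df, sep=sep))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if (df["blade_area_mm2"] <= 0).any() or (df["mean_cell_area_mm2"] <= 0).any():
        raise ValueError("areas must be positive")
    df["cell_number"] = df["blade_area_mm2"] / df["mean_cell_area_mm2"]
    return df


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    # degenerate zero-variance groups at n=3: equal means <=> no difference
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def cellular_differences(samples: pd.DataFrame, wt_genotype: str,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Percent difference vs WT per genotype and metric, with p-values.

    For each non-WT genotype and each of blade area, cell number and
    mean cell area, computes ``100 * (mean_mut - mean_wt) / mean_wt``
    and a two-sided Welch two-sample t-test against the WT replicates.
    Returns one row per (genotype, metric) with a significance flag at
    ``p < alpha``. Percent differences are invariant to a common unit
    rescaling of all areas.
    """
    df = load_cell_samples(samples)
    if wt_genotype not in set(df["genotype"]):
        raise ValueError(f"wild-type genotype {wt_genotype!r} not in data")
    counts = df.groupby("genotype")["replicate"].count()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"need >= 2 replicates per genotype; too few for: "
            f"{', '.join(map(str, small.index))}"
        )
    values = {
        "blade_area": df.set_index("genotype")["blade_area_mm2"],
        "cell_number": df.set_index("genotype")["cell_number"],
        "cell_area": df.set_index("genotype")["mean_cell_area_mm2"],
    }
    rows = []
    for g in sorted(set(df["genotype"]) - {wt_genotype}):
        for metric in METRICS:
            mut = values[metric].loc[[g]].to_numpy(float)
            wt = values[metric].loc[[wt_genotype]].to_numpy(float)
            pct = 100.0 * (mut.mean() - wt.mean()) / wt.mean()
            p = _welch_p(mut, wt)
            rows.append({
                "genotype": g,
                "metric": metric,
                "percent_difference": pct,
                "p_value": p,
                "significant": p < alpha,
                "n": len(mut),
                "n_wt": len(wt),
            })
    return pd.DataFrame(rows)
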