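import numpy as np
import pandas as pd
import pytest

from episcreen import null_screen_config, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def tiny_screen():
    """One combination, 3 experiments x 16 plants, full leaf series."""
    cfg = null_screen_config(1, seed=11, outlier_rate=0.0,
                             leaf_emergence_probs=np.ones(7))
    return cfg, simulate_screen(cfg)


@pytest.fixture
def single_experiment_screen():
    """One combination in a single balanced experiment (no random terms)."""
    cfg = null_screen_config(1, seed=17, n_experiments=1, n_plants=24,
                             sigma2_experiment=0.0, outlier_rate=0.0,
                             leaf_emergence_probs=np.ones(7))
    return cfg, simulate_screen(cfg)


def make_rosettes(areas_by_cell):
    """Rosette table from {(genotype, experiment): [areas mm^2]}."""
    rows = []
    for (g, e), areas in areas_by_cell.items():
        for i, a in enumerate(areas):
            rows.append({"plant_id": f"{g}|{e}|p{i}", "genotype": g,
                         "experiment": e, "rosette_area_mm2": float(a)})
    return pd.DataFrame(rows)
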