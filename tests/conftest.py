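import numpy as np
import pandas as pd
import pytest

from coedit.simulate import CohortConfig, default_planted_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Planted cohort small enough for unit tests: 4 planted pairs over 40
    sites, 150 tumors, with shared associated genes and 1 hazard pair."""
    cfg = default_planted_config(seed=11, n_tumor=150, n_sites=40, n_pairs=4,
                                 joint_boost=0.8, n_hazard_pairs=1)
    cfg.n_genes = 200
    editing, expression, clinical, segments, truth = generate_cohort(cfg)
    return {
        "config": cfg, "editing": editing, "expression": expression,
        "clinical": clinical, "segments": segments, "truth": truth,
    }


@pytest.fixture()
def tiny_edit_status():
    """4 sites x 6 samples hand-written binary matrix."""
    return pd.DataFrame(
        [[1, 1, 1, 0, 0, 0],
         [1, 1, 1, 1, 0, 0],
         [0, 0, 0, 1, 1, 1],
         [1, 0, 1, 0, 1, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"p{i}" for i in range(6)],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
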