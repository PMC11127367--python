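import numpy as np
import pandas as pd
import pytest

from scnoise import SimulationConfig, build_truth, simulate_counts


@pytest.fixture
def tiny_config():
    """Two clones, one integration each, three cells per clone, noise off."""
    return SimulationConfig(
        n_clones=2,
        integrations_per_clone=(1, 0),
        cells_per_clone=3,
        mu_loc=(float(np.log(20.0)), 0.0),
        sigma_ext=0.0,
        sigma_int=0.0,
        capture_scale=0.0,
        dropout_rate=0.0,
        barcode_error_rate=0.0,
        pcr_dup_mean=0.0,
        seed=1,
    )


@pytest.fixture
def small_matrix():
    """Deterministic 6-cell x 3-location count matrix for quant tests."""
    return pd.DataFrame(
        {
            "locA": [3, 2, 5, 1, 4, 2],
            "locB": [7, 1, 0, 2, 3, 1],
            "locC": [0, 4, 2, 6, 1, 3],
        },
        index=[f"cell{i}" for i in range(6)],
    )


@pytest.fixture
def simulated_pool():
    """A moderately sized noisy pool with its ground truth."""
    cfg = SimulationConfig(
        n_clones=15,
        cells_per_clone=25,
        dropout_rate=0.2,
        barcode_error_rate=0.0,
        seed=5,
    )
    truth = build_truth(cfg)
    counts = simulate_counts(truth, cfg)
    return cfg, truth, counts
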