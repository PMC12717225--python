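import numpy as np
import pandas as pd
import pytest

from plaquespace.simulate import SimConfig, generate_sample


@pytest.fixture(scope="session")
def small_sample():
    """One 300-cell plaque sample with the default catalogue."""
    cfg = SimConfig(cells_per_sample=300, seed=11)
    return generate_sample(cfg, "S00", "plaque", sample_index=0)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(cells_per_sample=300, seed=11)


def make_cells(xy, labels, sample_id="S0"):
    """Minimal cell table from coordinates and substate labels."""
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i}" for i in range(len(xy))],
            "sample_id": sample_id,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "area_um2": 100.0,
            "substate": list(labels),
            "avg_assignment_confidence": 0.9,
            "max_cluster_frac": 0.95,
            "lifespan": 100.0,
        }
    )
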