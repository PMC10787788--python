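import numpy as np
import pandas as pd
import pytest

from sstseg.config import SimConfig
from sstseg.markers import ReferenceProfile
from sstseg.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset shared by read-only tests."""
    cfg = SimConfig(image_height=96, image_width=96, n_cells=8, n_genes=20,
                    n_cell_types=3, mean_transcripts_per_cell=150,
                    background_noise_rate=0.0, rng_seed=7)
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def toy_profile():
    """Three types x nine genes with clean block structure."""
    genes = [f"G{i}" for i in range(9)]
    rows = np.full((3, 9), 1.0)
    for i in range(3):
        rows[i, 3 * i:3 * i + 3] = 8.0
        for j in range(3):
            if j != i:
                rows[i, 3 * j:3 * j + 3] = 0.125
    df = pd.DataFrame(rows, index=["type_0", "type_1", "type_2"], columns=genes)
    return ReferenceProfile(df, {"type_0": True, "type_1": False, "type_2": False})
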