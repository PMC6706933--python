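import numpy as np
import pandas as pd
import pytest

from chemoscreen import ScreenCounts, SimConfig, simulate_screen


def null_sim_config(seed: int, n_genes: int = 500) -> SimConfig:
    """A screen where treated and control differ only by resampling noise."""
    return SimConfig(
        n_genes=n_genes,
        frac_synergy=0.0,
        frac_suppressor=0.0,
        fitness_frac=0.0,
        effect_size=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def strong_screen():
    """1000 genes x 4 guides x 3 replicates, 5% synergy + 5% suppressor
    genes planted at a strong (-2 log2) effect, 10% fitness-only genes."""
    return simulate_screen(SimConfig(n_genes=1000, seed=11))


@pytest.fixture(scope="session")
def null_screen():
    return simulate_screen(null_sim_config(seed=0))


@pytest.fixture
def tiny_screen():
    """Hand-built 6-guide, 3-gene screen with one paired replicate."""
    counts = pd.DataFrame(
        {
            "C1": [100, 120, 80, 200, 150, 90],
            "T1": [50, 55, 40, 210, 160, 300],
        },
        index=pd.Index(
            ["gA_1", "gA_2", "gA_3", "gB_1", "gB_2", "gC_1"], name="GUIDE"
        ),
        dtype=np.int64,
    )
    genes = pd.Series(
        ["A", "A", "A", "B", "B", "C"], index=counts.index, name="GENE"
    )
    return ScreenCounts(
        counts=counts,
        genes=genes,
        control_samples=["C1"],
        treated_samples=["T1"],
    )
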