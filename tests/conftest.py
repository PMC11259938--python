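import numpy as np
import pandas as pd
import pytest

from dscore import synthetic


def make_variants(rows):
    """Build a variant frame from (id, chrom, pos, maf, functional_class) tuples."""
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos", "maf", "functional_class"])
    df["chrom"] = df["chrom"].astype(str)
    for col in ["dist_tss", "gene_density", "ld_partners"]:
        df[col] = 0
    df["ld_block"] = pd.NA
    df["assoc_p"] = np.nan
    df["date_added"] = pd.NaT
    return df


@pytest.fixture(scope="session")
def planted_dataset():
    """Small benchmark with 3 informative tissues out of 10, 1:10 design."""
    cfg = synthetic.SimulationConfig(
        n_pos=80,
        n_ctrl_per_pos=10,
        d_tissues=10,
        planted_support=(0, 1, 2),
        planted_beta=(4.0, 4.0, 4.0),
        seed=42,
    )
    return synthetic.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Labels independent of scores (no planted effects at all)."""
    cfg = synthetic.SimulationConfig(
        n_pos=60, n_ctrl_per_pos=10, d_tissues=8, baseline_alpha=0.0, seed=7
    )
    return synthetic.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def pool_20k():
    return synthetic.simulate_pool(20_000, seed=3)
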