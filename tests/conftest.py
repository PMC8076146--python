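import numpy as np
import pandas as pd
import pytest

from mrkit.summary_data import CANONICAL_COLUMNS, HarmonizedSet, SummaryDataset


def make_dataset(rows, trait_name="trait", trait_type="binary"):
    """Build a SummaryDataset from dicts of canonical fields (rest NA)."""
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return SummaryDataset(trait_name, trait_type, df[CANONICAL_COLUMNS])


def make_harmonized(beta_exp, se_exp, beta_out, se_out,
                    exposure="exposure", outcome="outcome"):
    snps = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(len(beta_exp))],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
    })
    return HarmonizedSet(exposure, outcome, snps)


@pytest.fixture
def five_snp_set():
    """Fixed 5-SNP harmonised table with unequal weights."""
    return make_harmonized(
        beta_exp=[0.10, 0.08, 0.12, 0.05, 0.20],
        se_exp=[0.010, 0.012, 0.009, 0.015, 0.008],
        beta_out=[0.031, 0.020, 0.041, 0.012, 0.055],
        se_out=[0.012, 0.020, 0.010, 0.030, 0.008])


@pytest.fixture
def six_snp_set():
    """Fixed 6-SNP table (all exposure betas positive, Egger-ready)."""
    return make_harmonized(
        beta_exp=[0.10, 0.08, 0.12, 0.05, 0.20, 0.15],
        se_exp=[0.010, 0.012, 0.009, 0.015, 0.008, 0.011],
        beta_out=[0.035, 0.022, 0.044, 0.018, 0.058, 0.047],
        se_out=[0.012, 0.020, 0.010, 0.030, 0.008, 0.014])
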