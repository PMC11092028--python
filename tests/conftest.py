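import numpy as np
import pandas as pd
import pytest

from mrkit.sumstats import SumStatsTable, SUMSTATS_COLUMNS, harmonize
from mrkit.instruments import select_by_pvalue, filter_weak
from mrkit.synth import harmonized_from_arrays


def make_table(rows, trait_name="trait", trait_type="continuous"):
    """Build a SumStatsTable from a list of dicts, filling optional fields."""
    df = pd.DataFrame(rows)
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if df["chrom"].isna().all():
        df["chrom"] = "1"
    if df["pos_bp"].isna().all():
        df["pos_bp"] = np.arange(len(df), dtype=float) * 1e6 + 1
    return SumStatsTable(trait_name, trait_type, df[SUMSTATS_COLUMNS])


def instruments_leg(exposure, outcome, p_threshold):
    """p-filter + F-screen + harmonize, skipping LD clumping (independent SNPs)."""
    t = select_by_pvalue(exposure, p_threshold)
    inst = filter_weak(t)
    it = SumStatsTable(exposure.trait_name, exposure.trait_type,
                       inst.df[exposure.df.columns])
    return harmonize(it, outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_harmonized():
    """Five clean instruments with a true ratio of 0.5 and no noise."""
    bx = np.array([0.1, 0.2, 0.15, -0.12, 0.3])
    sx = np.full(5, 0.01)
    so = np.full(5, 0.02)
    by = 0.5 * bx
    return harmonized_from_arrays(bx, sx, by, so)
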