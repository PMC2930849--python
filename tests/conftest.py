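import numpy as np
import pandas as pd
import pytest

from sibscan.lifetable import gompertz_life_table
from sibscan.panel import MarkerPanel, simulate_panel
from sibscan.simulate import simulate_cohort


@pytest.fixture(scope="session")
def life_table():
    return gompertz_life_table()


@pytest.fixture(scope="session")
def small_panel():
    """One 100-cM chromosome, 40 markers."""
    return simulate_panel(40, [100.0], maf_mean=0.3, seed=11)


@pytest.fixture(scope="session")
def null_cohort(small_panel):
    """30 sibships, no planted locus."""
    return simulate_cohort(small_panel, 30, seed=7)


def toy_panel(cms, chrom=1, freqs=None):
    """Hand-built panel at explicit cM positions."""
    cms = np.asarray(cms, dtype=float)
    if freqs is None:
        freqs = np.full(len(cms), 0.5)
    df = pd.DataFrame({
        "marker": [f"m{i + 1}" for i in range(len(cms))],
        "chrom": chrom,
        "bp": (cms * 1e6).astype(int) + 1,
        "cm": cms,
        "freq": freqs,
    })
    return MarkerPanel(df)
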