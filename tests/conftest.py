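import numpy as np
import pandas as pd
import pytest

from osteomr.sumstats import COLUMNS, HarmonizedInstrumentSet, SummaryStatsTable


def make_table(rows, trait_name="trait", trait_type="binary", **kwargs):
    """Build a SummaryStatsTable from a list of per-SNP dicts.

    Unspecified fields get valid defaults so tests only state what they
    exercise.
    """
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.01,
        "se": 0.01,
        "pvalue": 0.5,
        "n": 10_000,
    }
    full = []
    for i, row in enumerate(rows):
        rec = {"snp_id": f"rs{i + 1}", **defaults, **row}
        full.append(rec)
    df = pd.DataFrame(full)[COLUMNS]
    return SummaryStatsTable(trait_name, trait_type, df, **kwargs)


def make_hset(bx, by, se_by=None, se_bx=None, exposure_type="quantitative"):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_by = np.full_like(bx, 0.01) if se_by is None else np.asarray(se_by, float)
    se_bx = np.full_like(bx, 0.01) if se_bx is None else np.asarray(se_bx, float)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(len(bx))],
            "bx": bx,
            "se_bx": se_bx,
            "by": by,
            "se_by": se_by,
        }
    )
    return HarmonizedInstrumentSet("x", "y", exposure_type, df)


@pytest.fixture
def random_table():
    """A reproducible random-but-valid summary-statistics table."""
    rng = np.random.default_rng(1234)
    n = 50
    rows = []
    for i in range(n):
        se = float(rng.uniform(0.005, 0.05))
        beta = float(rng.normal(0, 0.05))
        rows.append(
            {
                "snp_id": f"rs{i + 1}",
                "chrom": str(rng.integers(1, 23)),
                "pos": int(rng.integers(1, 10**8)),
                "eaf": float(rng.uniform(0.01, 0.99)),
                "beta": beta,
                "se": se,
                "pvalue": float(rng.uniform(1e-12, 1.0)),
                "n": int(rng.integers(1000, 500_000)),
            }
        )
    return make_table(rows)
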