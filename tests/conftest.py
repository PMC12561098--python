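import numpy as np
import pandas as pd
import pytest

from mrmediate import build_summary_stats


def make_table(rows: list[dict]) -> pd.DataFrame:
    """Canonical summary-stats frame from sparse row dicts."""
    defaults = {"chrom": "1", "pos": 1000, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.02,
                "pval": 1e-9, "n": 10_000}
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults, rsid=f"rs{i + 1}", pos=1000 + 500 * i)
        rec.update(row)
        full.append(rec)
    return pd.DataFrame(full)


@pytest.fixture
def simple_exposure():
    """Three genome-wide-significant instruments."""
    tab = make_table([
        {"rsid": "rs1", "beta": 0.10, "se": 0.01, "pval": 1e-23, "eaf": 0.30},
        {"rsid": "rs2", "beta": 0.08, "se": 0.01, "pval": 1e-15, "eaf": 0.20,
         "effect_allele": "C", "other_allele": "T"},
        {"rsid": "rs3", "beta": -0.06, "se": 0.01, "pval": 1e-9, "eaf": 0.40},
    ])
    return build_summary_stats(tab, "exposure")


@pytest.fixture
def simple_outcome():
    tab = make_table([
        {"rsid": "rs1", "beta": 0.025, "se": 0.012, "pval": 0.04, "eaf": 0.31},
        {"rsid": "rs2", "beta": 0.020, "se": 0.011, "pval": 0.07, "eaf": 0.21,
         "effect_allele": "C", "other_allele": "T"},
        {"rsid": "rs3", "beta": -0.015, "se": 0.010, "pval": 0.13, "eaf": 0.41},
    ])
    return build_summary_stats(tab, "outcome", trait_type="binary")


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)
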