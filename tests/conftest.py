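import numpy as np
import pandas as pd
import pytest

from mrtriad.instruments import InstrumentSet, LdMatrix
from mrtriad.sumstats import CANONICAL_COLUMNS, SummaryStatsTable


def make_table(rows, trait_id="trait", trait_type="quantitative", **kwargs):
    """Build a SummaryStatsTable from a list of row dicts, filling defaults."""
    defaults = {"chrom": "1", "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3, "n": 10000.0}
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("variant_id", f"rs{i + 1}")
        r.setdefault("pos", 1_000_000 + i * 100_000)
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS) if full else pd.DataFrame(
        columns=CANONICAL_COLUMNS)
    if full:
        df = df.astype({"pos": "int64", "eaf": float, "beta": float,
                        "se": float, "pval": float, "n": float})
    return SummaryStatsTable(trait_id=trait_id, data=df, trait_type=trait_type,
                             **kwargs)


def make_instruments(b_gx, se_gx, b_gy, se_gy, **kwargs):
    k = len(b_gx)
    defaults = dict(exposure_id="X", outcome_id="Y", level="e5",
                    variant_ids=[f"rs{i + 1}" for i in range(k)])
    defaults.update(kwargs)
    return InstrumentSet(b_gx=np.asarray(b_gx, float), se_gx=np.asarray(se_gx, float),
                         b_gy=np.asarray(b_gy, float), se_gy=np.asarray(se_gy, float),
                         **defaults)


@pytest.fixture
def identity_ld():
    def _build(variant_ids):
        return LdMatrix(list(variant_ids), np.eye(len(variant_ids)))
    return _build
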