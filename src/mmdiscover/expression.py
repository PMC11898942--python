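"""miRNA expression preprocessing: normalization to the modeling scale.

The classifier stages operate on log2 counts-per-million.  Raw small-RNA
count tables are normalized per sample (scale invariant: doubling every
count in a sample leaves its row unchanged) and sparsely expressed
features can be dropped before modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureTable

#: Default fraction of samples in which a feature must be nonzero to survive
#: low-expression filtering.
DEFAULT_MIN_NONZERO_FRACTION = 0.2


def normalize_cpm_log(counts: FeatureTable) -> FeatureTable:
    """log2(1 + CPM) per-sample normalization of a raw count table."""
    x = counts.values
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = [counts.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"zero-total samples: {bad}")
    cpm = x / totals[:, None] * 1e6
    out = pd.DataFrame(
        np.log2(1.0 + cpm), index=counts.data.index, columns=counts.data.columns
    )
    return FeatureTable(out, counts.modality)


def filter_low_expression(
    table: FeatureTable, min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION
) -> FeatureTable:
    """Keep features nonzero in at least the given fraction of samples.

    Column order is preserved; filtering twice is a no-op.
    """
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise ValueError("min_nonzero_fraction must be in [0, 1]")
    frac = (table.values != 0).mean(axis=0)
    keep = [f for f, ok in zip(table.feature_ids, frac >= min_nonzero_fraction) if ok]
    if not keep:
        raise ValueError(
            f"no feature is nonzero in >= {min_nonzero_fraction:.0%} of samples"
        )
    return table.select(keep)
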