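"""Absolute-abundance ASV table: amplicon proportions scaled by qPCR loads.

Amplicon counts are compositional — they carry relative information only.
Multiplying each sample's ASV proportions by its independently measured
total 16S copy number turns the table into estimated absolute copy numbers,
the object on which all downstream community statistics operate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["to_proportions", "scale_by_load", "build_absolute_table"]


def to_proportions(asv_counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a samples x ASVs count table so each row sums to 1.

    Samples with zero total counts are excluded with a warning.
    """
    totals = asv_counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-count sample(s): "
                      f"{list(asv_counts.index[zero])[:5]}")
    counts = asv_counts.loc[~zero]
    return counts.div(counts.sum(axis=1), axis=0)


def scale_by_load(proportions: pd.DataFrame, loads: pd.Series) -> pd.DataFrame:
    """Entrywise product proportion(sample, asv) x load(sample).

    Samples without a load value are excluded with a warning; all-zero rows
    (zero load) are kept but flagged.
    """
    have = proportions.index.intersection(loads.index)
    missing = proportions.index.difference(loads.index)
    if len(missing):
        warnings.warn(f"excluding {len(missing)} sample(s) without a qPCR load: "
                      f"{list(missing)[:5]}")
    props = proportions.loc[have]
    loads = loads.loc[have].astype(float)
    if (loads == 0).any():
        warnings.warn(f"{int((loads == 0).sum())} sample(s) have zero load; "
                      "their rows are all-zero (degenerate)")
    table = props.mul(loads, axis=0)
    # row sums must reproduce the loads to numerical precision
    resid = np.abs(table.sum(axis=1) - loads) / np.maximum(loads, 1e-300)
    if (resid[loads > 0] > 1e-9).any():
        raise AssertionError("row-sum invariant violated in scale_by_load")
    return table


def build_absolute_table(asv_counts: pd.DataFrame, loads: pd.Series) -> pd.DataFrame:
    """Convenience: proportions then load scaling."""
    return scale_by_load(to_proportions(asv_counts), loads)
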