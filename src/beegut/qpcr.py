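"""Absolute bacterial quantification from qPCR quantification cycles.

The chain is: fit a standard curve (Cq vs log10 plasmid copies) per target
gene, invert it to raw copies per microlitre with n = E^(intercept - Cq),
scale by the DNA elution volume to copies per gut, normalize 16S copies
against the host actin gene (divide by the sample's actin copies, multiply
by the across-sample median actin copies — this cancels gut-size and
extraction-efficiency variation), and finally divide by four 16S rRNA gene
loci per bacterial genome to get cell numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats_core import TestResult, wilcoxon_rank_sum

__all__ = [
    "StandardCurve",
    "aggregate_cq",
    "fit_standard_curve",
    "raw_copies",
    "normalize_loads",
    "compare_loads",
    "quantify",
    "DEFAULT_ELUTION_VOLUME_UL",
    "RRNA_LOCI_PER_CELL",
]

#: DNA extracts are eluted in 50 uL of sterile water, so copies/uL x 50
#: gives copies per gut.
DEFAULT_ELUTION_VOLUME_UL = 50.0

#: Mean number of 16S rRNA gene loci per genome across honey bee gut
#: symbionts; copy numbers are divided by this to estimate cells.
RRNA_LOCI_PER_CELL = 4.0


@dataclass
class StandardCurve:
    """Linear calibration of Cq against log10 template copies.

    ``slope`` is in cycles per decade (negative for a valid dilution
    series); the amplification efficiency is E = 10^(-1/slope), with E = 2
    meaning perfect doubling each cycle.
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    gene: str = ""

    def __post_init__(self):
        if not (1.0 < self.efficiency <= 2.2):
            warnings.warn(
                f"standard curve for {self.gene or 'unknown gene'}: efficiency "
                f"{self.efficiency:.3f} outside the (1, 2.2] sanity band"
            )


def aggregate_cq(replicates, spread_warn: float = 1.0) -> float:
    """Mean Cq over technical replicates; warns when the spread exceeds one cycle."""
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        raise ValueError("no finite Cq replicate available")
    if reps.size > 1 and np.ptp(reps) > spread_warn:
        warnings.warn(f"Cq replicate spread {np.ptp(reps):.2f} cycles exceeds {spread_warn}")
    return float(reps.mean())


def fit_standard_curve(copies, cq, gene: str = "") -> StandardCurve:
    """Least-squares fit of Cq on log10(copies) over a plasmid dilution series."""
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if np.any(copies <= 0):
        raise ValueError("template copy numbers must be positive")
    if np.unique(copies).size < 3:
        raise ValueError("need at least 3 distinct copy levels to fit a standard curve")
    res = sps.linregress(np.log10(copies), cq)
    if res.slope >= 0:
        raise ValueError(f"standard curve for {gene or 'gene'} has non-negative slope "
                         f"({res.slope:.3f}); dilution series looks inverted")
    eff = 10.0 ** (-1.0 / res.slope)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(eff),
        r_squared=float(res.rvalue**2),
        gene=gene,
    )


def raw_copies(curve: StandardCurve, cq) -> np.ndarray | float:
    """Invert the standard curve: n = E^(intercept - Cq) template copies per uL."""
    cq = np.asarray(cq, dtype=float)
    n = curve.efficiency ** (curve.intercept - cq)
    return float(n) if n.ndim == 0 else n


def cq_from_copies(curve: StandardCurve, copies) -> np.ndarray | float:
    """Forward relation Cq = intercept - log_E(copies); exact inverse of raw_copies."""
    copies = np.asarray(copies, dtype=float)
    cq = curve.intercept - np.log(copies) / np.log(curve.efficiency)
    return float(cq) if cq.ndim == 0 else cq


def normalize_loads(
    raw_loads: pd.DataFrame,
    elution_volume: float = DEFAULT_ELUTION_VOLUME_UL,
    loci_per_cell: float = RRNA_LOCI_PER_CELL,
) -> pd.DataFrame:
    """Actin-normalized 16S copies and cell numbers per gut.

    Parameters
    ----------
    raw_loads : DataFrame
        Indexed by sample, with columns ``raw_16S`` and ``raw_actin`` holding
        copies per uL of extract.
    elution_volume : float
        Elution volume in uL; converts copies/uL to copies per gut.
    loci_per_cell : float
        16S rRNA loci per bacterial cell; divides normalized copies to cells.

    Returns
    -------
    DataFrame with columns raw_16S, raw_actin, copies_16S_per_gut,
    copies_actin_per_gut, normalized_16S, cells_per_gut. Samples with
    missing or non-positive actin are excluded (logged via warning).
    """
    required = {"raw_16S", "raw_actin"}
    if not required.issubset(raw_loads.columns):
        raise ValueError(f"raw_loads must have columns {sorted(required)}")
    df = raw_loads.copy()
    bad = ~(df["raw_actin"] > 0) | ~np.isfinite(df["raw_actin"]) | ~np.isfinite(df["raw_16S"])
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} sample(s) with missing/zero actin: "
            f"{list(df.index[bad])[:5]}"
        )
        df = df[~bad]
    df["copies_16S_per_gut"] = df["raw_16S"] * elution_volume
    df["copies_actin_per_gut"] = df["raw_actin"] * elution_volume
    median_actin = df["copies_actin_per_gut"].median()
    df["normalized_16S"] = (
        df["copies_16S_per_gut"] / df["copies_actin_per_gut"] * median_actin
    )
    df["cells_per_gut"] = df["normalized_16S"] / loci_per_cell
    return df


def compare_loads(cells_per_gut: pd.Series, colonization: pd.Series,
                  reference: str = "CL", other: str = "MD") -> TestResult:
    """Wilcoxon rank-sum comparison of gut loads between colonization strata.

    Returns the rank-sum result with ``extra['median_ratio']`` holding the
    ratio of stratum medians (reference / other).
    """
    cl = cells_per_gut[colonization == reference].to_numpy(dtype=float)
    md = cells_per_gut[colonization == other].to_numpy(dtype=float)
    if cl.size == 0 or md.size == 0:
        raise ValueError("both colonization strata must be nonempty")
    res = wilcoxon_rank_sum(cl, md)
    res.extra["median_ratio"] = float(np.median(cl) / np.median(md))
    return res


def quantify(
    cq_table: pd.DataFrame,
    dilution_series: pd.DataFrame,
    elution_volume: float = DEFAULT_ELUTION_VOLUME_UL,
    loci_per_cell: float = RRNA_LOCI_PER_CELL,
) -> tuple[pd.DataFrame, dict]:
    """Full chain from replicate Cq values to cells per gut.

    ``cq_table`` has columns (sample, gene, replicate, cq) with gene in
    {16S, actin}; ``dilution_series`` has columns (gene, copies, cq).
    Returns the normalized load table (see :func:`normalize_loads`) and the
    fitted standard curves keyed by gene.
    """
    curves = {
        gene: fit_standard_curve(sub["copies"], sub["cq"], gene=gene)
        for gene, sub in dilution_series.groupby("gene")
    }
    records = {}
    for (sample, gene), sub in cq_table.groupby(["sample", "gene"]):
        mean_cq = aggregate_cq(sub["cq"])
        records.setdefault(sample, {})[gene] = raw_copies(curves[gene], mean_cq)
    raw = pd.DataFrame.from_dict(records, orient="index").rename(
        columns={"16S": "raw_16S", "actin": "raw_actin"}
    )
    raw.index.name = "sample"
    if "raw_16S" not in raw or "raw_actin" not in raw:
        raise ValueError("cq_table must contain both '16S' and 'actin' genes")
    loads = normalize_loads(raw, elution_volume=elution_volume, loci_per_cell=loci_per_cell)
    return loads.sort_index(), curves
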