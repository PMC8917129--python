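"""Taxonomy-based ASV removal and reagent-contaminant identification.

Organellar and eukaryotic ASVs (mitochondria, chloroplast, Eukaryota) are
dropped on lineage strings. Reagent contaminants are then called from blank
extractions and negative controls with two complementary signals:

* prevalence — a contaminant is over-represented (presence/absence) in
  blanks relative to true samples; scored by a one-sided Fisher exact test;
* frequency — a contaminant enters at a roughly constant absolute level, so
  its *relative* abundance falls as total input DNA rises; scored by a
  one-sided Spearman test for negative correlation with log10 load.

An ASV is removed when either signal falls below the threshold ("either"
combination, default 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContaminantCall",
    "taxonomy_filter",
    "prevalence_method",
    "frequency_method",
    "combine_either",
    "ORGANELLE_TERMS",
    "DEFAULT_CONTAMINANT_THRESHOLD",
    "MIN_SAMPLES_FOR_FREQUENCY",
]

ORGANELLE_TERMS = ("mitochondria", "chloroplast", "eukaryota")
DEFAULT_CONTAMINANT_THRESHOLD = 0.1
#: below this many occupied true samples the frequency score is neutral 0.5
MIN_SAMPLES_FOR_FREQUENCY = 5


@dataclass
class ContaminantCall:
    asv: str
    prevalence_p: float
    frequency_score: float
    flagged_by: frozenset
    is_contaminant: bool


def taxonomy_filter(
    asv_counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Drop ASVs whose lineage names mitochondria, chloroplast or Eukaryota.

    ``asv_counts`` is samples x ASVs; ``taxonomy`` is indexed by ASV with
    rank columns (any string columns are searched, case-insensitively).
    ASVs missing from the taxonomy are retained with a warning.
    """
    missing = [a for a in asv_counts.columns if a not in taxonomy.index]
    if missing:
        warnings.warn(f"{len(missing)} ASV(s) missing from taxonomy; retained: {missing[:5]}")
    removed = []
    for asv in asv_counts.columns:
        if asv not in taxonomy.index:
            continue
        lineage = " ".join(str(v) for v in taxonomy.loc[asv].values).lower()
        if any(term in lineage for term in ORGANELLE_TERMS):
            removed.append(asv)
    return asv_counts.drop(columns=removed), removed


def prevalence_method(asv_counts: pd.DataFrame, is_blank: pd.Series) -> pd.Series:
    """Per-ASV one-sided Fisher exact p for over-representation in blanks.

    A 2x2 presence/absence table (blank vs true sample) is scored with the
    alternative that presence is more likely in blanks. ASVs absent
    everywhere get p = 1.
    """
    is_blank = is_blank.reindex(asv_counts.index)
    if is_blank.isna().any():
        raise ValueError("is_blank must cover every sample in the counts table")
    blanks = asv_counts.loc[is_blank.astype(bool)]
    trues = asv_counts.loc[~is_blank.astype(bool)]
    if len(blanks) == 0 or len(trues) == 0:
        raise ValueError("need at least one blank and one true sample")
    n_b, n_t = len(blanks), len(trues)
    out = {}
    pres_b = (blanks > 0).sum(axis=0)
    pres_t = (trues > 0).sum(axis=0)
    for asv in asv_counts.columns:
        b, t = int(pres_b[asv]), int(pres_t[asv])
        if b + t == 0:
            out[asv] = 1.0
            continue
        table = [[b, n_b - b], [t, n_t - t]]
        _, p = sps.fisher_exact(table, alternative="greater")
        out[asv] = float(p)
    return pd.Series(out, name="prevalence_p")


def frequency_method(
    asv_counts: pd.DataFrame,
    loads: pd.Series,
    min_samples: int = MIN_SAMPLES_FOR_FREQUENCY,
) -> pd.Series:
    """Per-ASV one-sided Spearman p for relative abundance falling with load.

    Computed over the true samples in which the ASV is present; ASVs present
    in fewer than ``min_samples`` samples, or with constant relative
    abundance, get the neutral score 0.5.
    """
    common = asv_counts.index.intersection(loads.index)
    counts = asv_counts.loc[common]
    loads = loads.loc[common].astype(float)
    totals = counts.sum(axis=1)
    ok = totals > 0
    counts, loads, totals = counts[ok], loads[ok], totals[ok]
    rel = counts.div(totals, axis=0)
    out = {}
    log_load = np.log10(loads)
    for asv in counts.columns:
        present = counts[asv] > 0
        if int(present.sum()) < min_samples:
            out[asv] = 0.5
            continue
        r = rel.loc[present, asv].to_numpy()
        ll = log_load[present].to_numpy()
        if np.ptp(r) == 0 or np.ptp(ll) == 0:
            out[asv] = 0.5
            continue
        res = sps.spearmanr(ll, r, alternative="less")
        out[asv] = float(res.pvalue)
    return pd.Series(out, name="frequency_score")


def combine_either(
    prevalence_p: pd.Series,
    frequency_score: pd.Series,
    threshold: float = DEFAULT_CONTAMINANT_THRESHOLD,
) -> pd.DataFrame:
    """OR-combine the two contaminant signals at a strict threshold.

    An ASV is a contaminant iff prevalence_p < threshold OR
    frequency_score < threshold (scores exactly at the threshold are not
    flagged). Returns one row per ASV with the individual scores, which
    signal(s) fired, and the final call.
    """
    asvs = prevalence_p.index.union(frequency_score.index)
    rows = []
    for asv in asvs:
        pp = float(prevalence_p.get(asv, 1.0))
        fs = float(frequency_score.get(asv, 0.5))
        flagged = set()
        if pp < threshold:
            flagged.add("prevalence")
        if fs < threshold:
            flagged.add("frequency")
        rows.append(
            {
                "asv": asv,
                "prevalence_p": pp,
                "frequency_score": fs,
                "flagged_by": ";".join(sorted(flagged)),
                "is_contaminant": bool(flagged),
            }
        )
    return pd.DataFrame(rows).set_index("asv")


def identify_contaminants(
    asv_counts: pd.DataFrame,
    is_blank: pd.Series,
    loads: pd.Series,
    strata: pd.Series | None = None,
    threshold: float = DEFAULT_CONTAMINANT_THRESHOLD,
) -> pd.DataFrame:
    """Prevalence + frequency contaminant calls with the "either" combination.

    When ``strata`` (e.g. colonization status per true sample) is given, the
    frequency score is computed within each stratum and the *largest*
    within-stratum p is kept: a reagent contaminant enters at a constant
    level regardless of the gut community, so its relative abundance must
    fall with load in every stratum. This guards against the confound where
    a taxon typical of the low-load stratum mimics a contaminant when
    strata are pooled.
    """
    prev = prevalence_method(asv_counts, is_blank)
    true_counts = asv_counts.loc[~is_blank.reindex(asv_counts.index).astype(bool)]
    if strata is None:
        freq = frequency_method(true_counts, loads)
    else:
        strata = strata.reindex(true_counts.index)
        scores = []
        for s in sorted(strata.dropna().unique(), key=str):
            sub = true_counts.loc[strata == s]
            scores.append(frequency_method(sub, loads))
        freq = pd.concat(scores, axis=1).max(axis=1)
        freq.name = "frequency_score"
    return combine_either(prev, freq, threshold)


def remove_contaminants(
    asv_counts: pd.DataFrame,
    calls: pd.DataFrame,
    is_blank: pd.Series | None = None,
) -> pd.DataFrame:
    """Drop contaminant ASV columns, and blank rows when flags are given."""
    contaminants = calls.index[calls["is_contaminant"]]
    out = asv_counts.drop(columns=[c for c in contaminants if c in asv_counts.columns])
    if is_blank is not None:
        out = out.loc[~is_blank.reindex(out.index).astype(bool)]
    return out
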