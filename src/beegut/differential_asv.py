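"""Per-ASV permutation ANOVA on absolute abundances.

For each ASV within each colonization stratum, pesticide-treatment effects
on estimated 16S copy numbers are tested by randomizing the copy numbers
across samples (10,000 times by default) and recomputing, for every
randomized dataset, the omnibus F and the per-treatment t statistics of a
linear model with Control as the reference level. The omnibus p-value is
the proportion of randomized F values that are greater than or equal to the
observed one; per-treatment p-values are computed analogously on |t|
(two-sided) or on t (the one-sided "ge" variant). Tukey HSD with Bonferroni
adjustment provides pairwise detail, and significant ASV sets from the two
strata are partitioned into a Venn layout.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core

__all__ = [
    "AsvTestRecord",
    "VennPartition",
    "permutation_anova_asv",
    "run_all_asvs",
    "posthoc_vs_control",
    "venn_partition",
    "DEFAULT_N_PERMUTATIONS",
    "DEFAULT_PREVALENCE_FLOOR",
]

DEFAULT_N_PERMUTATIONS = 10_000
#: ASVs present in fewer than this fraction of a stratum's samples are not tested
DEFAULT_PREVALENCE_FLOOR = 0.25


@dataclass
class AsvTestRecord:
    asv: str
    stratum: str
    statistic_f: float
    p_permutation: float
    n_permutations: int
    seed: int | None
    significant: bool
    t_vs_control: dict = field(default_factory=dict)   # treatment -> t
    p_t_vs_control: dict = field(default_factory=dict) # treatment -> permutation p
    posthoc: pd.DataFrame | None = None
    degenerate: bool = False


@dataclass
class VennPartition:
    set_a: frozenset
    set_b: frozenset
    label_a: str = "CL"
    label_b: str = "MD"

    @property
    def shared(self) -> frozenset:
        return self.set_a & self.set_b

    @property
    def only_a(self) -> frozenset:
        return self.set_a - self.set_b

    @property
    def only_b(self) -> frozenset:
        return self.set_b - self.set_a

    @property
    def counts(self) -> dict:
        return {
            f"{self.label_a}_only": len(self.only_a),
            f"{self.label_b}_only": len(self.only_b),
            "shared": len(self.shared),
            "total": len(self.set_a | self.set_b),
        }


def _design(treatments, control):
    treatments = np.asarray(treatments)
    levels = sorted(pd.unique(treatments).tolist(), key=str)
    if control not in levels:
        raise ValueError(f"control level {control!r} absent from treatments")
    noncontrol = [t for t in levels if t != control]
    onehot = np.stack([(treatments == t).astype(float) for t in levels], axis=1)
    sizes = onehot.sum(axis=0)
    return levels, noncontrol, onehot, sizes


def _f_and_t(perm_values, onehot, sizes, control_idx, noncontrol_idx):
    """Vectorized omnibus F and vs-control t for a batch of value vectors.

    ``perm_values`` is (batch, n); returns (F: (batch,), t: (batch, k-1)).
    """
    n = perm_values.shape[1]
    k = onehot.shape[1]
    sums = perm_values @ onehot                        # (batch, k)
    means = sums / sizes
    total = perm_values.sum(axis=1, keepdims=True)
    ss_total = (perm_values**2).sum(axis=1) - (total[:, 0] ** 2) / n
    ss_between = (sums**2 / sizes).sum(axis=1) - (total[:, 0] ** 2) / n
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / np.maximum(ss_within / df_w, 1e-300)
        ms_w = ss_within / df_w
        se = np.sqrt(
            ms_w[:, None]
            * (1.0 / sizes[noncontrol_idx] + 1.0 / sizes[control_idx])
        )
        t = (means[:, noncontrol_idx] - means[:, [control_idx]]) / np.maximum(se, 1e-300)
    return f, t


def permutation_anova_asv(
    abundances,
    treatments,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    control: str = "Control",
    alpha: float = 0.05,
    tail: str = "two-sided",
    permutations: str = "sampled",
    asv: str = "",
    stratum: str = "",
) -> AsvTestRecord:
    """Permutation ANOVA for one ASV across pesticide treatments.

    ``tail='two-sided'`` compares |t| of each randomization against the
    observed |t|; ``tail='ge'`` keeps the raw one-sided >= rule on t.
    ``permutations='exhaustive'`` enumerates all value arrangements (only
    sensible for very small n). The omnibus p always uses F >= F_obs.
    """
    values = np.asarray(abundances, dtype=float)
    treatments = np.asarray(treatments)
    if values.shape != treatments.shape:
        raise ValueError("abundances and treatments must align")
    levels, noncontrol, onehot, sizes = _design(treatments, control)
    if len(levels) < 2:
        raise ValueError("need at least 2 treatment levels")
    if (sizes < 3).any():
        raise ValueError("need at least 3 samples per treatment")
    control_idx = levels.index(control)
    noncontrol_idx = [levels.index(t) for t in noncontrol]
    if np.ptp(values) == 0:
        return AsvTestRecord(asv, stratum, 0.0, 1.0, 0, seed, False,
                             degenerate=True)
    f_obs, t_obs = _f_and_t(values[None, :], onehot, sizes, control_idx, noncontrol_idx)
    f_obs, t_obs = float(f_obs[0]), t_obs[0]
    if permutations == "exhaustive":
        perms = np.array(sorted(set(itertools.permutations(values.tolist()))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((n_permutations, values.size))
        for i in range(n_permutations):
            perms[i] = rng.permutation(values)
    f_perm, t_perm = _f_and_t(perms, onehot, sizes, control_idx, noncontrol_idx)
    # tolerant >=: value arrangements sharing the observed partition must
    # count as ties despite float summation-order noise
    def _ge(a, b):
        return a >= b - 1e-9 * np.abs(b)

    p_f = float(_ge(f_perm, f_obs).mean())
    if tail == "two-sided":
        p_t = _ge(np.abs(t_perm), np.abs(t_obs)).mean(axis=0)
    elif tail == "ge":
        p_t = _ge(t_perm, t_obs).mean(axis=0)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return AsvTestRecord(
        asv=asv,
        stratum=stratum,
        statistic_f=f_obs,
        p_permutation=p_f,
        n_permutations=int(perms.shape[0]),
        seed=seed,
        significant=bool(p_f < alpha),
        t_vs_control=dict(zip(noncontrol, t_obs.tolist())),
        p_t_vs_control=dict(zip(noncontrol, np.asarray(p_t).tolist())),
    )


def posthoc_vs_control(abundances, treatments, control: str = "Control") -> pd.DataFrame:
    """Tukey HSD over all treatment pairs, Bonferroni-adjusted.

    Returns the full pairwise table with an ``is_control_contrast`` flag on
    the rows comparing a treatment against the control level.
    """
    table = stats_core.tukey_hsd(abundances, treatments)
    table = table.copy()
    table["adjusted_p"] = stats_core.adjust_p(table["raw_p"].to_numpy(), "bonferroni")
    table["adjust_method"] = "tukey+bonferroni"
    table["is_control_contrast"] = (table["group_a"] == control) | (
        table["group_b"] == control
    )
    return table


def _derive_seed(master_seed: int | None, asv: str, stratum: str) -> int:
    base = 0 if master_seed is None else int(master_seed)
    h = zlib.crc32(f"{stratum}:{asv}".encode())
    return (base * 1_000_003 + h) % (2**31 - 1)


def run_all_asvs(
    abs_table: pd.DataFrame,
    metadata: pd.DataFrame,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    master_seed: int | None = 0,
    prevalence_floor: float = DEFAULT_PREVALENCE_FLOOR,
    control: str = "Control",
    alpha: float = 0.05,
    tail: str = "two-sided",
    strata: tuple = ("CL", "MD"),
) -> dict[str, list[AsvTestRecord]]:
    """Permutation ANOVA per ASV, separately within each colonization stratum.

    Only ASVs present in at least ``prevalence_floor`` of the stratum's
    samples are tested; per-ASV seeds are derived deterministically from the
    master seed and the ASV/stratum identity, so results do not depend on
    column order. Significant records also carry the Tukey+Bonferroni
    posthoc table.
    """
    results: dict[str, list[AsvTestRecord]] = {}
    for stratum in strata:
        samples = metadata.index[metadata["colonization"] == stratum]
        # canonical sample order so results do not depend on input row order
        samples = sorted(s for s in samples if s in abs_table.index)
        if not samples:
            raise ValueError(f"no samples in stratum {stratum!r}")
        sub = abs_table.loc[samples]
        treatments = metadata.loc[samples, "pesticide"].to_numpy()
        records = []
        for asv in sorted(sub.columns):
            vals = sub[asv].to_numpy(dtype=float)
            if (vals > 0).mean() < prevalence_floor:
                continue
            rec = permutation_anova_asv(
                vals,
                treatments,
                n_permutations=n_permutations,
                seed=_derive_seed(master_seed, asv, stratum),
                control=control,
                alpha=alpha,
                tail=tail,
                asv=asv,
                stratum=stratum,
            )
            if rec.significant and not rec.degenerate:
                rec.posthoc = posthoc_vs_control(vals, treatments, control=control)
            records.append(rec)
        results[stratum] = records
    return results


def venn_partition(sig_a, sig_b, label_a: str = "CL", label_b: str = "MD") -> VennPartition:
    """Partition two significant-ASV sets into only-A / only-B / shared."""
    return VennPartition(frozenset(sig_a), frozenset(sig_b), label_a, label_b)


def records_to_frame(results: dict[str, list[AsvTestRecord]]) -> pd.DataFrame:
    rows = []
    for stratum, records in results.items():
        for r in records:
            rows.append(
                {
                    "asv": r.asv,
                    "stratum": stratum,
                    "F": r.statistic_f,
                    "p_perm": r.p_permutation,
                    "n_permutations": r.n_permutations,
                    "significant": r.significant,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)
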