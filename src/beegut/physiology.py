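"""Physiological-marker statistics and the control-normalized cluster view.

Five enzymatic markers (GST, G6PDH, LDH in head/abdomen/midgut; ALP and POx
in the midgut only — 11 tissue x marker combinations) are compared across
pesticide treatments within each colonization stratum. The test route is
chosen from the residual distribution: ANOVA + Tukey HSD when residuals
pass a Shapiro-Wilk check, Kruskal-Wallis + Dunn (Benjamini-Hochberg)
otherwise. Treatment means are then normalized to the colonized control
(CL.Control) as a rate of variation, clustered with UPGMA on Euclidean
distances, and rendered as a green-black-red heatmap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .stats_core import TestResult

__all__ = [
    "VALID_COMBINATIONS",
    "Dendrogram",
    "marker_treatment_tests",
    "colonization_contrast",
    "marker_matrix",
    "control_normalize",
    "upgma_cluster",
    "render_heatmap",
]

TISSUES = ("head", "abdomen", "midgut")
MARKERS = ("GST", "G6PDH", "LDH", "ALP", "POx")
#: ALP and POx are assayed in the midgut only
VALID_COMBINATIONS = tuple(
    (t, m)
    for t in TISSUES
    for m in MARKERS
    if m in ("GST", "G6PDH", "LDH") or t == "midgut"
)


@dataclass
class Dendrogram:
    """UPGMA merge tree over labeled items.

    ``merges`` is a list of (left, right, height, new_label) tuples where
    heights are ultrametric node heights (half the average inter-cluster
    distance at the merge) and are non-decreasing.
    """

    labels: list
    merges: list = field(default_factory=list)

    @property
    def heights(self):
        return [m[2] for m in self.merges]

    def leaf_order(self) -> list:
        if not self.merges:
            return list(self.labels)
        order = {}
        for left, right, _, new in self.merges:
            order[new] = order.get(left, [left]) + order.get(right, [right])
        return order[self.merges[-1][3]]

    def to_newick(self) -> str:
        if not self.merges:
            return ";".join(self.labels) + ";"
        height = {lab: 0.0 for lab in self.labels}
        newick = {lab: lab for lab in self.labels}
        for left, right, h, new in self.merges:
            bl = h - height[left]
            br = h - height[right]
            newick[new] = f"({newick[left]}:{bl:g},{newick[right]}:{br:g})"
            height[new] = h
        return newick[self.merges[-1][3]] + ";"


def _residuals(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    resid = values.copy()
    for g in pd.unique(groups):
        mask = groups == g
        resid[mask] -= values[mask].mean()
    return resid


def _route_and_test(values, groups, alpha=0.05):
    route = stats_core.normality_route(_residuals(values, groups), alpha=alpha)
    if route == "parametric":
        omnibus = stats_core.anova_oneway(values, groups)
        posthoc = stats_core.tukey_hsd(values, groups)
    else:
        omnibus = stats_core.kruskal_wallis(values, groups)
        posthoc = stats_core.dunn_test(values, groups, adjust="benjamini-hochberg")
    return route, omnibus, posthoc


def marker_treatment_tests(
    enzyme_table: pd.DataFrame, alpha: float = 0.05, strata: tuple = ("CL", "MD")
) -> pd.DataFrame:
    """Omnibus + posthoc treatment tests per (tissue, marker, stratum).

    ``enzyme_table`` columns: tissue, marker, colonization, treatment,
    replicate, activity. Returns one row per combination with the route,
    omnibus statistic/p, and the posthoc table attached in the ``posthoc``
    column (a DataFrame per row).
    """
    required = {"tissue", "marker", "colonization", "treatment", "activity"}
    if not required.issubset(enzyme_table.columns):
        raise ValueError(f"enzyme table must have columns {sorted(required)}")
    rows = []
    for (tissue, marker), sub_tm in enzyme_table.groupby(["tissue", "marker"]):
        for stratum in strata:
            sub = sub_tm[sub_tm["colonization"] == stratum]
            if sub.empty:
                continue
            counts = sub.groupby("treatment")["activity"].count()
            if (counts < 3).any():
                short = counts.index[counts < 3].tolist()
                raise ValueError(
                    f"{tissue}/{marker}/{stratum}: treatment level(s) {short} "
                    "have fewer than 3 replicates"
                )
            route, omnibus, posthoc = _route_and_test(
                sub["activity"].to_numpy(), sub["treatment"].to_numpy(), alpha
            )
            rows.append(
                {
                    "tissue": tissue,
                    "marker": marker,
                    "stratum": stratum,
                    "route": route,
                    "method": omnibus.method,
                    "statistic": omnibus.statistic,
                    "p_value": omnibus.p_value,
                    "degenerate": omnibus.degenerate,
                    "posthoc": posthoc,
                }
            )
    return pd.DataFrame(rows)


def colonization_contrast(enzyme_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """CL-vs-MD comparison per (tissue, marker, pesticide treatment).

    Uses the same normality routing as the omnibus tests: pooled-variance t
    (via the k=2 ANOVA identity t = sign x sqrt(F)) when residuals look
    normal, Wilcoxon rank-sum otherwise.
    """
    rows = []
    for (tissue, marker, treatment), sub in enzyme_table.groupby(
        ["tissue", "marker", "treatment"]
    ):
        strata = set(sub["colonization"])
        if not {"CL", "MD"}.issubset(strata):
            continue
        cl = sub.loc[sub["colonization"] == "CL", "activity"].to_numpy(dtype=float)
        md = sub.loc[sub["colonization"] == "MD", "activity"].to_numpy(dtype=float)
        values = np.concatenate([cl, md])
        groups = np.array(["CL"] * cl.size + ["MD"] * md.size)
        route = stats_core.normality_route(_residuals(values, groups), alpha=alpha)
        estimate = float(cl.mean() - md.mean())
        if route == "parametric":
            res = stats_core.anova_oneway(values, groups)
            t = math.copysign(math.sqrt(res.statistic), estimate) if np.isfinite(
                res.statistic
            ) else math.inf * np.sign(estimate)
            result = TestResult(t, res.p_value, res.df, "pooled_t",
                                degenerate=res.degenerate)
        else:
            result = stats_core.wilcoxon_rank_sum(cl, md)
        rows.append(
            {
                "tissue": tissue,
                "marker": marker,
                "treatment": treatment,
                "route": route,
                "method": result.method,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "estimate_CL_minus_MD": estimate,
            }
        )
    return pd.DataFrame(rows)


def marker_matrix(enzyme_table: pd.DataFrame) -> pd.DataFrame:
    """Mean activity per (tissue, marker) row and colonization.treatment column."""
    df = enzyme_table.copy()
    df["row"] = df["tissue"] + "." + df["marker"]
    df["column"] = df["colonization"] + "." + df["treatment"]
    mat = df.pivot_table(index="row", columns="column", values="activity", aggfunc="mean")
    if mat.isna().any().any():
        missing = [
            (r, c) for r in mat.index for c in mat.columns if pd.isna(mat.loc[r, c])
        ]
        raise ValueError(f"missing marker cells after aggregation: {missing[:5]}")
    return mat


def control_normalize(
    matrix: pd.DataFrame, control_column: str = "CL.Control", mode: str = "relative"
) -> pd.DataFrame:
    """Normalize each row to its value in the colonized-control column.

    ``relative`` (default): (treatment - control) / control, so the control
    column maps to 0 and sign encodes direction of change. ``ratio``:
    treatment / control.
    """
    if control_column not in matrix.columns:
        raise ValueError(f"control column {control_column!r} absent")
    control = matrix[control_column]
    zero = control == 0
    if zero.any():
        raise ValueError(f"zero control mean in row(s): {list(matrix.index[zero])}")
    if mode == "relative":
        return matrix.sub(control, axis=0).div(control, axis=0)
    if mode == "ratio":
        return matrix.div(control, axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def upgma_cluster(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Average-linkage (UPGMA) clustering on Euclidean distances.

    Ties are broken by lexicographic order of the merged labels, making the
    result independent of input row order. Node heights are half the
    average inter-cluster distance at each merge (ultrametric convention).
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    labels = [str(l) for l in matrix.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    x = matrix.to_numpy(dtype=float)
    # average-linkage distances between current clusters
    dist = {
        frozenset((a, b)): float(np.linalg.norm(x[i] - x[j]))
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    sizes = {lab: 1 for lab in labels}
    active = sorted(labels)
    dendro = Dendrogram(labels=sorted(labels))
    merges = []
    while len(active) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], a, b)
                for i, a in enumerate(active)
                for b in active[i + 1:]
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d, a, b = best
        new = f"({a}+{b})"
        for c in active:
            if c in (a, b):
                continue
            da = dist.pop(frozenset((a, c)))
            db = dist.pop(frozenset((b, c)))
            dist[frozenset((new, c))] = (sizes[a] * da + sizes[b] * db) / (
                sizes[a] + sizes[b]
            )
        dist.pop(frozenset((a, b)))
        sizes[new] = sizes[a] + sizes[b]
        active = sorted([c for c in active if c not in (a, b)] + [new])
        merges.append((a, b, d / 2.0, new))
    dendro.merges = merges
    return dendro


def render_heatmap(
    normalized: pd.DataFrame,
    path,
    row_dendrogram: Dendrogram | None = None,
    col_dendrogram: Dendrogram | None = None,
    vlim: float | None = None,
):
    """Green-black-red heatmap of the control-normalized matrix.

    Zero (no change versus the colonized control) is black; decreases are
    green, increases red. Rows/columns follow the dendrogram leaf orders
    when given. Returns the leaf orders actually used.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    rows = row_dendrogram.leaf_order() if row_dendrogram else list(normalized.index)
    cols = col_dendrogram.leaf_order() if col_dendrogram else list(normalized.columns)
    data = normalized.loc[rows, cols].to_numpy(dtype=float)
    if vlim is None:
        vlim = max(np.abs(data).max(), 1e-12)
    cmap = LinearSegmentedColormap.from_list("gbr", ["#00b200", "#000000", "#d40000"])
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(cols)), max(4, 0.4 * len(rows))))
    im = ax.imshow(data, cmap=cmap, vmin=-vlim, vmax=vlim, aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=90)
    ax.set_yticks(range(len(rows)), rows)
    fig.colorbar(im, ax=ax, label="rate of variation vs CL.Control")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return {"row_order": rows, "col_order": cols}
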