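"""Community dissimilarities, ordination and permutational multivariate tests.

Everything here is computed from first principles on labeled abundance
tables (samples x ASVs):

* Bray-Curtis dissimilarity and weighted/unweighted UniFrac (phylogeny from
  a Newick tree, parsed with dendropy);
* principal coordinate analysis by Gower double-centering, with negative
  eigenvalues reported rather than silently dropped;
* PERMANOVA (pseudo-F directly from the distance matrix via the Gower
  identity), ANOSIM (rank-based R), and PERMDISP (Anderson's test of
  multivariate dispersion homogeneity), each with seeded label-permutation
  p-values and an exhaustive-enumeration mode for small designs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "permanova",
    "anosim",
    "permdisp",
]


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample labels."""

    data: np.ndarray
    ids: list
    metric: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("negative dissimilarities")
        np.fill_diagonal(self.data, 0.0)
        self.data[self.data < 0] = 0.0

    def __len__(self):
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def filter(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(self.data[np.ix_(idx, idx)], list(ids), self.metric)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix."""

    eigenvalues: np.ndarray          # all eigenvalues, descending
    coordinates: pd.DataFrame        # samples x positive axes
    proportion_explained: np.ndarray # per positive axis, over positive eigenvalues


@dataclass
class PermutationTestResult:
    """Observed statistic plus its seeded permutation null summary."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    effect_size: float | None = None   # R^2 for PERMANOVA
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------- distances

def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i) over ASVs."""
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    totals = x.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size >= 2:
        names = [table.index[i] for i in zero]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {names}")
    from scipy.spatial.distance import squareform, pdist

    num = squareform(pdist(x, metric="cityblock"))
    den = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(table.index), "braycurtis")


def _tree_membership(tree_or_newick, asv_ids):
    """Per-branch leaf membership over the table's ASVs, plus branch lengths.

    Returns (M, lengths): M is branches x ASVs boolean, lengths the branch
    lengths. The root edge is excluded (it subtends every leaf and cancels
    in all UniFrac terms anyway only for weighted; we keep edges with a
    parent only, the standard convention).
    """
    if isinstance(tree_or_newick, dendropy.Tree):
        tree = tree_or_newick
    else:
        tree = dendropy.Tree.get(data=str(tree_or_newick), schema="newick")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [a for a in asv_ids if a not in leaf_labels]
    if missing:
        raise ValueError(f"ASV(s) missing from the tree: {missing[:5]}")
    col = {a: i for i, a in enumerate(asv_ids)}
    rows, lengths = [], []
    member = {}
    for node in tree.postorder_node_iter():
        vec = np.zeros(len(asv_ids), dtype=bool)
        if node.is_leaf():
            j = col.get(node.taxon.label)
            if j is not None:
                vec[j] = True
        else:
            for child in node.child_nodes():
                vec |= member[id(child)]
        member[id(node)] = vec
        if node.parent_node is not None:
            rows.append(vec)
            lengths.append(node.edge.length if node.edge.length is not None else 0.0)
    return np.array(rows, dtype=bool), np.array(lengths, dtype=float)


def unweighted_unifrac(table: pd.DataFrame, tree) -> DistanceMatrix:
    """Fraction of branch length unique to either sample over their union.

    Presence/absence only: a branch counts for a sample when any leaf in its
    subtree is present in that sample.
    """
    M, lengths = _tree_membership(tree, list(table.columns))
    pres = table.to_numpy(dtype=float) > 0
    a = pres @ M.T                          # samples x branches occupancy counts
    occ = a > 0
    weighted = occ * lengths                # branch length carried per sample
    s = weighted.sum(axis=1)
    shared = occ.astype(float) * lengths @ occ.T.astype(float)  # sum len over both-present
    den = s[:, None] + s[None, :] - shared
    num = s[:, None] + s[None, :] - 2.0 * shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(d, list(table.index), "unweighted_unifrac")


def weighted_unifrac(table: pd.DataFrame, tree, normalized: bool = True) -> DistanceMatrix:
    """Sum over branches of length x |p_A - p_B| of subtree relative abundance.

    With ``normalized`` the raw distance is divided by
    sum(length x (p_A + p_B)), bounding it to [0, 1].
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = [table.index[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"zero-abundance sample(s): {bad}")
    M, lengths = _tree_membership(tree, list(table.columns))
    p = (x / totals[:, None]) @ M.T          # samples x branches subtree proportions
    n = len(table)
    d = np.zeros((n, n))
    t = (p * lengths).sum(axis=1)
    for i in range(n):
        diff = np.abs(p[i] - p[i + 1:])      # (n-i-1) x branches
        raw = diff @ lengths
        if normalized:
            den = t[i] + t[i + 1:]
            raw = np.where(den > 0, raw / np.maximum(den, 1e-300), 0.0)
        d[i, i + 1:] = raw
        d[i + 1:, i] = raw
    return DistanceMatrix(
        d, list(table.index),
        "weighted_unifrac_normalized" if normalized else "weighted_unifrac",
    )


# --------------------------------------------------------------- ordination

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _full_eigen(dm: DistanceMatrix):
    b = _gower_center(dm.data)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering.

    Coordinates are built from strictly positive eigenvalues only; negative
    eigenvalues (non-Euclidean input) are reported in ``eigenvalues``.
    """
    if len(dm) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    vals, vecs = _full_eigen(dm)
    pos = vals > eps * max(vals.max(), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(eigenvalues=vals, coordinates=frame, proportion_explained=prop)


# ----------------------------------------------------------- permutation tests

def _codes(grouping, ids):
    g = pd.Series(grouping)
    if not set(ids).issubset(set(g.index)) and len(g) == len(ids):
        g.index = ids
    g = g.loc[ids]
    labels = sorted(g.unique().tolist(), key=str)
    lut = {lab: i for i, lab in enumerate(labels)}
    return np.array([lut[v] for v in g]), labels


def _distinct_label_arrangements(codes):
    """All distinct arrangements of a label multiset (exhaustive mode)."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, k: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.where(codes == g)[0]
        if idx.size:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        return (math.inf if ss_between > 0 else 0.0), ss_between, ss_total
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between, ss_total


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 999,
              seed: int | None = None, permutations: str = "sampled"
              ) -> PermutationTestResult:
    """One-way PERMANOVA (ADONIS) on a distance matrix.

    Pseudo-F is computed directly from sums of squared distances via the
    Gower identity; R^2 = SS_between / SS_total. The p-value is the
    proportion of label arrangements (including the observed one among the
    sampled set) whose F is >= the observed F. ``permutations='exhaustive'``
    enumerates every distinct arrangement instead of sampling.
    """
    codes, labels = _codes(grouping, dm.ids)
    k = len(labels)
    counts = np.bincount(codes, minlength=k)
    if k < 2 or (counts < 2).any():
        raise ValueError("PERMANOVA needs >=2 groups each with >=2 samples")
    if permutations == "sampled" and n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    d2 = dm.data**2
    f_obs, ss_b, ss_t = _permanova_f(d2, codes, k)
    r2 = ss_b / ss_t if ss_t > 0 else 0.0
    if ss_t <= 0:
        return PermutationTestResult("permanova", 0.0, 1.0, 0, seed, 0.0,
                                     {"degenerate": True})
    if permutations == "exhaustive":
        fs = np.array([_permanova_f(d2, perm, k)[0]
                       for perm in _distinct_label_arrangements(codes)])
        p = float((fs >= f_obs).sum() / fs.size)
        n_used = fs.size
    else:
        rng = np.random.default_rng(seed)
        count = 1  # observed arrangement counts as one
        for _ in range(n_permutations):
            f_p, _, _ = _permanova_f(d2, rng.permutation(codes), k)
            count += f_p >= f_obs
        p = count / (n_permutations + 1)
        n_used = n_permutations
    return PermutationTestResult("permanova", float(f_obs), float(p), int(n_used),
                                 seed, float(r2))


def _anosim_r(rank_condensed, same_mask, m):
    rw = rank_condensed[same_mask].mean()
    rb = rank_condensed[~same_mask].mean()
    return (rb - rw) / (m / 2.0)


def anosim(dm: DistanceMatrix, grouping, n_permutations: int = 999,
           seed: int | None = None, permutations: str = "sampled"
           ) -> PermutationTestResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (M/2).

    Ranks are over all M = n(n-1)/2 pairwise distances (midranks for ties);
    R is in [-1, 1]. p-value conventions match :func:`permanova`.
    """
    codes, labels = _codes(grouping, dm.ids)
    k = len(labels)
    counts = np.bincount(codes, minlength=k)
    if k < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >=2 groups each with >=2 samples")
    n = len(dm)
    iu = np.triu_indices(n, 1)
    ranks = sps.rankdata(dm.condensed(), method="average")
    m = ranks.size
    same = codes[iu[0]] == codes[iu[1]]
    r_obs = _anosim_r(ranks, same, m)
    if permutations == "exhaustive":
        rs = []
        for perm in _distinct_label_arrangements(codes):
            s = perm[iu[0]] == perm[iu[1]]
            rs.append(_anosim_r(ranks, s, m))
        rs = np.array(rs)
        p = float((rs >= r_obs).sum() / rs.size)
        n_used = rs.size
    else:
        rng = np.random.default_rng(seed)
        count = 1
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            s = perm[iu[0]] == perm[iu[1]]
            count += _anosim_r(ranks, s, m) >= r_obs
        p = count / (n_permutations + 1)
        n_used = n_permutations
    return PermutationTestResult("anosim", float(r_obs), float(p), int(n_used), seed)


def _dispersion_distances(dm: DistanceMatrix, codes: np.ndarray, k: int) -> np.ndarray:
    """Per-sample distance to its group centroid in full PCoA space.

    Axes with negative eigenvalues contribute negatively (Anderson's
    correction); negative squared distances are clipped at zero with a
    warning.
    """
    vals, vecs = _full_eigen(dm)
    pos = vals > 1e-9 * max(abs(vals).max(), 1.0)
    neg = vals < -1e-9 * max(abs(vals).max(), 1.0)
    xr = vecs[:, pos] * np.sqrt(vals[pos])
    xi = vecs[:, neg] * np.sqrt(-vals[neg])
    n = len(dm)
    d2 = np.zeros(n)
    for g in range(k):
        idx = codes == g
        cr = xr[idx].mean(axis=0) if xr.size else np.zeros(0)
        ci = xi[idx].mean(axis=0) if xi.size else np.zeros(0)
        real = ((xr[idx] - cr) ** 2).sum(axis=1) if xr.size else 0.0
        imag = ((xi[idx] - ci) ** 2).sum(axis=1) if xi.size else 0.0
        d2[idx] = real - imag
    if (d2 < -1e-12).any():
        warnings.warn("negative squared centroid distances clipped at 0")
    return np.sqrt(np.clip(d2, 0.0, None))


def _anova_f_plain(values, codes, k):
    n = values.size
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(k):
        v = values[codes == g]
        ss_b += v.size * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    if ss_w <= 0:
        return math.inf if ss_b > 0 else 0.0
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def permdisp(dm: DistanceMatrix, grouping, n_permutations: int = 999,
             seed: int | None = None) -> PermutationTestResult:
    """PERMDISP (betadisper): homogeneity of multivariate dispersions.

    Distances to group centroids are computed in the full principal
    coordinate space (negative-eigenvalue axes subtract); the one-way F on
    those distances is referred to a null built by permuting the distances
    across samples.
    """
    codes, labels = _codes(grouping, dm.ids)
    k = len(labels)
    counts = np.bincount(codes, minlength=k)
    if k < 2 or (counts < 2).any():
        raise ValueError("PERMDISP needs >=2 groups each with >=2 samples")
    d = _dispersion_distances(dm, codes, k)
    if np.ptp(d) == 0:
        return PermutationTestResult("permdisp", 0.0, 1.0, 0, seed,
                                     extra={"degenerate": True})
    f_obs = _anova_f_plain(d, codes, k)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_permutations):
        count += _anova_f_plain(rng.permutation(d), codes, k) >= f_obs
    p = count / (n_permutations + 1)
    return PermutationTestResult("permdisp", float(f_obs), float(p),
                                 int(n_permutations), seed)
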