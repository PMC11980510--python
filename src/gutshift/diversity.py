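"""Alpha diversity, weighted UniFrac beta diversity and PERMANOVA.

The phylogenetic metrics are implemented from first principles on top of
a branch incidence table extracted from a rooted :class:`skbio.TreeNode`:
for every branch (edge above a non-root node) we record its length and
the set of leaf taxa descending through it.  Faith's phylogenetic
diversity is then the summed length of branches with at least one
present descendant (root-inclusive convention: every branch on a path
from the root to a present leaf counts), and weighted UniFrac is a
length-weighted L1 distance between the two samples' per-branch
descendant abundance fractions,

    d(u, v) = sum_b l_b |A_b - B_b| / sum_b l_b (A_b + B_b)

for the normalized variant, where ``A_b`` is the fraction of sample u's
counts descending through branch b.  PERMANOVA follows Anderson's
pseudo-F construction on squared distances with whole-label
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import TreeNode


# ---------------------------------------------------------------------------
# branch incidence


def branch_table(tree: TreeNode, taxa) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and leaf incidence for a rooted tree.

    Returns ``(lengths, incidence)`` where ``lengths`` has one entry per
    non-root node (its branch to the parent) and ``incidence[b, t]`` is
    True iff taxon ``t`` descends through branch ``b``.  Taxa must all be
    leaves of the tree; a missing taxon raises by name.
    """
    taxa = list(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    if len(index) != len(taxa):
        raise ValueError("duplicate taxon identifiers")
    leaf_names = {leaf.name for leaf in tree.tips()}
    missing = [t for t in taxa if t not in leaf_names]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:10]}")
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(taxa), dtype=bool)
            if node.name in index:
                mask[index[node.name]] = True
        else:
            mask = np.zeros(len(taxa), dtype=bool)
            for child in node.children:
                mask |= masks.pop(id(child))
        masks[id(node)] = mask
        if node.parent is not None:
            if node.length is None:
                raise ValueError(f"branch length missing above node {node.name!r}")
            lengths.append(float(node.length))
            rows.append(mask)
    return np.asarray(lengths), np.asarray(rows)


def _as_row(counts, taxa) -> tuple[np.ndarray, list]:
    if isinstance(counts, pd.Series):
        return counts.to_numpy(dtype=float), list(counts.index)
    if taxa is None:
        raise ValueError("taxa must be given when counts is not a pandas Series")
    return np.asarray(counts, dtype=float), list(taxa)


# ---------------------------------------------------------------------------
# alpha diversity


def shannon(counts) -> float:
    """Shannon entropy (natural log) of the positive count proportions."""
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Number of taxa with a positive count."""
    return int((np.asarray(counts, dtype=float) > 0).sum())


def faith_pd(counts, tree: TreeNode, taxa=None) -> float:
    """Faith's phylogenetic diversity, root-inclusive."""
    row, names = _as_row(counts, taxa)
    lengths, incidence = branch_table(tree, names)
    present = row > 0
    return float(lengths[(incidence & present).any(axis=1)].sum())


def alpha_diversity(table: pd.DataFrame, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample Shannon, richness and (if a tree is given) Faith's PD."""
    out = pd.DataFrame(index=table.index)
    out["shannon"] = [shannon(r) for r in table.to_numpy()]
    out["richness"] = (table.to_numpy() > 0).sum(axis=1)
    if tree is not None:
        lengths, incidence = branch_table(tree, table.columns)
        present = table.to_numpy() > 0  # samples x taxa
        spanned = incidence.astype(float) @ present.T.astype(float) > 0
        out["faith_pd"] = lengths @ spanned
    return out


# ---------------------------------------------------------------------------
# beta diversity


def _branch_fractions(values: np.ndarray, incidence: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("weighted UniFrac undefined for an empty sample")
    return incidence.astype(float) @ (values / totals).T  # branches x samples


def weighted_unifrac(u, v, tree: TreeNode, taxa=None, normalized: bool = True) -> float:
    """Weighted UniFrac between two count rows over the same taxa."""
    ru, names_u = _as_row(u, taxa)
    rv, names_v = _as_row(v, taxa)
    if names_u != names_v:
        raise ValueError("samples must share one taxon ordering")
    lengths, incidence = branch_table(tree, names_u)
    frac = _branch_fractions(np.vstack([ru, rv]), incidence)
    num = float(lengths @ np.abs(frac[:, 0] - frac[:, 1]))
    if not normalized:
        return num
    den = float(lengths @ (frac[:, 0] + frac[:, 1]))
    return num / den


def weighted_unifrac_matrix(
    table: pd.DataFrame, tree: TreeNode, normalized: bool = True
) -> pd.DataFrame:
    """All-pairs weighted UniFrac; symmetric with a zero diagonal."""
    lengths, incidence = branch_table(tree, table.columns)
    frac = _branch_fractions(table.to_numpy(dtype=float), incidence)
    n = frac.shape[1]
    dist = np.zeros((n, n))
    depth = lengths @ frac  # per-sample total length-weighted mass
    for i in range(n):
        diff = lengths @ np.abs(frac - frac[:, [i]])
        if normalized:
            dist[i] = diff / (depth + depth[i])
        else:
            dist[i] = diff
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = codes == g
        ng = int(idx.sum())
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    return ss_total, ss_within


def permanova(
    dist: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``pseudo_f = (SS_among/(k-1)) / (SS_within/(N-k))`` from squared
    distances; ``r_squared = SS_among / SS_total``; the p-value is
    ``(1 + #{F_perm >= F_obs}) / (n_permutations + 1)`` over whole-label
    permutations, so its floor is ``1/(n_permutations+1)``.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    groups = pd.Series(np.asarray(groups), dtype="object")
    codes, uniques = pd.factorize(groups)
    k = len(uniques)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [uniques[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"every group needs >= 2 members; too small: {small}")
    n = d.shape[0]
    if len(codes) != n:
        raise ValueError("group labels must match the distance matrix")
    d2 = d ** 2

    def f_stat(c: np.ndarray) -> float:
        ss_total, ss_within = _permanova_ss(d2, c, k)
        ss_among = ss_total - ss_within
        return (ss_among / (k - 1)) / (ss_within / (n - k))

    ss_total, ss_within = _permanova_ss(d2, codes, k)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (k - 1)) / (ss_within / (n - k))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(codes)) >= f_obs:
            hits += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(ss_among / ss_total),
        p_value=(1 + hits) / (n_permutations + 1),
        n_permutations=n_permutations,
    )


def pairwise_group_tests(values, groups) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for every pair of groups.

    Returns one row per unordered pair with the U statistic (for the
    first-listed group) and the two-sided p-value.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups, dtype=object))
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in combinations(levels, 2):
        xa = values[groups.to_numpy() == a]
        xb = values[groups.to_numpy() == b]
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"empty group in pair ({a}, {b})")
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb),
                     "statistic": float(res.statistic), "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)
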