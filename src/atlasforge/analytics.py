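"""Quantitative analysis of a cellular-resolution expression atlas.

Implements the atlas analytics: pairwise coexpression fractions and Dice
coefficients, topology trajectories (identity / inclusion / exclusion /
intersection of domain pairs over stages), WPGMA hierarchical clustering of
cells (morphogenetic domains) and of genes across stages (synexpression
groups), Shannon entropy of per-cell binary expression profiles in bits per
cell, cophenetic and distance-matrix correlations, robustness experiments
under threshold and table perturbations, and expansion-rate ratios of gene
domains against overall proliferation.

WPGMA merges the closest pair of clusters and averages distances without
size weighting: d(k, i∪j) = (d(k,i) + d(k,j)) / 2. Ties are broken toward
the lexicographically smallest pair of current node indices so trees are
reproducible; inversions (a merge below an earlier one) are possible and not
corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .atlas import CellProfileTable

__all__ = [
    "PairOverlap",
    "LinkageTree",
    "EntropyReport",
    "pair_overlap",
    "topology_trajectory",
    "wpgma",
    "cut_tree",
    "cluster_cells",
    "cluster_genes",
    "entropy",
    "cophenetic_correlation",
    "distance_matrix_correlation",
    "robustness_experiment",
    "perturb_one_cell",
    "perturb_random_third",
    "perturb_full_random",
    "expansion_rate_ratio",
]


# --------------------------------------------------------------------------
# Coexpression
# --------------------------------------------------------------------------

@dataclass
class PairOverlap:
    """Coexpression counts for one gene pair in one stage's template."""

    gene_a: str
    gene_b: str
    n_a: int
    n_b: int
    n_ab: int
    undefined: bool = False  # set when a denominator was zero

    @property
    def frac_a(self) -> float:
        return self.n_ab / self.n_a if self.n_a else 0.0

    @property
    def frac_b(self) -> float:
        return self.n_ab / self.n_b if self.n_b else 0.0

    @property
    def dice(self) -> float:
        return 2.0 * self.n_ab / (self.n_a + self.n_b) if (self.n_a + self.n_b) else 0.0


def pair_overlap(table: CellProfileTable, gene_a: str, gene_b: str) -> PairOverlap:
    """Cells coexpressing a gene pair, relative to each gene's positives.

    Cells flagged as not observed (outside every imaged analyzed volume) are
    excluded from the counts, since absence of signal there is not
    negativity.
    """
    a = table.column(gene_a).astype(bool)
    b = table.column(gene_b).astype(bool)
    if table.observed is not None:
        a = a & table.observed
        b = b & table.observed
    n_a, n_b = int(a.sum()), int(b.sum())
    return PairOverlap(gene_a, gene_b, n_a, n_b, int((a & b).sum()),
                       undefined=(n_a == 0 or n_b == 0))


def topology_trajectory(overlaps: Sequence[PairOverlap]) -> pd.DataFrame:
    """Topology chart: one (x, y) point per stage for a gene pair.

    x = fraction of gene-a positives coexpressing b, y = the converse.
    Corners classify the relationship — exclusion (0,0), a ⊂ b (x=1, y<1),
    b ⊂ a (y=1, x<1), identity (1,1) — anything else is an intersection.
    Corner tests use a one-cell tolerance relative to each denominator.
    """
    rows = []
    for k, ov in enumerate(overlaps):
        x, y = ov.frac_a, ov.frac_b
        eps_x = 1.0 / ov.n_a if ov.n_a else 0.0
        eps_y = 1.0 / ov.n_b if ov.n_b else 0.0
        if ov.undefined:
            label = "undefined"
        elif x >= 1 - eps_x and y >= 1 - eps_y:
            label = "identity"
        elif x >= 1 - eps_x:
            label = "a_in_b"
        elif y >= 1 - eps_y:
            label = "b_in_a"
        elif x <= eps_x and y <= eps_y:
            label = "exclusion"
        else:
            label = "intersection"
        rows.append({"stage_index": k, "x_frac_a": x, "y_frac_b": y,
                     "relationship": label})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# WPGMA clustering
# --------------------------------------------------------------------------

@dataclass
class LinkageTree:
    """Agglomerative merge history.

    Leaves are numbered 0..n−1; the k-th merge creates node n+k joining
    ``(node_i, node_j)`` at ``height`` with ``size`` leaves. WPGMA does not
    guarantee monotone heights along root paths; only non-negativity and
    exactly n−1 merges are invariant.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        if len(self.merges) != max(self.n_leaves - 1, 0):
            raise ValueError("a tree over n leaves must have exactly n-1 merges")
        if any(h < 0 for _, _, h, _ in self.merges):
            raise ValueError("merge heights must be non-negative")

    def to_scipy(self) -> np.ndarray:
        """SciPy linkage-matrix form (n−1, 4)."""
        return np.array([[i, j, h, s] for i, j, h, s in self.merges], dtype=float)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the dendrogram."""
        children = {self.n_leaves + k: (i, j) for k, (i, j, _, _) in enumerate(self.merges)}
        order: list[int] = []

        def walk(node: int) -> None:
            if node < self.n_leaves:
                order.append(node)
            else:
                i, j = children[node]
                walk(i)
                walk(j)

        if self.merges:
            walk(self.n_leaves + len(self.merges) - 1)
        else:
            order.extend(range(self.n_leaves))
        return order

    def cophenetic(self) -> np.ndarray:
        """Condensed matrix of pair merge heights (lowest common ancestor)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros(n * (n - 1) // 2)

        def idx(i: int, j: int) -> int:
            if i > j:
                i, j = j, i
            return n * i - i * (i + 1) // 2 + (j - i - 1)

        for k, (a, b, h, _) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    out[idx(i, j)] = h
            members[n + k] = members.pop(a) + members.pop(b)
        return out

    def to_newick(self, labels: Sequence[str] | None = None) -> str:
        """Newick serialization with branch lengths from merge heights."""
        labels = list(labels) if labels is not None else [str(i) for i in range(self.n_leaves)]
        height = {i: 0.0 for i in range(self.n_leaves)}
        node_str = {i: labels[i] for i in range(self.n_leaves)}
        for k, (i, j, h, _) in enumerate(self.merges):
            node = self.n_leaves + k
            bi = max(h - height[i], 0.0)
            bj = max(h - height[j], 0.0)
            node_str[node] = f"({node_str[i]}:{bi:.6g},{node_str[j]}:{bj:.6g})"
            height[node] = h
        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return node_str[root] + ";"


def _as_condensed(dist) -> tuple[np.ndarray, int]:
    d = np.asarray(dist, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("distance table contains NaN")
    if d.ndim == 2:
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("square distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        n = d.shape[0]
        d = squareform(d, checks=False)
    else:
        m = len(d)
        n = int(round((1 + math.sqrt(1 + 8 * m)) / 2))
        if n * (n - 1) // 2 != m:
            raise ValueError("condensed distance vector has invalid length")
    if np.any(np.isnan(d)):
        raise ValueError("distance table contains NaN")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return d, n


def wpgma(dist) -> LinkageTree:
    """Weighted pair-group method with averaging on a distance table.

    Accepts a condensed vector or a symmetric square matrix. Iteratively
    merges the closest pair; the merged cluster's distance to any other
    cluster is the unweighted mean of its two members' distances. Ties are
    broken toward the smallest (i, j) pair of current node indices.
    """
    d, n = _as_condensed(dist)
    if n < 2:
        raise ValueError("clustering requires at least 2 items")
    big = np.inf
    work = squareform(d).astype(float)
    np.fill_diagonal(work, big)
    node_of_row = np.arange(n)        # current node id living in each matrix row
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        val = work.min()
        ii, jj = np.nonzero(work == val)
        u_ids = node_of_row[ii]
        v_ids = node_of_row[jj]
        lo = np.minimum(u_ids, v_ids)
        hi = np.maximum(u_ids, v_ids)
        best = np.lexsort((hi, lo))[0]
        u, v = int(lo[best]), int(hi[best])
        ru = int(np.flatnonzero(node_of_row == u)[0])
        rv = int(np.flatnonzero(node_of_row == v)[0])
        new_node = n + step
        merges.append((u, v, float(val), sizes[u] + sizes[v]))
        new_row = (work[ru] + work[rv]) / 2.0
        work[ru] = new_row
        work[:, ru] = new_row
        work[ru, ru] = big
        work[rv] = big
        work[:, rv] = big
        node_of_row[ru] = new_node
        node_of_row[rv] = -1
        sizes[new_node] = sizes[u] + sizes[v]
    return LinkageTree(n_leaves=n, merges=merges)


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Cut a tree into k clusters by removing the k−1 largest-height merges.

    Ties between equal heights are resolved toward removing the later merge.
    Returns integer labels (0..k−1) per leaf, numbered by first occurrence.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError("k must lie in 1..n_leaves")
    drop_order = sorted(range(len(tree.merges)),
                        key=lambda m: (tree.merges[m][2], m), reverse=True)
    dropped = set(drop_order[:k - 1])
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (i, j, _, _) in enumerate(tree.merges):
        node = n + m
        if m in dropped:
            continue
        for child in (i, j):
            parent[find(child)] = find(node)
    # merged nodes always absorb their children; dropped merges leave the
    # children's components separate but the new node still anchors later merges
    for m in dropped:
        i, j, _, _ = tree.merges[m]
        node = n + m
        # attach the dropped node to its first child so later merges resolve
        parent[find(node)] = find(i)
    roots = [find(i) for i in range(n)]
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        labels[i] = seen.setdefault(r, len(seen))
    return labels


def cluster_cells(
    table: CellProfileTable, k: int, include_all_zero: bool = False
) -> tuple[np.ndarray, np.ndarray, LinkageTree]:
    """WPGMA clustering of cells by the Euclidean distance of their profiles.

    By default only cells with at least one positive gene are clustered
    (all-zero profiles are excluded, matching the focus on positive cells).

    Returns
    -------
    (indices, labels, tree)
        Row indices of the clustered cells, their cluster labels after
        cutting to k clusters, and the full linkage tree. The tree's leaves
        are numbered in the canonical (profile, position) order, which makes
        the clustering invariant to the table's cell ordering.
    """
    mask = np.ones(table.n_cells, dtype=bool) if include_all_zero else table.positive_any()
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError("need at least 2 cells to cluster")
    # canonical row order (profile code, then position) so tie-breaking in
    # the linkage does not depend on the table's cell ordering
    codes = table.profiles()[idx]
    pos = table.positions[idx]
    order = np.lexsort((pos[:, 2], pos[:, 1], pos[:, 0], codes))
    d = pdist(table.G[idx[order]].astype(float), metric="euclidean")
    tree = wpgma(d)
    canon_labels = cut_tree(tree, min(k, len(idx)))
    labels = np.empty(len(idx), dtype=int)
    labels[order] = canon_labels
    return idx, labels, tree


def cluster_genes(tables: Sequence[CellProfileTable]) -> tuple[LinkageTree, list[str]]:
    """Synexpression-group tree: WPGMA over spatiotemporal gene vectors.

    Each gene's binary column is concatenated across all stages into a
    length-C vector (C = total cells over all observation times); genes are
    clustered by the Euclidean distance between these vectors.
    """
    if not tables:
        raise ValueError("need at least one stage table")
    genes = list(tables[0].genes)
    for t in tables[1:]:
        if list(t.genes) != genes:
            raise ValueError("all stage tables must share the same gene list")
    stacked = np.vstack([t.G for t in tables]).T.astype(float)  # genes × C
    tree = wpgma(pdist(stacked, metric="euclidean"))
    return tree, genes


# --------------------------------------------------------------------------
# Entropy
# --------------------------------------------------------------------------

@dataclass
class EntropyReport:
    """Shannon entropy of the per-cell profile distribution, in bits per cell."""

    H: float
    n_genes: int
    n_cells: int
    profile_codes: np.ndarray       # observed profiles, sorted by contribution
    profile_counts: np.ndarray
    contributions: np.ndarray       # −p log2 p per observed profile
    n_profiles_used: int
    profiles_for_60pct: int
    profiles_for_75pct: int
    profiles_for_90pct: int

    @property
    def probabilities(self) -> np.ndarray:
        return self.profile_counts / self.n_cells


def entropy(table: CellProfileTable | np.ndarray) -> EntropyReport:
    """Plug-in Shannon entropy of the empirical profile distribution.

    H = −Σ_k p̂_k log2 p̂_k over all 2^N possible N-gene profiles, with
    p̂_k = n_k / C and 0·log 0 = 0 (unobserved profiles contribute nothing).
    Also reports each profile's information contribution and how many
    profiles, taken in decreasing contribution order, carry 60/75/90% of H.
    """
    if isinstance(table, CellProfileTable):
        g = table.G
    else:
        g = np.asarray(table)
    if g.ndim != 2 or g.shape[0] == 0:
        raise ValueError("need a non-empty cells × genes matrix")
    n_cells, n_genes = g.shape
    weights = 1 << np.arange(n_genes, dtype=np.int64)[::-1]
    codes = g.astype(np.int64) @ weights
    uniq, counts = np.unique(codes, return_counts=True)
    p = counts / n_cells
    contrib = -p * np.log2(p)
    h = float(contrib.sum())
    order = np.argsort(-contrib, kind="stable")
    uniq, counts, contrib = uniq[order], counts[order], contrib[order]
    cum = np.cumsum(contrib)

    def needed(frac: float) -> int:
        if h == 0:
            return 0
        return int(np.searchsorted(cum, frac * h - 1e-12) + 1)

    return EntropyReport(
        H=h, n_genes=n_genes, n_cells=n_cells,
        profile_codes=uniq, profile_counts=counts, contributions=contrib,
        n_profiles_used=len(uniq),
        profiles_for_60pct=needed(0.60),
        profiles_for_75pct=needed(0.75),
        profiles_for_90pct=needed(0.90),
    )


# --------------------------------------------------------------------------
# Tree/distance agreement metrics
# --------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def cophenetic_correlation(tree: LinkageTree, dist) -> float:
    """Pearson correlation between input distances and cophenetic distances.

    The cophenetic distance of a pair is the merge height of their lowest
    common ancestor in the tree. Constant distance tables make the
    correlation undefined and raise.
    """
    d, n = _as_condensed(dist)
    if n != tree.n_leaves:
        raise ValueError("distance table size does not match the tree")
    return _pearson(d, tree.cophenetic())


def distance_matrix_correlation(d1, d2) -> float:
    """Pearson correlation between two distance tables (upper triangles)."""
    a, n1 = _as_condensed(d1)
    b, n2 = _as_condensed(d2)
    if n1 != n2:
        raise ValueError("distance tables must describe the same number of items")
    return _pearson(a, b)


# --------------------------------------------------------------------------
# Robustness
# --------------------------------------------------------------------------

def perturb_one_cell(table: CellProfileTable, rng: np.random.Generator) -> CellProfileTable:
    """Minimal perturbation: flip one gene value of one cell."""
    g = table.G.copy()
    i = int(rng.integers(table.n_cells))
    j = int(rng.integers(len(table.genes)))
    g[i, j] = 1 - g[i, j]
    return table.with_G(g)


def perturb_random_third(table: CellProfileTable, rng: np.random.Generator) -> CellProfileTable:
    """Substantial perturbation: re-randomize one third of the table entries."""
    g = table.G.copy()
    n_entries = g.size
    pick = rng.choice(n_entries, size=n_entries // 3, replace=False)
    flat = g.ravel()
    flat[pick] = rng.integers(0, 2, size=len(pick))
    return table.with_G(flat.reshape(g.shape))


def perturb_full_random(table: CellProfileTable, rng: np.random.Generator) -> CellProfileTable:
    """Replace the table by a random atlas of the same size."""
    g = rng.integers(0, 2, size=table.G.shape).astype(np.int8)
    return table.with_G(g)


def robustness_experiment(
    table: CellProfileTable,
    perturbed: Mapping[str, CellProfileTable],
    include_all_zero: bool = True,
) -> pd.DataFrame:
    """Entropy and clustering stability under atlas perturbations.

    For each perturbed table (e.g. re-segmented under ±10% thresholds, one
    flipped cell, one-third randomized, fully random), reports the entropy
    difference ΔH in bits, the cophenetic correlation of the *original* tree
    against the perturbed pairwise distances, and the Pearson correlation
    between the original and perturbed distance matrices. Cell sets must
    align, so distances are computed over all template cells by default.
    """
    mask = np.ones(table.n_cells, dtype=bool) if include_all_zero else table.positive_any()
    base_g = table.G[mask].astype(float)
    d_orig = pdist(base_g, metric="euclidean")
    tree = wpgma(d_orig)
    h_orig = entropy(table).H
    rows = []
    for name, pt in perturbed.items():
        if pt.n_cells != table.n_cells or list(pt.genes) != list(table.genes):
            raise ValueError(f"perturbed table {name!r} does not align with the original")
        d_pert = pdist(pt.G[mask].astype(float), metric="euclidean")
        rows.append({
            "perturbation": name,
            "delta_H_bits": entropy(pt).H - h_orig,
            "cophenetic_r": _pearson(tree.cophenetic(), d_pert),
            "distance_matrix_r": _pearson(d_orig, d_pert),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Expansion rates
# --------------------------------------------------------------------------

def expansion_rate_ratio(
    positive_counts: pd.DataFrame, roi_counts: Sequence[float]
) -> pd.DataFrame:
    """Gene-domain growth relative to overall proliferation, per stage pair.

    ``positive_counts`` is genes × stages; ``roi_counts`` the total cells in
    the region of interest per stage. For consecutive stages t, t+1 the ratio
    is (n_g(t+1)/n_g(t)) / (n_roi(t+1)/n_roi(t)); 1 means the domain expands
    exactly with proliferation (sustained expression), <1 down-regulation,
    >1 recruitment of newly expressing cells.
    """
    roi = np.asarray(roi_counts, dtype=float)
    if positive_counts.shape[1] != len(roi):
        raise ValueError("roi_counts must have one entry per stage")
    if np.any(roi[:-1] <= 0):
        raise ValueError("ROI counts must be positive")
    stages = list(positive_counts.columns)
    out = {}
    for t in range(len(stages) - 1):
        roi_rate = roi[t + 1] / roi[t]
        gene_prev = positive_counts.iloc[:, t].to_numpy(dtype=float)
        gene_next = positive_counts.iloc[:, t + 1].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (gene_next / gene_prev) / roi_rate
        out[f"{stages[t]}->{stages[t + 1]}"] = ratio
    return pd.DataFrame(out, index=positive_counts.index)
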