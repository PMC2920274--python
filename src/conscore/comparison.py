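"""Method-comparison machinery: correlations, clustering, bootstrap.

Scores are compared only *within* alignments (scores are generally
incomparable across alignments because several depend on alignment size):
one Spearman rank-correlation matrix per alignment, averaged elementwise
over alignments, converted to a distance ``D = 1 - C_bar``, and clustered
agglomeratively.  Node reliability comes from a bootstrap over alignments:
resample the alignment set with replacement, rebuild the dendrogram, and
count how often each original node reappears with an identical leaf set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)

ID_COLUMNS = ("alignment_id", "column", "is_catalytic")

LINKAGE_METHODS = ("average", "single", "complete")


def method_names(score_table: pd.DataFrame) -> list[str]:
    return [c for c in score_table.columns if c not in ID_COLUMNS]


def per_alignment_correlations(
    score_table: pd.DataFrame, min_sites: int = 3
) -> tuple[list[str], np.ndarray]:
    """Spearman correlation matrix of the methods for each alignment.

    Returns the alignment ids used and a stacked ``(m, K, K)`` array.
    Alignments with fewer than ``min_sites`` analyzable columns are
    excluded; method pairs involving a constant score vector are undefined
    (NaN) for that alignment and excluded from later averaging.
    """
    names = method_names(score_table)
    mats, used = [], []
    for aln_id, group in score_table.groupby("alignment_id", sort=False):
        X = group[names].to_numpy()
        if X.shape[0] < min_sites:
            logger.info("skipping %s: only %d sites", aln_id, X.shape[0])
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            C = spearmanr(X).statistic
        if np.ndim(C) == 0:  # scipy collapses the K=2 case to a scalar
            C = np.array([[1.0, float(C)], [float(C), 1.0]])
        np.fill_diagonal(C, 1.0)
        mats.append(C)
        used.append(aln_id)
    if not mats:
        raise ValueError("no alignment had enough analyzable columns")
    return used, np.stack(mats)


def average_and_distance(corr_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average correlation matrix over alignments and ``D = 1 - C_bar``.

    Averaging ignores NaN entries (undefined pairs); a pair undefined in
    every alignment is an error.
    """
    with np.errstate(invalid="ignore"):
        C_bar = np.nanmean(corr_stack, axis=0)
    if np.isnan(C_bar).any():
        i, j = np.argwhere(np.isnan(C_bar))[0]
        raise ValueError(
            f"method pair ({i}, {j}) has no defined correlation in any alignment"
        )
    C_bar = (C_bar + C_bar.T) / 2.0
    np.fill_diagonal(C_bar, 1.0)
    D = 1.0 - C_bar
    np.fill_diagonal(D, 0.0)
    return C_bar, D


def hierarchical_cluster(D: np.ndarray, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of the method distance matrix.

    Returns a scipy linkage matrix; merge heights are distances, so the
    average correlation at which a node joins is ``acc = 1 - height``.
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    condensed = squareform(np.clip(D, 0.0, None), checks=False)
    return hierarchy.linkage(condensed, method=linkage)


def _node_leafsets(Z: np.ndarray, n_leaves: int) -> list[frozenset[int]]:
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(n_leaves)]
    for a, b in Z[:, :2].astype(int):
        sets.append(sets[a] | sets[b])
    return sets[n_leaves:]


@dataclass(frozen=True)
class Dendrogram:
    """Clustering result: linkage matrix, method names, optional supports."""

    methods: tuple[str, ...]
    linkage_matrix: np.ndarray
    support: np.ndarray | None = None  # percent, one entry per internal node

    def node_leafsets(self) -> list[frozenset[str]]:
        return [
            frozenset(self.methods[i] for i in s)
            for s in _node_leafsets(self.linkage_matrix, len(self.methods))
        ]

    def merge_acc(self) -> np.ndarray:
        """Average correlation coefficient at each merge (1 - height)."""
        return 1.0 - self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick with branch lengths from merge heights and support labels."""
        n = len(self.methods)
        text = {i: self.methods[i] for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for t, row in enumerate(self.linkage_matrix):
            a, b, h = int(row[0]), int(row[1]), row[2]
            label = (
                "" if self.support is None else f"{self.support[t]:.0f}"
            )
            text[n + t] = (
                f"({text[a]}:{h - height[a]:.6g},{text[b]}:{h - height[b]:.6g}){label}"
            )
            height[n + t] = h
        return text[n + len(self.linkage_matrix) - 1] + ";"


def cluster_methods(
    score_table: pd.DataFrame,
    linkage: str = "average",
    n_boot: int = 1000,
    seed: int = 0,
    min_sites: int = 3,
) -> tuple[np.ndarray, np.ndarray, Dendrogram]:
    """Full comparison pipeline: correlations, distance, dendrogram, bootstrap.

    Returns ``(C_bar, D, dendrogram)``; the dendrogram carries per-node
    bootstrap support percentages when ``n_boot > 0``.
    """
    names = method_names(score_table)
    _, stack = per_alignment_correlations(score_table, min_sites=min_sites)
    C_bar, D = average_and_distance(stack)
    Z = hierarchical_cluster(D, linkage)
    support = (
        bootstrap_support(stack, Z, n_boot=n_boot, linkage=linkage, seed=seed)
        if n_boot > 0
        else None
    )
    return C_bar, D, Dendrogram(tuple(names), Z, support)


def bootstrap_support(
    corr_stack: np.ndarray,
    Z: np.ndarray,
    n_boot: int = 1000,
    linkage: str = "average",
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap node support over alignments, in percent.

    Each bootstrap sample redraws the ``m`` alignments with replacement,
    averages their correlation matrices, reclusters, and scores an
    original node as present when some bootstrap node has the identical
    leaf set.  Samples in which a method pair is undefined everywhere are
    redrawn (logged).
    """
    rng = np.random.default_rng(seed)
    m = corr_stack.shape[0]
    n_leaves = corr_stack.shape[1]
    original = _node_leafsets(Z, n_leaves)
    hits = np.zeros(len(original))
    done = 0
    while done < n_boot:
        idx = rng.integers(0, m, size=m)
        try:
            C_bar, D = average_and_distance(corr_stack[idx])
        except ValueError:
            logger.info("bootstrap sample had an everywhere-undefined pair; redrawn")
            continue
        boot_sets = set(_node_leafsets(hierarchical_cluster(D, linkage), n_leaves))
        for k, s in enumerate(original):
            if s in boot_sets:
                hits[k] += 1
        done += 1
    return 100.0 * hits / n_boot


def size_dependency(
    score_table: pd.DataFrame, alignment_sizes: dict[str, int]
) -> pd.Series:
    """Pearson correlation of alignment size with per-alignment mean score.

    ``alignment_sizes`` maps alignment id to its number of sequences N.
    Methods whose mean score is constant, or datasets with fewer than 3
    distinct sizes, yield NaN entries.
    """
    names = method_names(score_table)
    means = score_table.groupby("alignment_id", sort=False)[names].mean()
    sizes = np.array([alignment_sizes[a] for a in means.index])
    out = {}
    for name in names:
        y = means[name].to_numpy()
        if len(np.unique(sizes)) < 3 or np.ptp(y) == 0:
            out[name] = np.nan
        else:
            out[name] = pearsonr(sizes, y).statistic
    return pd.Series(out, name="pearson_r")
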