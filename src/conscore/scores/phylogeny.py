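"""Phylogeny-aware scores: UPGMA trees and the real-valued evolutionary trace.

The real-valued evolutionary trace (Mihalek04) builds a UPGMA tree from
percent sequence distances and accumulates, over every cut of the tree
into ``n`` groups (n = 1..N-1), the residue entropies of the groups,
weighting each cut by ``1/n``.  Variation confined to a clade is thereby
penalized less than the same variation scattered over the tree.  Zhang08
replaces the within-group Shannon entropy by the von Neumann entropy so
that stereochemically similar residues count as partly identical.

An adapter hook for the external Rate4Site program (Mayrose04) is
provided; when no executable is configured the method is simply absent
from the registry and the pipeline runs on the remaining scores.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..alphabet import N_AA
from .entropy import shannon_entropy, von_neumann_entropy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UpgmaTree:
    """A rooted ultrametric binary tree over sequence indices.

    ``merges`` follows the scipy linkage convention: row ``t`` joins
    cluster ids ``left``/``right`` (leaves are 0..N-1, internal node
    created by row ``t`` has id ``N+t``) at ``height``.  Merges are in
    non-decreasing height order, so cutting at the ``n-1`` highest nodes
    equals keeping only the first ``N-n`` merges.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float], ...]  # (left_id, right_id, height)

    def cut(self, n: int) -> list[frozenset[int]]:
        """Partition the leaves into ``n`` groups (nested in ``n``)."""
        if not 1 <= n <= self.n_leaves:
            raise ValueError(f"cut size {n} outside [1, {self.n_leaves}]")
        parent = list(range(self.n_leaves + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        groups: dict[int, set[int]] = {i: {i} for i in range(self.n_leaves)}
        for t, (a, b, _h) in enumerate(self.merges[: self.n_leaves - n]):
            ra, rb = find(a), find(b)
            node = self.n_leaves + t
            parent[ra] = parent[rb] = node
            groups[node] = groups.pop(ra) | groups.pop(rb)
        return sorted((frozenset(g) for g in groups.values()), key=min)

    def node_leafsets(self) -> list[frozenset[int]]:
        """Leaf set under each internal node, in merge order."""
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(self.n_leaves)]
        for a, b, _h in self.merges:
            sets.append(sets[a] | sets[b])
        return sets[self.n_leaves :]

    def cut_coefficients(self) -> tuple[list[frozenset[int]], np.ndarray]:
        """Evolutionary-trace coefficient of every tree node.

        Node ``v`` is a group of ``cut(n)`` for a contiguous range of
        ``n``; its coefficient is ``sum 1/n`` over that range intersected
        with the trace summation range ``1 <= n <= N-1``.  Returns the
        leaf sets of all 2N-1 nodes and their coefficients; singleton
        leaves are included for completeness although their entropy is 0.
        """
        n_leaves = self.n_leaves
        n_nodes = n_leaves + len(self.merges)
        created = np.empty(n_nodes, dtype=int)  # merge index creating the node
        created[:n_leaves] = -1
        created[n_leaves:] = np.arange(len(self.merges))
        absorbed = np.full(n_nodes, len(self.merges), dtype=int)
        for t, (a, b, _h) in enumerate(self.merges):
            absorbed[a] = absorbed[b] = t
        inv = np.concatenate([[0.0], 1.0 / np.arange(1, n_leaves + 1)])
        cum = np.cumsum(inv)  # cum[n] = sum_{m<=n} 1/m
        coeffs = np.zeros(n_nodes)
        for v in range(n_nodes):
            # node exists in cut(n) for N - absorbed[v] <= n <= N - created[v] - 1
            lo = max(1, n_leaves - absorbed[v])
            hi = min(n_leaves - 1, n_leaves - created[v] - 1)
            if hi >= lo:
                coeffs[v] = cum[hi] - cum[lo - 1]
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(n_leaves)]
        for a, b, _h in self.merges:
            sets.append(sets[a] | sets[b])
        return sets, coeffs

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick string with ultrametric branch lengths."""
        labels = labels or [str(i) for i in range(self.n_leaves)]
        text = {i: lab for i, lab in enumerate(labels)}
        height = {i: 0.0 for i in range(self.n_leaves)}
        for t, (a, b, h) in enumerate(self.merges):
            node = self.n_leaves + t
            text[node] = (
                f"({text[a]}:{h - height[a]:.6g},{text[b]}:{h - height[b]:.6g})"
            )
            height[node] = h
        return text[self.n_leaves + len(self.merges) - 1] + ";"


def build_upgma(D: np.ndarray) -> UpgmaTree:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Node heights are half the merge distance (ultrametric convention).
    Ties are broken deterministically toward the pair whose clusters
    contain the smallest leaf indices.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.diag(D).any():
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    # active cluster id -> (size, min leaf); distances in a dict-of-dicts
    dist = {i: {j: D[i, j] for j in range(n) if j != i} for i in range(n)}
    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(dist) > 1:
        best = None
        for i in dist:
            for j, d in dist[i].items():
                if j <= i:
                    continue
                key = (d, min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        d = dist[i][j]
        a, b = (i, j) if min_leaf[i] <= min_leaf[j] else (j, i)
        merges.append((a, b, d / 2.0))
        new = {}
        for k in dist:
            if k in (i, j):
                continue
            new[k] = (size[i] * dist[i][k] + size[j] * dist[j][k]) / (
                size[i] + size[j]
            )
        for k in (i, j):
            for other in dist[k]:
                dist[other].pop(k, None)
            del dist[k]
        for k, d_k in new.items():
            dist[k][next_id] = d_k
        dist[next_id] = new
        size[next_id] = size[i] + size[j]
        min_leaf[next_id] = min(min_leaf[i], min_leaf[j])
        next_id += 1
    return UpgmaTree(n_leaves=n, merges=tuple(merges))


def _group_distribution(codes: np.ndarray, members: frozenset[int]) -> np.ndarray:
    sub = codes[sorted(members)]
    return np.bincount(sub, minlength=N_AA) / len(sub)


def mihalek04(
    codes: np.ndarray,
    tree: UpgmaTree,
    per_sequence: bool = False,
    base: float = np.e,
) -> float:
    """Real-valued evolutionary trace of a column on a UPGMA tree.

    ``r(k) = sum_{n=1}^{N-1} (1/n) sum_{g in cut(n)} S(p_g(k))`` with
    Shannon entropies of the within-group residue distributions.  The
    original formulation adds a constant 1 and optionally divides by
    ``N - 1`` (``per_sequence=True``); both are monotone transforms that
    leave within-alignment rankings unchanged, and the constant is
    dropped here.  Native orientation: variability.
    """
    sets, coeffs = tree.cut_coefficients()
    total = 0.0
    for members, c in zip(sets, coeffs):
        if c == 0.0 or len(members) == 1:
            continue
        total += c * shannon_entropy(_group_distribution(codes, members), base=base)
    if per_sequence:
        total /= tree.n_leaves - 1
    return total


def zhang08(
    codes: np.ndarray,
    tree: UpgmaTree,
    M_f: np.ndarray,
    per_sequence: bool = False,
    base: float = np.e,
) -> float:
    """Evolutionary trace with von Neumann group entropies.

    Identical summation to :func:`mihalek04` but each group's Shannon
    entropy is replaced by the von Neumann entropy built from ``M_f``, so
    conservative within-group variation is discounted.  Native
    orientation: variability.
    """
    sets, coeffs = tree.cut_coefficients()
    total = 0.0
    for members, c in zip(sets, coeffs):
        if c == 0.0 or len(members) == 1:
            continue
        p_g = _group_distribution(codes, members)
        total += c * von_neumann_entropy(p_g, M_f, base=base)
    if per_sequence:
        total /= tree.n_leaves - 1
    return total


def mayrose04_adapter(
    alignment, exe_path: str | Path | None = None
) -> np.ndarray | None:
    """Optional hook for the external Rate4Site program.

    Writes the alignment to FASTA, invokes the executable, and parses its
    per-site rate table (site index, rate per line; comment lines
    ignored).  Rates are returned as-is (higher rate = more variable);
    the registry negates them into conservation orientation.  Returns
    ``None`` — and the method is simply skipped — when no executable is
    available or the invocation fails.
    """
    if exe_path is None or not shutil.which(str(exe_path)):
        logger.warning("Rate4Site executable not configured; skipping mayrose04")
        return None
    from ..msa_io import write_alignment

    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "aln.fasta"
        out = Path(tmp) / "rates.txt"
        write_alignment(alignment, fasta)
        try:
            subprocess.run(
                [str(exe_path), "-s", str(fasta), "-o", str(out)],
                check=True,
                capture_output=True,
                timeout=3600,
            )
            rates = {}
            for line in out.read_text().splitlines():
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                try:
                    rates[int(parts[0])] = float(parts[2] if len(parts) > 2 else parts[1])
                except (ValueError, IndexError):
                    continue
            if not rates:
                raise ValueError("no parseable rate lines")
            return np.array([rates[i] for i in sorted(rates)])
        except (subprocess.SubprocessError, ValueError, KeyError) as exc:
            logger.warning("Rate4Site invocation failed (%s); skipping mayrose04", exc)
            return None
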