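"""Substitution-matrix scores.

These methods score the residue *substitutions* observed at a site rather
than the residues themselves: sum-of-pairs similarity (Karlin96,
Sander91sp, Valdar01), its alphabet-summed analogue (Pei01sp), a vector
deviation from a consensus profile (Thompson97), relative entropy of
residue pairs (Mihalek07), and comparison to the most common residue
(Liu08w).
"""

from __future__ import annotations

import numpy as np

from ..alphabet import N_AA


def _pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def karlin96(codes: np.ndarray, M_K: np.ndarray) -> float:
    """Unweighted sum-of-pairs similarity with the unit-diagonal matrix M_K.

    ``(2 / (N(N-1))) * sum_{i<j} M_K(A_i, A_j)``; equals 1 at any fully
    conserved site because the diagonal of M_K is 1.
    """
    i, j = _pairs(len(codes))
    return float(M_K[codes[i], codes[j]].mean())


def sander91sp_pair_weights(D: np.ndarray) -> np.ndarray:
    """Pair weights proportional to percent sequence distance.

    ``w_ij = d(A_i, A_j) / sum d`` so diverged pairs dominate; a
    degenerate alignment of identical sequences (all distances zero) falls
    back to equal weights.
    """
    i, j = _pairs(D.shape[0])
    w = D[i, j].astype(float)
    total = w.sum()
    if total == 0:
        return np.full(len(w), 1.0 / len(w))
    return w / total


def sander91sp(codes: np.ndarray, M_K: np.ndarray, pair_weights: np.ndarray) -> float:
    """Distance-weighted sum-of-pairs similarity with M_K.

    Same form as :func:`karlin96` but each sequence pair carries a weight
    derived from its percent distance; reduces to Karlin96 under equal
    weights.
    """
    i, j = _pairs(len(codes))
    w = np.asarray(pair_weights, dtype=float)
    if w.sum() == 0:
        raise ValueError("all pair weights are zero")
    return float((w * M_K[codes[i], codes[j]]).sum() / w.sum())


def valdar_weights(D: np.ndarray) -> np.ndarray:
    """Tree-free sequence weights: mean percent distance to all others.

    Normalized to sum 1; identical-sequence alignments get equal weights.
    """
    n = D.shape[0]
    w = D.sum(axis=1) / (n - 1)
    total = w.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return w / total


def valdar01(codes: np.ndarray, M_V: np.ndarray, seq_weights: np.ndarray) -> float:
    """Sequence-weighted sum of pairs with the [0, 1]-normalized matrix M_V.

    ``sum_{i<j} w_i w_j M_V(A_i, A_j) / sum_{i<j} w_i w_j``.  Because the
    diagonal of M_V retains the self-similarity spread of BLOSUM62, fully
    conserved sites of high self-similarity residues (e.g. Trp) outrank
    fully conserved sites of commoner residues.
    """
    i, j = _pairs(len(codes))
    w = np.asarray(seq_weights, dtype=float)
    ww = w[i] * w[j]
    return float((ww * M_V[codes[i], codes[j]]).sum() / ww.sum())


def pei01sp(p_k: np.ndarray, M_K: np.ndarray) -> float:
    """Alphabet-summed sum of pairs: ``sum_ab p_k(a) p_k(b) M_K(a, b)``.

    The weighted variant differs only in how ``p_k`` was estimated.
    Differs from :func:`karlin96` by O(1/N) (self pairs included).
    """
    return float(p_k @ M_K @ p_k)


def thompson97(codes: np.ndarray, M: np.ndarray, seq_weights: np.ndarray) -> float:
    """Mean Euclidean deviation from the site's consensus profile vector.

    Each sequence contributes the substitution-matrix row of its residue
    (a 20-dimensional vector); the score is the weighted average distance
    to the weighted mean vector.  Native orientation: variability (0 at a
    fully conserved site).
    """
    w = np.asarray(seq_weights, dtype=float)
    w = w / w.sum()
    vectors = M[codes]  # (N, 20)
    mean_vec = w @ vectors
    dists = np.linalg.norm(vectors - mean_vec, axis=1)
    return float(w @ dists)


def pair_distribution(codes: np.ndarray) -> np.ndarray:
    """Distribution over unordered residue pairs at a site.

    Returned as a symmetric 20x20 array whose upper triangle (including
    the diagonal) sums to 1; entry (a, b) with a != b holds half the
    unordered-pair probability on each side.
    """
    n = len(codes)
    i, j = _pairs(n)
    counts = np.zeros((N_AA, N_AA))
    np.add.at(counts, (codes[i], codes[j]), 1.0)
    counts = (counts + counts.T) / 2.0  # symmetric; off-diag split across halves
    total = n * (n - 1) / 2.0
    return counts / total


def mihalek07(codes: np.ndarray, M_M: np.ndarray) -> float:
    """Relative entropy of observed residue pairs against M_M.

    The background over unordered pairs is proportional to
    ``M_M(a, b) * (2 - delta_ab)``, renormalized; the score is
    ``sum_{a<=b} p_k(a,b) log(p_k(a,b) / b(a,b))``.  Rare substitutions
    therefore raise the score.  Conservation orientation (non-negative up
    to the background normalization).
    """
    P = pair_distribution(codes)
    B = M_M * (2.0 - np.eye(N_AA))
    iu = np.triu_indices(N_AA)
    p = P[iu] * np.where(iu[0] == iu[1], 1.0, 2.0)  # unordered-pair masses
    b = B[iu] / B[iu].sum()
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / b[nz])).sum())


def liu08w(codes: np.ndarray, M_L: np.ndarray, seq_weights: np.ndarray) -> float:
    """Weighted similarity of every residue to the site's most common one.

    ``sum_i w_i M_L(A_i, a0)`` with ``a0`` the residue of largest weighted
    frequency (ties broken deterministically toward the earliest residue
    in canonical order).  Bounded in [2, 10]; equals 10 when fully
    conserved because the M_L diagonal is pinned to 10.
    """
    w = np.asarray(seq_weights, dtype=float)
    w = w / w.sum()
    freq = np.zeros(N_AA)
    np.add.at(freq, codes, w)
    alpha0 = int(np.argmax(freq))  # argmax takes the first (canonical-order) tie
    return float(w @ M_L[codes, alpha0])
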