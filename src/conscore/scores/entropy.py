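"""Entropy-family scores.

Shannon entropy (base 20) merges the Sander91 / Shenkin91 / Gerstein95
variants, which are monotone transforms of one another within an alignment
and therefore indistinguishable to rank-based comparison.  Relative
entropy against the BLOSUM62 background gives Wang06w; the Jensen-Shannon
divergence (base 2, bounded in [0, 1]) gives Capra07w.  Grouped alphabets
give Mirny99 (entropy over 6 groups) and Williamson95 (relative entropy
over 9 groups against the alignment-wide distribution).  Caffrey04w is the
von Neumann entropy of a density matrix that mixes the site distribution
with the BLOSUM62 frequency matrix, so that similar residues reduce the
effective entropy.

Log bases for the grouped scores are config arguments: the choices below
make each score's natural range [0, 1]-like, and any base yields identical
within-alignment rankings.
"""

from __future__ import annotations

import numpy as np

from ..alphabet import AA_INDEX, N_AA

#: Six-group reduced alphabet (hydrophobic, aromatic, polar, basic, acidic, special).
MIRNY_GROUPS = ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "GP")

#: Nine-group reduced alphabet.
WILLIAMSON_GROUPS = ("VLIM", "FWY", "ST", "NQ", "HKR", "DE", "AG", "P", "C")


def group_map(groups: tuple[str, ...]) -> np.ndarray:
    """Residue code -> group index for a disjoint covering group alphabet."""
    mapping = np.full(N_AA, -1, dtype=np.intp)
    for g, members in enumerate(groups):
        for aa in members:
            mapping[AA_INDEX[aa]] = g
    if (mapping < 0).any():
        raise ValueError("group alphabet does not cover all residues")
    return mapping


def shannon_entropy(p: np.ndarray, base: float = 20.0) -> float:
    """``-sum p log_base p`` with the convention ``0 log 0 = 0``."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * (np.log(p[nz]) / np.log(base))).sum())


def relative_entropy(p: np.ndarray, q: np.ndarray, base: float = np.e) -> float:
    """Kullback-Leibler divergence ``sum p log_base(p/q)`` (p=0 terms are 0)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    nz = p > 0
    return float((p[nz] * (np.log(p[nz] / q[nz]) / np.log(base))).sum())


def shannon(p_k: np.ndarray) -> float:
    """Shannon site entropy, base 20 (native orientation: variability)."""
    return shannon_entropy(p_k, base=20.0)


def wang06w(p_k: np.ndarray, q: np.ndarray) -> float:
    """Relative entropy of the (weighted) site distribution vs background."""
    return relative_entropy(p_k, q)


def capra07w(p_k: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2) of site vs background; in [0, 1]."""
    r = (p_k + q) / 2.0
    return 0.5 * relative_entropy(p_k, r, base=2.0) + 0.5 * relative_entropy(
        q, r, base=2.0
    )


def grouped_distribution(p_k: np.ndarray, mapping: np.ndarray) -> np.ndarray:
    """Project a 20-residue distribution onto a reduced group alphabet."""
    n_groups = int(mapping.max()) + 1
    out = np.zeros(n_groups)
    np.add.at(out, mapping, p_k)
    return out


def mirny99(p_k: np.ndarray, base: float = 6.0) -> float:
    """Entropy over the six-group alphabet (native orientation: variability)."""
    g = grouped_distribution(p_k, group_map(MIRNY_GROUPS))
    return shannon_entropy(g, base=base)


def williamson95(
    p_k: np.ndarray,
    alignment_p: np.ndarray,
    base: float = np.e,
    smoothing: float = 1e-6,
) -> float:
    """Relative entropy of the 9-group site distribution vs the alignment.

    ``alignment_p`` is the 20-residue distribution pooled over the
    alignment's analyzable columns.  The grouped background is smoothed by
    ``smoothing`` (then renormalized) so a group present in a column but
    absent from the pooled alignment cannot divide by zero.
    """
    mapping = group_map(WILLIAMSON_GROUPS)
    gp = grouped_distribution(p_k, mapping)
    gb = grouped_distribution(alignment_p, mapping) + smoothing
    gb = gb / gb.sum()
    return relative_entropy(gp, gb, base=base)


def von_neumann_entropy(
    p_k: np.ndarray, M_f: np.ndarray, base: float = 20.0
) -> float:
    """von Neumann entropy of ``omega = diag(p_k) @ M_f`` rescaled to trace 1.

    ``omega`` is similar to the symmetric matrix
    ``diag(sqrt(p)) @ M_f @ diag(sqrt(p))`` restricted to the support of
    ``p_k``, so its nonzero eigenvalues are computed from that (small)
    symmetric restriction; with a positive-definite ``M_f`` they are
    non-negative.  Tiny negative rounding (> -1e-10) is clipped; anything
    worse raises.
    """
    support = np.flatnonzero(p_k > 0)
    sqrt_p = np.sqrt(p_k[support])
    omega = sqrt_p[:, None] * M_f[np.ix_(support, support)] * sqrt_p[None, :]
    omega = omega / np.trace(omega)
    eigvals = np.linalg.eigvalsh((omega + omega.T) / 2.0)
    if eigvals.min() < -1e-10:  # pragma: no cover - defensive
        raise ArithmeticError(f"negative density-matrix eigenvalue {eigvals.min()}")
    eigvals = np.clip(eigvals, 0.0, None)
    return shannon_entropy(eigvals, base=base)


def caffrey04w(p_k: np.ndarray, M_f: np.ndarray) -> float:
    """von Neumann site entropy, base 20 (native orientation: variability)."""
    return von_neumann_entropy(p_k, M_f, base=20.0)
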