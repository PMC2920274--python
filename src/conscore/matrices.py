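"""BLOSUM62-derived matrix family, background distribution, sequence weights.

Six matrices are used by the scoring methods, all derived from BLOSUM62:

``M``
    the integer half-bit log-odds matrix;
``M_f``
    the matrix of target (pair) frequencies, summing to 1;
``M_V``
    ``M`` rescaled linearly onto [0, 1] (global min -> 0, global max -> 1);
``M_K``
    similarity normalized so the diagonal is exactly 1,
    ``M_K(a,b) = M(a,b) / sqrt(M(a,a) * M(b,b))``;
``M_M``
    ``M_f`` balanced so every row and column sums approximately to 1
    (Sinkhorn iterations with a symmetrizing step; exact double
    stochasticity is incompatible with symmetry);
``M_L``
    affine rescaling of ``M_K`` with the unit diagonal pinned to 10 and the
    off-diagonal range mapped into [2, 10].

The background distribution ``q`` is the marginal of ``M_f``.

This module also provides Henikoff position-based sequence weights and the
percent sequence distance used by pair-weighted scores and by the UPGMA
tree construction, both computed over analyzable columns only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AA_ORDER, N_AA
from .msa_io import Alignment, AlignmentInputError, Column, analyzable_columns


class MatrixFormatError(ValueError):
    """Malformed substitution-matrix file."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("conscore").joinpath("data", name)))


def load_blosum62(
    bla_path: str | Path | None = None,
    qij_path: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Load the BLOSUM62 log-odds matrix ``M`` and frequency matrix ``M_f``.

    Defaults to the package-data files.  Both are returned as symmetric
    20x20 float arrays in canonical residue order; ``M_f`` is normalized to
    sum exactly to 1.
    """
    bla_path = _data_path("blosum62.bla") if bla_path is None else Path(bla_path)
    qij_path = (
        _data_path("blosum62_qij_synthetic.qij") if qij_path is None else Path(qij_path)
    )

    # --- log-odds: square table with a residue header row and row labels
    lines = [
        ln for ln in bla_path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split()
    if sorted(header) != sorted(AA_ORDER) or len(header) != N_AA:
        raise MatrixFormatError(f"{bla_path}: expected 20 residue columns")
    col_order = [AA_INDEX[a] for a in header]
    M = np.zeros((N_AA, N_AA))
    seen_rows = set()
    for ln in lines[1:]:
        parts = ln.split()
        aa, values = parts[0], parts[1:]
        if aa not in AA_INDEX or len(values) != N_AA:
            raise MatrixFormatError(f"{bla_path}: bad row {aa!r}")
        M[AA_INDEX[aa], col_order] = [float(v) for v in values]
        seen_rows.add(aa)
    if seen_rows != set(AA_ORDER):
        raise MatrixFormatError(
            f"{bla_path}: missing rows {sorted(set(AA_ORDER) - seen_rows)}"
        )
    if not np.array_equal(M, M.T):
        raise MatrixFormatError(f"{bla_path}: matrix is not symmetric")

    # --- frequencies: lower triangle with a residue header row
    lines = [
        ln for ln in qij_path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split()
    if sorted(header) != sorted(AA_ORDER):
        raise MatrixFormatError(f"{qij_path}: expected 20 residue columns")
    order = [AA_INDEX[a] for a in header]
    Mf = np.zeros((N_AA, N_AA))
    if len(lines[1:]) != N_AA:
        raise MatrixFormatError(f"{qij_path}: expected 20 triangle rows")
    for i, ln in enumerate(lines[1:]):
        values = [float(v) for v in ln.split()]
        if len(values) != i + 1:
            raise MatrixFormatError(f"{qij_path}: triangle row {i + 1} malformed")
        for j, v in enumerate(values):
            Mf[order[i], order[j]] = Mf[order[j], order[i]] = v
    Mf = Mf / Mf.sum()
    return M, Mf


def balance_to_doubly_stochastic(
    Mf: np.ndarray, tol: float = 1e-6, max_iter: int = 1000, fail_tol: float = 1e-3
) -> np.ndarray:
    """Balance a positive symmetric matrix so rows/columns sum ~1 (``M_M``).

    Sinkhorn scaling with a symmetrization (average with the transpose)
    after every round.  Stops when the largest row/column-sum deviation
    drops below ``tol``; raises if it is still above ``fail_tol`` after
    ``max_iter`` rounds.
    """
    A = np.array(Mf, dtype=float)
    if (A <= 0).any():
        raise ValueError("balancing requires strictly positive entries")
    for _ in range(max_iter):
        A = A / A.sum(axis=1, keepdims=True)
        A = (A + A.T) / 2.0
        dev = max(
            np.abs(A.sum(axis=1) - 1.0).max(), np.abs(A.sum(axis=0) - 1.0).max()
        )
        if dev < tol:
            return A
    if dev > fail_tol:  # pragma: no cover - defensive
        raise ArithmeticError(f"matrix balancing did not converge (dev={dev:.2e})")
    return A


@dataclass(frozen=True)
class ScoreMatrixSet:
    """The BLOSUM62 matrix family plus the background distribution ``q``."""

    M: np.ndarray
    M_f: np.ndarray
    M_V: np.ndarray
    M_K: np.ndarray
    M_M: np.ndarray
    M_L: np.ndarray
    q: np.ndarray


def derive_matrices(M: np.ndarray, Mf: np.ndarray) -> ScoreMatrixSet:
    """Derive the full :class:`ScoreMatrixSet` from ``M`` and ``M_f``."""
    diag = np.diag(M)
    M_K = M / np.sqrt(np.outer(diag, diag))
    M_V = (M - M.min()) / (M.max() - M.min())
    off = ~np.eye(N_AA, dtype=bool)
    # Pin the unit diagonal of M_K to 10 and map the off-diagonal range to [2, 10].
    lo = M_K[off].min()
    M_L = 2.0 + (M_K - lo) * (10.0 - 2.0) / (1.0 - lo)
    np.fill_diagonal(M_L, 10.0)
    M_M = balance_to_doubly_stochastic(Mf)
    q = Mf.sum(axis=1)
    return ScoreMatrixSet(M=M, M_f=Mf, M_V=M_V, M_K=M_K, M_M=M_M, M_L=M_L, q=q)


@lru_cache(maxsize=1)
def default_matrices() -> ScoreMatrixSet:
    """The package-data BLOSUM62 matrix set (cached)."""
    return derive_matrices(*load_blosum62())


# ---------------------------------------------------------------------------
# sequence weights and distances


def henikoff_weights(alignment: Alignment) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights, summing to 1.

    In each analyzable column a residue type observed ``s`` times among
    ``r`` distinct types contributes ``1/(r*s)`` to each sequence carrying
    it; a sequence's raw weight is the sum over analyzable columns.
    """
    columns = analyzable_columns(alignment)
    if not columns:
        raise AlignmentInputError(
            f"alignment {alignment.id!r} has no analyzable columns"
        )
    n = alignment.n_sequences
    raw = np.zeros(n)
    for col in columns:
        codes = col.codes
        counts = np.bincount(codes, minlength=N_AA)
        r = int((counts > 0).sum())
        raw += 1.0 / (r * counts[codes])
    return raw / raw.sum()


def distance_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise percent sequence distances over analyzable columns.

    ``d(i, j) = 100 * (1 - fraction of identical residues)``; symmetric
    with a zero diagonal.
    """
    columns = analyzable_columns(alignment)
    if not columns:
        raise AlignmentInputError(
            f"alignment {alignment.id!r} has no analyzable columns"
        )
    codes = np.stack([c.codes for c in columns], axis=1)  # (N, n_cols)
    n = alignment.n_sequences
    D = np.zeros((n, n))
    for i in range(n):
        ident = (codes[i] == codes[i + 1 :]).mean(axis=1)
        D[i, i + 1 :] = D[i + 1 :, i] = 100.0 * (1.0 - ident)
    return D


def percent_distance(alignment: Alignment, i: int, j: int) -> float:
    """Percent distance between sequences ``i`` and ``j`` (0-based)."""
    return float(distance_matrix(alignment)[i, j])


def column_distribution(
    column: Column | np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Residue distribution ``p_k`` of a column, optionally sequence-weighted.

    Unweighted: relative frequencies.  Weighted: the total sequence weight
    carried by each residue type (weights are renormalized to sum to 1).
    """
    codes = column.codes if isinstance(column, Column) else np.asarray(column)
    if weights is None:
        weights = np.full(len(codes), 1.0 / len(codes))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    p = np.zeros(N_AA)
    np.add.at(p, codes, weights)
    return p
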