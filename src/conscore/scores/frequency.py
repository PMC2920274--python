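"""Symbol-frequency scores: Wu70, Lockless99 and Pei01var(w).

These scores look only at how often each amino acid occurs at a site,
either in absolute terms (Wu70) or relative to a background distribution
(Lockless99, Pei01var).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from ..alphabet import N_AA


def wu70(codes: np.ndarray) -> float:
    """Wu-Kabat variability: distinct residue count over top frequency.

    ``d_k / p_k(a0)`` with ``d_k`` the number of different amino acids at
    the site and ``a0`` its most common amino acid (unweighted
    frequencies).  Native orientation: larger = more variable; minimum 1
    at a fully conserved site.
    """
    counts = np.bincount(codes, minlength=N_AA)
    d_k = int((counts > 0).sum())
    p_top = counts.max() / len(codes)
    return d_k / p_top


def lockless99(codes: np.ndarray, q: np.ndarray) -> float:
    """Statistical-coupling site conservation from binomial surprise.

    Models the count of each amino acid as a binomial draw from the
    background ``q`` and accumulates, over the alphabet, the squared
    log-odds between the probability of the observed count and the
    probability of the expected count (the integer nearest ``N*q``),
    returning the root of the sum.  Evaluated in log space to avoid
    underflow.  Conservation orientation: deviation from background grows
    with conservation of any (especially rare) residue and with N.
    """
    n = len(codes)
    counts = np.bincount(codes, minlength=N_AA)
    expected = np.rint(n * q).astype(int)
    log_obs = binom.logpmf(counts, n, q)
    log_exp = binom.logpmf(expected, n, q)
    return float(np.sqrt(np.sum((log_obs - log_exp) ** 2)))


def pei01var(p_k: np.ndarray, q: np.ndarray) -> float:
    """Euclidean deviation of the site distribution from the background.

    ``sqrt(sum_a (p_k(a) - q(a))^2)``; bounded by sqrt(2).  The weighted
    variant differs only in how ``p_k`` was estimated.
    """
    return float(np.sqrt(np.sum((p_k - q) ** 2)))
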