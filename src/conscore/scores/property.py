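"""Stereochemical property scores: Taylor86 and Zvelebil87."""

from __future__ import annotations

import numpy as np

from ..properties import PropertySets


def taylor86(codes: np.ndarray, props: PropertySets) -> int:
    """Size of the smallest Taylor set containing all residues at the site.

    An integer in [2, 20]; smaller means more conserved (native
    orientation is variability).  The full 20-residue set guarantees a
    cover always exists; monotone under addition of residue types.
    """
    present = frozenset(int(c) for c in codes)
    best = min(len(t) for t in props.taylor_sets if present <= t)
    return best


def zvelebil87(codes: np.ndarray, props: PropertySets) -> float:
    """Property-dissimilarity conservation: ``0.9 - 0.1 * n_dis``.

    ``n_dis`` counts the binary physicochemical properties that take both
    values among the residues present.  A single-residue site scores
    exactly 1.  Conservation orientation.
    """
    present = np.unique(codes)
    if len(present) == 1:
        return 1.0
    membership = props.zvelebil[:, present]  # (n_props, n_present)
    varies = membership.any(axis=1) & ~membership.all(axis=1)
    return 0.9 - 0.1 * int(varies.sum())
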