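"""Canonical amino-acid alphabet shared by all modules.

Matrices, distributions and residue codes use one fixed ordering of the 20
standard amino acids.  Gap and ambiguity characters are recognized on input
but never enter a score computation: columns containing them are filtered
out upstream.
"""

import numpy as np

#: Canonical residue order used for every matrix and distribution.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Residue -> integer code in canonical order.
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Number of standard amino acids.
N_AA = 20

#: Gap characters accepted on input ('.' is treated as a synonym of '-').
GAP_CHARS = frozenset("-.")

#: Ambiguity codes accepted on input but excluded from analyzable columns.
AMBIGUITY_CHARS = frozenset("BXZ")

VALID_CHARS = frozenset(AA_ORDER) | GAP_CHARS | AMBIGUITY_CHARS


def encode(residues: str) -> np.ndarray:
    """Encode a string of standard residues as integer codes.

    Raises ``ValueError`` on gaps, ambiguity codes or unknown characters;
    use this only on analyzable (filtered) columns.
    """
    try:
        return np.array([AA_INDEX[r] for r in residues], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-standard residue {exc} in column") from exc
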