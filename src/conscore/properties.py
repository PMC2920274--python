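"""Stereochemical property tables for the Taylor and Zvelebil scores.

Two package-data resources back these scores:

* ``taylor_sets_synthetic.tsv`` — 61 residue subsets in the spirit of
  Taylor's Venn-diagram classification (see the file header for how the
  reconstruction was generated).  The smallest set is {D, E} and the full
  20-residue set is included, so the minimal-covering-set score is always
  defined and lies in [2, 20].
* ``zvelebil_properties.tsv`` — ten binary physicochemical properties
  (hydrophobic, polar, small, tiny, aliphatic, aromatic, charged,
  positive, negative, proline).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .alphabet import AA_INDEX, N_AA


@dataclass(frozen=True)
class PropertySets:
    """Taylor residue subsets and the Zvelebil binary property table."""

    taylor_sets: tuple[frozenset[int], ...]  # residue-code sets
    taylor_names: tuple[str, ...]
    zvelebil: np.ndarray  # (n_properties, 20) boolean membership
    zvelebil_names: tuple[str, ...]


def _read_data_lines(name: str) -> list[str]:
    text = resources.files("conscore").joinpath("data", name).read_text()
    return [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@lru_cache(maxsize=1)
def default_properties() -> PropertySets:
    """Load the package-data property tables (cached)."""
    names, sets = [], []
    for ln in _read_data_lines("taylor_sets_synthetic.tsv")[1:]:
        name, members = ln.split("\t")
        names.append(name)
        sets.append(frozenset(AA_INDEX[a] for a in members))
    if not any(len(s) == N_AA for s in sets):  # pragma: no cover - data guard
        raise ValueError("Taylor table must include the full 20-residue set")

    zv_names, rows = [], []
    for ln in _read_data_lines("zvelebil_properties.tsv")[1:]:
        name, members = ln.split("\t")
        zv_names.append(name)
        row = np.zeros(N_AA, dtype=bool)
        row[[AA_INDEX[a] for a in members]] = True
        rows.append(row)
    return PropertySets(
        taylor_sets=tuple(sets),
        taylor_names=tuple(names),
        zvelebil=np.array(rows),
        zvelebil_names=tuple(zv_names),
    )
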