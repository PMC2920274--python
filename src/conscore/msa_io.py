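"""Alignment and annotation input/output.

Alignments are read from aligned FASTA.  Catalytic-site annotations are a
two-column TSV (``alignment_id``, ``column``) with 1-based column indices,
the convention used by the Catalytic Site Atlas.  The only filtering rule
applied anywhere in the package lives here: an alignment column is
*analyzable* when no sequence carries a gap or one of the ambiguity codes
B, X, Z at that position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AMBIGUITY_CHARS, GAP_CHARS, VALID_CHARS, encode


class AlignmentFormatError(ValueError):
    """Malformed alignment or annotation file (ragged records, bad chars)."""


class AlignmentInputError(ValueError):
    """Structurally valid file that violates a precondition (e.g. N < 2)."""


@dataclass(frozen=True)
class SiteAnnotation:
    """A catalytic-site annotation: 1-based column in a named alignment."""

    alignment_id: str
    column: int  # 1-based


@dataclass(frozen=True)
class Column:
    """A gap-free, ambiguity-free alignment column.

    ``index`` keeps the original 1-based position in the source alignment,
    so annotations remain meaningful after filtering.
    """

    alignment_id: str
    index: int  # 1-based position in the source alignment
    residues: str
    is_catalytic: bool = False

    @property
    def codes(self) -> np.ndarray:
        """Integer residue codes in canonical order."""
        return encode(self.residues)

    @property
    def n_sequences(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple sequence alignment over the 20 amino acids plus gaps/B/X/Z."""

    id: str
    seq_ids: list[str]
    sequences: list[str]
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise AlignmentInputError(
                f"alignment {self.id!r} needs at least 2 sequences"
            )
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"alignment {self.id!r} has ragged sequence lengths {sorted(lengths)}"
            )
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise AlignmentFormatError(f"duplicate sequence ids in {self.id!r}")
        cleaned = []
        for sid, seq in zip(self.seq_ids, self.sequences):
            seq = seq.upper().replace(".", "-")
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentFormatError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )
            cleaned.append(seq)
        self.sequences = cleaned
        self._matrix = np.array([list(s) for s in cleaned], dtype="U1")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def column_residues(self, index: int) -> str:
        """Residues of 1-based column ``index`` in sequence order."""
        return "".join(self._matrix[:, index - 1])


def read_alignment(path: str | Path, alignment_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequence order is preserved.  The alignment id defaults to the file stem.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    return Alignment(
        id=alignment_id or path.stem,
        seq_ids=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.seq_ids, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a catalytic-site annotation TSV (header ``alignment_id<TAB>column``).

    Duplicate rows are collapsed; every listed (alignment, column) pair is
    catalytic, all unlisted columns are implicitly non-catalytic.
    """
    seen: set[tuple[str, int]] = set()
    out: list[SiteAnnotation] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.rstrip("\n").split("\t")[:2] == ["alignment_id", "column"]:
            raise AlignmentFormatError(
                f"annotation file {path} must start with 'alignment_id\\tcolumn'"
            )
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise AlignmentFormatError(f"{path}:{ln}: expected 2 columns")
            try:
                col = int(parts[1])
            except ValueError as exc:
                raise AlignmentFormatError(
                    f"{path}:{ln}: non-integer column {parts[1]!r}"
                ) from exc
            key = (parts[0], col)
            if key not in seen:
                seen.add(key)
                out.append(SiteAnnotation(alignment_id=parts[0], column=col))
    return out


def write_annotations(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("alignment_id\tcolumn\n")
        for ann in annotations:
            fh.write(f"{ann.alignment_id}\t{ann.column}\n")


def analyzable_columns(
    alignment: Alignment,
    annotations: Sequence[SiteAnnotation] = (),
) -> list[Column]:
    """Return the analyzable columns of ``alignment`` with catalytic flags.

    A column survives iff no sequence has a gap or B/X/Z there.  Catalytic
    annotations landing on a filtered-out column are silently dropped, i.e.
    positives are counted only among analyzable columns.
    """
    catalytic: set[int] = set()
    for ann in annotations:
        if ann.alignment_id != alignment.id:
            continue
        if not 1 <= ann.column <= alignment.length:
            raise AlignmentInputError(
                f"annotation column {ann.column} out of range for "
                f"{alignment.id!r} (L={alignment.length})"
            )
        catalytic.add(ann.column)
    excluded = GAP_CHARS | AMBIGUITY_CHARS
    out = []
    for idx in range(1, alignment.length + 1):
        residues = alignment.column_residues(idx)
        if excluded.isdisjoint(residues):
            out.append(
                Column(
                    alignment_id=alignment.id,
                    index=idx,
                    residues=residues,
                    is_catalytic=idx in catalytic,
                )
            )
    return out
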