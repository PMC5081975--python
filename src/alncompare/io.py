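"""Reading, validating and exporting multiple sequence alignments.

Supports FASTA, Clustal, MSF and Phylip input.  All parsed alignments are
normalised to a single internal convention: residues uppercased, and every
input gap character (``-``, ``.`` or ``~``) mapped to ``-``.  The comparison
machinery in :mod:`alncompare.core` assumes this normal form.

Column labels in all written matrices are 1-based, matching the convention
used in alignment viewers and in the figures produced by :mod:`alncompare.viz`.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

GAP = "-"
#: Gap characters accepted on input (MSF conventionally uses ".").
GAP_INPUT_CHARS = frozenset({"-", ".", "~"})
#: Formats accepted by :func:`read_alignment`.
FORMATS = ("fasta", "clustal", "msf", "phylip")


class AlignmentError(Exception):
    """Base class for alignment handling errors."""


class AlignmentFormatError(AlignmentError):
    """The input file could not be parsed as an alignment."""


class AlignmentValidationError(AlignmentError):
    """Two alignments cannot be compared (rows do not correspond)."""


@dataclass(frozen=True)
class Alignment:
    """An ``n x width`` character matrix of aligned sequences.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, one per row.
    chars:
        ``(n, width)`` array of single uppercase characters; gaps are ``-``.
    name:
        Optional display name (defaults to the source file stem on read).
    """

    ids: tuple[str, ...]
    chars: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        chars = np.asarray(self.chars, dtype="<U1")
        object.__setattr__(self, "chars", chars)
        object.__setattr__(self, "ids", tuple(self.ids))
        if chars.ndim != 2:
            raise AlignmentFormatError("alignment must be a 2-D character matrix")
        n, width = chars.shape
        if n < 2:
            raise AlignmentFormatError(f"an alignment needs at least 2 sequences, got {n}")
        if width < 1:
            raise AlignmentFormatError("alignment width must be at least 1 column")
        if len(self.ids) != n:
            raise AlignmentFormatError(
                f"{len(self.ids)} identifiers for {n} rows"
            )
        if len(set(self.ids)) != n:
            raise AlignmentFormatError("sequence identifiers are not unique")
        bad = (chars != GAP) & ~np.char.isalpha(chars)
        if bad.any():
            x = int(np.argwhere(bad)[0][0])
            raise AlignmentFormatError(
                f"sequence {self.ids[x]!r} contains a non-residue, non-gap character"
            )

    @property
    def n(self) -> int:
        """Number of sequences (rows)."""
        return self.chars.shape[0]

    @property
    def width(self) -> int:
        """Number of alignment columns."""
        return self.chars.shape[1]

    @classmethod
    def from_rows(
        cls, ids: Sequence[str], rows: Sequence[str], name: str = ""
    ) -> "Alignment":
        """Build a normalised alignment from one string per sequence.

        Rows are uppercased and all accepted gap characters unified to ``-``.
        Raises :class:`AlignmentFormatError` if rows are ragged, naming the
        first offending sequence.
        """
        ids = [str(i) for i in ids]
        rows = [str(r) for r in rows]
        if not rows:
            raise AlignmentFormatError("no sequences found")
        width = len(rows[0])
        for sid, row in zip(ids, rows):
            if len(row) != width:
                raise AlignmentFormatError(
                    f"sequence {sid!r} has length {len(row)}, expected {width}"
                )
        norm = []
        for row in rows:
            up = row.upper()
            norm.append([GAP if c in GAP_INPUT_CHARS else c for c in up])
        return cls(ids=tuple(ids), chars=np.array(norm, dtype="<U1"), name=name)

    def row_str(self, x: int) -> str:
        """Row ``x`` as a plain string (with gaps)."""
        return "".join(self.chars[x])

    def degapped(self) -> tuple[str, ...]:
        """The ungapped sequence of every row, in row order."""
        return tuple("".join(c for c in self.chars[x] if c != GAP) for x in range(self.n))

    def reorder(self, order: Sequence[int]) -> "Alignment":
        """Return a copy with rows permuted so that new row x = old row order[x]."""
        order = np.asarray(order, dtype=int)
        return Alignment(
            ids=tuple(self.ids[i] for i in order),
            chars=self.chars[order],
            name=self.name,
        )


@dataclass(frozen=True)
class PairValidation:
    """Row correspondence between a reference and a comparison alignment.

    ``row_order[x]`` is the row index in the comparison alignment whose
    ungapped sequence corresponds to reference row ``x``; applying
    ``comparison.reorder(row_order)`` lines the two alignments up row-for-row.
    """

    row_order: np.ndarray
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _sniff_format(text: str) -> str:
    """Detect the alignment format from file content.

    Detection order: Clustal header, MSF header, Phylip numeric first line,
    otherwise FASTA if the first non-blank character is ``>``.
    """
    first = ""
    for line in text.splitlines():
        if line.strip():
            first = line.strip()
            break
    if not first:
        raise AlignmentFormatError("file is empty")
    if first.upper().startswith("CLUSTAL"):
        return "clustal"
    if first.startswith("!!") or "MSF:" in text[:2048]:
        return "msf"
    tokens = first.split()
    if len(tokens) == 2 and all(t.isdigit() for t in tokens):
        return "phylip"
    if first.startswith(">"):
        return "fasta"
    raise AlignmentFormatError(
        "could not detect alignment format; supported formats: " + ", ".join(FORMATS)
    )


def _parse_fasta(text: str) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(_stdio.StringIO(text), "fasta"))
    if not records:
        raise AlignmentFormatError("no FASTA records found")
    return [r.id for r in records], [str(r.seq) for r in records]


def read_alignment(path: str | Path, format: str = "auto") -> Alignment:
    """Read one multiple sequence alignment from ``path``.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``fasta``, ``clustal``, ``msf``, ``phylip`` or ``auto``
        (content sniffing).

    Raises
    ------
    OSError
        If the file cannot be read.
    AlignmentFormatError
        If the content cannot be parsed, rows are ragged, or the format is
        unknown.
    """
    path = Path(path)
    text = path.read_text()
    fmt = format.lower()
    if fmt == "auto":
        fmt = _sniff_format(text)
    if fmt not in FORMATS:
        raise AlignmentFormatError(
            f"unknown format {format!r}; supported formats: {', '.join(FORMATS)} or auto"
        )
    if fmt == "fasta":
        # parsed manually so ragged rows can be reported by sequence name
        ids, rows = _parse_fasta(text)
    else:
        candidates = ["phylip-relaxed", "phylip"] if fmt == "phylip" else [fmt]
        msa = None
        err: Exception | None = None
        for cand in candidates:
            try:
                msa = AlignIO.read(_stdio.StringIO(text), cand)
                break
            except ValueError as exc:  # Biopython parse failure
                err = exc
        if msa is None:
            raise AlignmentFormatError(f"could not parse {path} as {fmt}: {err}")
        ids = [r.id for r in msa]
        rows = [str(r.seq) for r in msa]
    return Alignment.from_rows(ids, rows, name=path.stem)


def validate_pair(reference: Alignment, comparison: Alignment) -> PairValidation:
    """Check that two alignments hold the same ungapped sequences and pair rows.

    Rows are matched by identifier when the two id sets are equal; otherwise
    by unique ungapped sequence content (with a warning).  Ambiguity —
    duplicated ungapped sequences that cannot be resolved by ids — is a hard
    error, as is any reference sequence without a counterpart.
    """
    if reference.n != comparison.n:
        raise AlignmentValidationError(
            f"sequence counts differ: reference has {reference.n}, "
            f"comparison has {comparison.n}"
        )
    warnings: list[str] = []
    ref_seqs = reference.degapped()
    comp_seqs = comparison.degapped()

    if set(reference.ids) == set(comparison.ids):
        comp_index = {sid: x for sid, x in zip(comparison.ids, range(comparison.n))}
        order = np.array([comp_index[sid] for sid in reference.ids], dtype=int)
        for x, sid in enumerate(reference.ids):
            if ref_seqs[x] != comp_seqs[order[x]]:
                raise AlignmentValidationError(
                    f"sequence {sid!r} differs between the alignments once gaps "
                    "are removed; the two alignments must contain the same sequences"
                )
        return PairValidation(row_order=order, warnings=tuple(warnings))

    # content-based fallback
    warnings.append(
        "identifier sets differ; rows were paired by ungapped sequence content"
    )
    if len(set(ref_seqs)) != reference.n or len(set(comp_seqs)) != comparison.n:
        raise AlignmentValidationError(
            "identifier sets differ and ungapped sequences are not unique; "
            "row correspondence is ambiguous"
        )
    comp_by_seq = {seq: x for x, seq in enumerate(comp_seqs)}
    order = np.empty(reference.n, dtype=int)
    for x, seq in enumerate(ref_seqs):
        if seq not in comp_by_seq:
            raise AlignmentValidationError(
                f"sequence {reference.ids[x]!r} has no counterpart in the "
                "comparison alignment"
            )
        order[x] = comp_by_seq[seq]
    return PairValidation(row_order=order, warnings=tuple(warnings))


def write_matrix(
    matrix,
    path: str | Path,
    row_labels: Sequence | None = None,
    col_labels: Sequence | None = None,
) -> None:
    """Write a 2-D result matrix as CSV with labelled rows and columns.

    Labels default to 1-based integer indices.  Values round-trip through
    :func:`pandas.read_csv` exactly to float precision.
    """
    if not str(path):
        raise OSError("cannot write matrix: empty output path")
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise ValueError("write_matrix expects a 2-D matrix")
    if row_labels is None:
        row_labels = range(1, arr.shape[0] + 1)
    if col_labels is None:
        col_labels = range(1, arr.shape[1] + 1)
    df = pd.DataFrame(arr, index=list(row_labels), columns=list(col_labels))
    df.to_csv(path)


def write_summary_json(summary: dict, path: str | Path) -> None:
    """Write the comparison summary (scores, warnings, metadata) as JSON."""
    if not str(path):
        raise OSError("cannot write summary: empty output path")

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default) + "\n")


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA (used by the fixture generator)."""
    lines = []
    for sid, x in zip(alignment.ids, range(alignment.n)):
        lines.append(f">{sid}")
        lines.append(alignment.row_str(x))
    Path(path).write_text("\n".join(lines) + "\n")
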