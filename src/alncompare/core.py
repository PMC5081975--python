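"""Column-pair similarity, cell categorisation and summary scores.

The comparison treats the two alignments as character matrices P (reference,
n x p) and Q (comparison, n x q) over the same n sequences.  Each residue is
first labelled by its per-row occurrence ("the k-th A in this row") so that
repeated residues are distinguished; two cells are *equivalent* when both are
non-gap and carry the same residue symbol and occurrence label.

The similarity matrix S is the fraction of rows with equivalent cells for
every column pair (p_i, q_j):

    S_ij = (1/n) * sum_x eps(P_xi, Q_xj)

Each reference column i is then matched to the comparison column j that
maximises S_ij, and every cell of the reference is categorised against its
matched comparison cell as one of five mutually exclusive outcomes:

* ``match``         — equal non-gap cells
* ``conserved_gap`` — gap in both alignments
* ``merge``         — gap in the reference, residue in the comparison
* ``split``         — residue in the reference, gap in the comparison
* ``shift``         — unequal non-gap cells (a homology reassignment)

Per-column category proportions form the 5 x p results matrix R, from which
the overall similarity score is derived as the mean match proportion divided
by one minus the mean conserved-gap proportion (conserved gaps are excluded
so that sparse, gappy alignments do not look artificially similar).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np

from .io import Alignment, AlignmentValidationError, GAP, validate_pair


class Category(IntEnum):
    """Cell categories of the dissimilarity classification."""

    MATCH = 1
    CONSERVED_GAP = 2
    MERGE = 3
    SPLIT = 4
    SHIFT = 5


#: Row order of the results matrix and of all category-indexed outputs.
CATEGORY_NAMES = ("match", "conserved_gap", "merge", "split", "shift")


class UndefinedScoreError(AlignmentValidationError):
    """The overall score is undefined (every cell is a conserved gap)."""


@dataclass(frozen=True)
class OccurrenceEncodedAlignment:
    """Alignment with every residue labelled by per-row occurrence.

    ``symbols`` mirrors the alignment's character matrix; ``occ[x, i]`` is k
    when cell (x, i) holds the k-th occurrence (counting non-gap cells left to
    right) of that residue symbol in row x, and 0 for gaps.  Within a row all
    non-gap (symbol, occurrence) pairs are therefore distinct.
    """

    symbols: np.ndarray
    occ: np.ndarray

    @property
    def n(self) -> int:
        return self.symbols.shape[0]

    @property
    def width(self) -> int:
        return self.symbols.shape[1]

    def cell(self, x: int, i: int) -> Optional[tuple[str, int]]:
        """Cell (x, i) as ``(symbol, occurrence)``, or ``None`` for a gap."""
        k = int(self.occ[x, i])
        if k == 0:
            return None
        return (str(self.symbols[x, i]), k)


@dataclass(frozen=True)
class MatchVector:
    """Best comparison column for each reference column.

    ``indices`` holds 0-based comparison column indices; ``tie_flags[i]`` is
    True when the maximum of S along row i was not unique (including all-zero
    rows), so the reported match is the tie-break choice.
    """

    indices: np.ndarray
    tie_flags: np.ndarray


@dataclass(frozen=True)
class ColumnSummaries:
    """Per-reference-column category proportions normalised to occupancy.

    Each proportion is divided by the fraction of cells in that column that
    are not conserved gaps.  Columns consisting entirely of conserved gaps
    have no defined normalised value: ``defined`` is False there and the
    arrays hold NaN.
    """

    match: np.ndarray
    merge: np.ndarray
    split: np.ndarray
    shift: np.ndarray
    defined: np.ndarray


@dataclass(frozen=True)
class ComparisonResult:
    """Bundled result of a pairwise alignment comparison (PAC object)."""

    reference_name: str
    comparison_name: str
    S: np.ndarray
    D: np.ndarray
    R: np.ndarray
    match: MatchVector
    overall_score: float
    column_score: float
    sps: float
    cs: float
    sps_per_column: np.ndarray
    summaries: ColumnSummaries
    cysteine: np.ndarray
    warnings: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @property
    def q(self) -> int:
        return self.S.shape[1]


def encode_occurrences(a: Alignment) -> OccurrenceEncodedAlignment:
    """Label every residue with its per-row occurrence index.

    Example: the row ``A C - A G`` encodes to ``(A,1) (C,1) gap (A,2) (G,1)``.
    """
    n, width = a.chars.shape
    occ = np.zeros((n, width), dtype=np.int32)
    for x in range(n):
        counts: dict[str, int] = {}
        row = a.chars[x]
        for i in range(width):
            c = row[i]
            if c == GAP:
                continue
            k = counts.get(c, 0) + 1
            counts[c] = k
            occ[x, i] = k
    return OccurrenceEncodedAlignment(symbols=a.chars, occ=occ)


def cell_equivalent(
    a: Optional[tuple[str, int]], b: Optional[tuple[str, int]]
) -> int:
    """1 iff both cells are non-gap and identical in symbol and occurrence.

    Two gaps are *not* equivalent: gap-gap agreement is handled separately as
    the conserved-gap category and never contributes to similarity.
    """
    if a is None or b is None:
        return 0
    return int(a == b)


def _int_codes(
    Penc: OccurrenceEncodedAlignment, Qenc: OccurrenceEncodedAlignment
) -> tuple[np.ndarray, np.ndarray]:
    """Shared integer coding of (symbol, occurrence) cells; 0 encodes a gap."""
    syms = np.union1d(np.unique(Penc.symbols), np.unique(Qenc.symbols))
    sym_idx = {s: k for k, s in enumerate(syms)}
    lut = np.vectorize(sym_idx.get, otypes=[np.int64])
    max_occ = int(max(Penc.occ.max(initial=0), Qenc.occ.max(initial=0))) + 1
    pcodes = np.where(
        Penc.occ > 0, lut(Penc.symbols) * max_occ + Penc.occ, 0
    ).astype(np.int64)
    qcodes = np.where(
        Qenc.occ > 0, lut(Qenc.symbols) * max_occ + Qenc.occ, 0
    ).astype(np.int64)
    return pcodes, qcodes


def similarity_matrix(
    Penc: OccurrenceEncodedAlignment, Qenc: OccurrenceEncodedAlignment
) -> np.ndarray:
    """The p x q similarity matrix S of column-pair equivalence fractions.

    Every entry is a rational with denominator n.  Because occurrence
    encoding makes non-gap cells unique within a row, each row contributes at
    most one count per (reference column, comparison column) pair, and the
    whole matrix is accumulated in O(n (p + q) log) time rather than by the
    literal O(n p q) triple loop.
    """
    if Penc.n != Qenc.n:
        raise AlignmentValidationError(
            f"row counts differ: {Penc.n} vs {Qenc.n}"
        )
    n, p = Penc.symbols.shape
    q = Qenc.symbols.shape[1]
    pcodes, qcodes = _int_codes(Penc, Qenc)
    counts = np.zeros((p, q), dtype=np.int64)
    for x in range(n):
        pi = np.flatnonzero(pcodes[x])
        qj = np.flatnonzero(qcodes[x])
        _, ip, iq = np.intersect1d(
            pcodes[x, pi], qcodes[x, qj], assume_unique=True, return_indices=True
        )
        np.add.at(counts, (pi[ip], qj[iq]), 1)
    return counts / n


def match_columns(S: np.ndarray) -> MatchVector:
    """Match each reference column to the comparison column maximising S.

    Ties (including all-zero rows of S) are broken by the smallest column
    distance ``|j - i|``, then the smaller j, and flagged in ``tie_flags``.
    """
    p, q = S.shape
    indices = np.empty(p, dtype=int)
    tie_flags = np.zeros(p, dtype=bool)
    for i in range(p):
        row = S[i]
        js = np.flatnonzero(row == row.max())
        if js.size > 1 or row.max() == 0:
            tie_flags[i] = True
        pick = js[np.lexsort((js, np.abs(js - i)))[0]]
        indices[i] = pick
    return MatchVector(indices=indices, tie_flags=tie_flags)


def dissimilarity_matrix(
    Penc: OccurrenceEncodedAlignment,
    Qenc: OccurrenceEncodedAlignment,
    match: MatchVector,
    swap_merge_split: bool = False,
) -> np.ndarray:
    """Categorise every reference cell against its matched comparison cell.

    Returns the n x p category-code matrix D (values from :class:`Category`).
    With the default orientation a ``merge`` is a reference gap aligned to a
    comparison residue (the comparison packed residues into fewer columns)
    and a ``split`` the reverse; ``swap_merge_split`` exchanges the two
    labels for compatibility with conventions that orient them the other way.
    """
    j = match.indices
    psym, pocc = Penc.symbols, Penc.occ
    qsym, qocc = Qenc.symbols[:, j], Qenc.occ[:, j]
    p_res = pocc > 0
    q_res = qocc > 0
    eq = p_res & q_res & (psym == qsym) & (pocc == qocc)
    merge_code = Category.SPLIT if swap_merge_split else Category.MERGE
    split_code = Category.MERGE if swap_merge_split else Category.SPLIT
    codes = np.select(
        [eq, ~p_res & ~q_res, ~p_res & q_res, p_res & ~q_res],
        [Category.MATCH, Category.CONSERVED_GAP, merge_code, split_code],
        default=Category.SHIFT,
    )
    return codes.astype(np.int8)


def results_matrix(D: np.ndarray) -> np.ndarray:
    """Per-column category proportions: the 5 x p results matrix R.

    Row order is match, conserved gap, merge, split, shift; every column sums
    to 1 and every entry is a rational with denominator n.
    """
    n = D.shape[0]
    return np.stack([(D == k).sum(axis=0) for k in Category]) / n


def overall_score(R: np.ndarray) -> float:
    """Overall similarity: mean match proportion over columns, excluding
    conserved gaps from the denominator.

        score = mean_i(R_match,i) / (1 - mean_i(R_gap,i))

    Since the five category proportions are exhaustive, the denominator is
    evaluated as the summed mass of the four non-conserved-gap categories —
    identical in exact arithmetic, and numerically stable: a comparison where
    every non-conserved-gap cell matches scores exactly 1.  Raises
    :class:`UndefinedScoreError` when every cell of both alignments is a
    conserved gap.
    """
    matched = R[0].sum()
    denom = matched + R[2].sum() + R[3].sum() + R[4].sum()
    if denom <= 0:
        raise UndefinedScoreError(
            "overall score undefined: the alignments consist entirely of "
            "conserved gaps"
        )
    return float(matched / denom)


def _overall_score_from_categories(D: np.ndarray) -> float:
    """Integer-exact evaluation of the overall score from category codes."""
    cells = D.size
    matches = int((D == Category.MATCH).sum())
    gaps = int((D == Category.CONSERVED_GAP).sum())
    if gaps >= cells:
        raise UndefinedScoreError(
            "overall score undefined: the alignments consist entirely of "
            "conserved gaps"
        )
    return matches / (cells - gaps)


def column_score(D: np.ndarray) -> float:
    """Fraction of reference columns reproduced perfectly by their matched
    comparison column (every cell a match or a conserved gap)."""
    perfect = np.isin(D, (Category.MATCH, Category.CONSERVED_GAP)).all(axis=0)
    return float(perfect.mean())


def per_column_summaries(R: np.ndarray) -> ColumnSummaries:
    """Normalise the match/merge/split/shift rows of R by column occupancy.

    The normaliser is ``1 - R_gap,i``, the proportion of cells that are not
    conserved gaps, evaluated as the summed mass of the other four categories
    (identical by exhaustiveness, and exact when a column is all matches);
    columns where it is zero are flagged undefined.
    """
    denom = R[0] + R[2] + R[3] + R[4]
    defined = denom > 0
    safe = np.where(defined, denom, np.nan)
    return ColumnSummaries(
        match=R[0] / safe,
        merge=R[2] / safe,
        split=R[3] / safe,
        shift=R[4] / safe,
        defined=defined,
    )


def cysteine_proportion(a: Alignment) -> np.ndarray:
    """Per-column proportion of cells holding the literal symbol ``C``.

    Intended for protein alignments of cysteine-rich families, where
    alignment quality tracks the conserved cysteine scaffold.  On nucleotide
    alignments this simply reports the cytosine fraction.
    """
    return (a.chars == "C").sum(axis=0) / a.n


def compare_alignments(
    reference: Alignment,
    comparison: Alignment,
    swap_merge_split: bool = False,
) -> ComparisonResult:
    """Run the full pairwise alignment comparison and assemble the PAC object.

    Validates that the two alignments hold the same ungapped sequences
    (pairing rows by id, falling back to content), computes S, the column
    matching, D, R, the overall and column scores, the per-column summaries,
    the cysteine track, and the classical sum-of-pairs / total column scores.
    """
    from .pairscores import sum_of_pairs

    validation = validate_pair(reference, comparison)
    comp = comparison.reorder(validation.row_order)
    Penc = encode_occurrences(reference)
    Qenc = encode_occurrences(comp)
    S = similarity_matrix(Penc, Qenc)
    match = match_columns(S)
    D = dissimilarity_matrix(Penc, Qenc, match, swap_merge_split=swap_merge_split)
    R = results_matrix(D)
    score = _overall_score_from_categories(D)
    cscore = column_score(D)
    summaries = per_column_summaries(R)
    pair = sum_of_pairs(reference, comp, row_order=np.arange(reference.n))
    return ComparisonResult(
        reference_name=reference.name or "reference",
        comparison_name=comparison.name or "comparison",
        S=S,
        D=D,
        R=R,
        match=match,
        overall_score=score,
        column_score=cscore,
        sps=pair.sps_overall,
        cs=pair.cs_overall,
        sps_per_column=pair.sps_per_column,
        summaries=summaries,
        cysteine=cysteine_proportion(reference),
        warnings=validation.warnings,
    )
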