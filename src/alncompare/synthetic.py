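"""Deterministic generation of alignment pairs with known expected outcomes.

The generator builds a reference alignment (random, or from user-supplied
ungapped sequences) and derives a comparison alignment by applying a chain of
*perturbations* — edits that re-arrange gaps but never alter any row's
ungapped sequence, so the pair always validates:

* ``insert_gap_column`` — insert an all-gap column.
* ``split_column``     — spread one column's residues over two columns.
* ``merge_columns``    — pack residues from one column into another's gaps.
* ``shift_block``      — slide a block of residues sideways into gap space.
* ``translocate_rows`` — displace entire sequences to the right, as an
  aligner mis-anchoring a subfamily would.

For perturbation chains whose effects are local and non-interacting the
expected per-category cell counts and overall score of the comparison are
predicted analytically, giving fixtures with known ground truth; chains whose
outcome cannot be predicted safely yield ``expected=None`` and are still
usable for oracle-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import GAP, Alignment
from .core import CATEGORY_NAMES, Category

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

PERTURBATION_KINDS = (
    "insert_gap_column",
    "split_column",
    "merge_columns",
    "shift_block",
    "translocate_rows",
)


class PerturbationError(ValueError):
    """A perturbation cannot be applied to the alignment's geometry."""


@dataclass(frozen=True)
class Perturbation:
    """One gap-rearranging edit.  All indices are 0-based.

    Parameter use by kind:

    * ``insert_gap_column`` — ``position`` (0..width).
    * ``split_column``     — ``column``, ``rows`` (rows whose residue moves
      into a freshly inserted column directly right of ``column``).
    * ``merge_columns``    — ``source``, ``target``, ``rows`` (each row must
      hold a residue at ``source`` and a gap at ``target``).
    * ``shift_block``      — ``rows``, ``start``, ``stop`` (inclusive),
      ``offset`` (signed; destination cells must be gaps).
    * ``translocate_rows`` — ``rows``, ``offset`` (> 0; the alignment is
      widened by ``offset`` gap columns on the right).
    """

    kind: str
    rows: tuple[int, ...] = ()
    column: Optional[int] = None
    source: Optional[int] = None
    target: Optional[int] = None
    start: Optional[int] = None
    stop: Optional[int] = None
    offset: int = 0
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise PerturbationError(
                f"unknown perturbation kind {self.kind!r}; "
                f"expected one of {PERTURBATION_KINDS}"
            )
        object.__setattr__(self, "rows", tuple(int(r) for r in self.rows))

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for key in ("rows", "column", "source", "target", "start", "stop",
                    "position"):
            v = getattr(self, key)
            if v is not None and v != ():
                d[key] = list(v) if isinstance(v, tuple) else v
        if self.kind in ("shift_block", "translocate_rows"):
            d["offset"] = self.offset
        return d


@dataclass(frozen=True)
class ExpectedOutcome:
    """Analytically predicted comparison outcome for a fixture pair."""

    category_counts: dict[str, int]
    overall_score: float


@dataclass(frozen=True)
class FixturePair:
    """A reference/comparison pair plus its predicted outcome (when known)."""

    reference: Alignment
    comparison: Alignment
    perturbations: tuple[Perturbation, ...]
    expected: Optional[ExpectedOutcome]
    seed: Optional[int] = None


def _check_rows(rows: Sequence[int], n: int, kind: str) -> tuple[int, ...]:
    rows = tuple(int(r) for r in rows)
    if not rows:
        raise PerturbationError(f"{kind}: no rows given")
    if len(set(rows)) != len(rows):
        raise PerturbationError(f"{kind}: duplicate rows")
    for r in rows:
        if not 0 <= r < n:
            raise PerturbationError(f"{kind}: row {r} out of range (n={n})")
    return rows


def apply_perturbation(alignment: Alignment, pert: Perturbation) -> Alignment:
    """Apply one perturbation, returning a new alignment.

    Raises :class:`PerturbationError` when the edit does not fit the
    alignment's geometry or would reorder a row's residues.
    """
    chars = alignment.chars.copy()
    n, width = chars.shape
    kind = pert.kind

    if kind == "insert_gap_column":
        pos = int(pert.position if pert.position is not None else width)
        if not 0 <= pos <= width:
            raise PerturbationError(f"insert position {pos} out of range")
        new = np.insert(chars, pos, GAP, axis=1)

    elif kind == "split_column":
        c = int(pert.column) if pert.column is not None else None
        if c is None or not 0 <= c < width:
            raise PerturbationError(f"split column {pert.column} out of range")
        rows = _check_rows(pert.rows, n, kind)
        for x in rows:
            if chars[x, c] == GAP:
                raise PerturbationError(
                    f"split_column: row {x} has a gap at column {c}"
                )
        new = np.insert(chars, c + 1, GAP, axis=1)
        for x in rows:
            new[x, c + 1] = new[x, c]
            new[x, c] = GAP

    elif kind == "merge_columns":
        s, t = pert.source, pert.target
        if s is None or t is None or not (0 <= s < width and 0 <= t < width):
            raise PerturbationError("merge_columns: source/target out of range")
        if s == t:
            raise PerturbationError("merge_columns: source equals target")
        rows = _check_rows(pert.rows, n, kind)
        new = chars
        for x in rows:
            if new[x, s] == GAP:
                raise PerturbationError(
                    f"merge_columns: row {x} has a gap at source column {s}"
                )
            if new[x, t] != GAP:
                raise PerturbationError(
                    f"merge_columns: row {x} target column {t} is occupied"
                )
            new[x, t] = new[x, s]
            new[x, s] = GAP

    elif kind == "shift_block":
        start, stop, off = pert.start, pert.stop, int(pert.offset)
        if start is None or stop is None or not (0 <= start <= stop < width):
            raise PerturbationError("shift_block: bad column range")
        if off == 0:
            raise PerturbationError("shift_block: zero offset")
        rows = _check_rows(pert.rows, n, kind)
        new = chars
        for x in rows:
            cols = [i for i in range(start, stop + 1) if new[x, i] != GAP]
            moved = [(i, new[x, i]) for i in cols]
            for i, _ in moved:
                if not 0 <= i + off < width:
                    raise PerturbationError(
                        f"shift_block: destination of column {i} out of range"
                    )
            for i, _ in moved:
                new[x, i] = GAP
            for i, ch in moved:
                if new[x, i + off] != GAP:
                    raise PerturbationError(
                        f"shift_block: destination cell ({x}, {i + off}) is occupied"
                    )
                new[x, i + off] = ch

    elif kind == "translocate_rows":
        off = int(pert.offset)
        if off <= 0:
            raise PerturbationError("translocate_rows: offset must be positive")
        rows = _check_rows(pert.rows, n, kind)
        new = np.concatenate(
            [chars, np.full((n, off), GAP, dtype="<U1")], axis=1
        )
        for x in rows:
            new[x, off:] = chars[x, :]
            new[x, :off] = GAP

    result = Alignment(ids=alignment.ids, chars=new, name=alignment.name)
    if result.degapped() != alignment.degapped():
        raise PerturbationError(
            f"{kind}: perturbation would reorder residues within a row"
        )
    return result


def random_alignment(
    rng: np.random.Generator,
    n: int = 8,
    width: int = 30,
    alphabet: str = PROTEIN_ALPHABET,
    gap_fraction: float = 0.15,
    cysteine_columns: Sequence[int] = (),
    dense_rows: Sequence[int] = (),
    name: str = "reference",
) -> Alignment:
    """Sample a random alignment.

    ``cysteine_columns`` pins whole columns to ``C`` (a cysteine scaffold, as
    in cysteine-rich protein families); ``dense_rows`` forces the listed rows
    to be gap-free.  Every row is guaranteed at least one residue.
    """
    letters = np.array(list(alphabet), dtype="<U1")
    chars = letters[rng.integers(0, len(letters), size=(n, width))]
    gaps = rng.random((n, width)) < gap_fraction
    chars[gaps] = GAP
    for c in cysteine_columns:
        chars[:, c] = "C"
    for x in dense_rows:
        row_gaps = chars[x] == GAP
        chars[x, row_gaps] = letters[rng.integers(0, len(letters), row_gaps.sum())]
    for x in range(n):
        if (chars[x] == GAP).all():
            chars[x, rng.integers(width)] = letters[rng.integers(len(letters))]
    ids = tuple(f"seq{i + 1}" for i in range(n))
    return Alignment(ids=ids, chars=chars, name=name)


def random_regap(
    rng: np.random.Generator,
    alignment: Alignment,
    extra_columns: int = 3,
    name: str = "comparison",
) -> Alignment:
    """Re-distribute every row's gaps at random, preserving ungapped content.

    Produces an arbitrary alternative alignment of the same sequences — the
    worst-case input for the comparison machinery, used for oracle testing.
    """
    seqs = alignment.degapped()
    min_width = max(len(s) for s in seqs)
    new_width = max(min_width, alignment.width) + int(rng.integers(0, extra_columns + 1))
    chars = np.full((alignment.n, new_width), GAP, dtype="<U1")
    for x, seq in enumerate(seqs):
        pos = np.sort(rng.choice(new_width, size=len(seq), replace=False))
        chars[x, pos] = list(seq)
    return Alignment(ids=alignment.ids, chars=chars, name=name)


# ---------------------------------------------------------------------------
# analytic expectation

def _identity_counts(reference: Alignment) -> dict[Category, int]:
    residues = int((reference.chars != GAP).sum())
    total = reference.n * reference.width
    counts = {cat: 0 for cat in Category}
    counts[Category.MATCH] = residues
    counts[Category.CONSERVED_GAP] = total - residues
    return counts


def _score_from_counts(counts: dict[Category, int], n: int, p: int) -> float:
    cells = n * p
    return counts[Category.MATCH] / (cells - counts[Category.CONSERVED_GAP])


def _predict_translocation(
    reference: Alignment, pert: Perturbation
) -> Optional[dict[Category, int]]:
    """Expected counts for a lone translocation.

    Valid when, at every reference column, the residues of the sequences left
    in place are at least as numerous as the displaced residues arriving
    there, so that the column matching stays on the identity diagonal.
    """
    chars = reference.chars
    n, p = chars.shape
    rows = set(pert.rows)
    off = pert.offset
    others = np.array([x for x in range(n) if x not in rows], dtype=int)
    res = chars != GAP
    r_i = res[others].sum(axis=0)  # anchoring residues per column
    # residues of translocated rows that land back inside the reference window
    t_land = np.zeros(p, dtype=int)
    if p > off:
        t_land[off:] = res[sorted(rows)][:, : p - off].sum(axis=0)
    # matching must stay identity: anchors >= arriving displaced residues
    if (r_i < t_land).any():
        return None
    counts = _identity_counts(reference)
    for x in rows:
        for i in range(p):
            ref_res = res[x, i]
            comp_res = i >= off and res[x, i - off]
            if ref_res:
                counts[Category.MATCH] -= 1
                counts[Category.SHIFT if comp_res else Category.SPLIT] += 1
            else:
                if comp_res:
                    counts[Category.CONSERVED_GAP] -= 1
                    counts[Category.MERGE] += 1
    return counts


def predict_expected(
    reference: Alignment, perturbations: Sequence[Perturbation]
) -> Optional[ExpectedOutcome]:
    """Predict category counts and overall score for a perturbation chain.

    Predictions are made only when they are provably safe: the perturbations
    must touch pairwise-disjoint sets of reference columns, and any edit
    whose outcome would hinge on fragile argmax tie-breaking (in combination
    with column insertions elsewhere) yields ``None`` instead.  ``None``
    means "not predicted", never "no difference".
    """
    chars = reference.chars
    n, p = chars.shape
    res = chars != GAP
    counts = _identity_counts(reference)

    real = [pt for pt in perturbations if pt.kind != "insert_gap_column"]
    width_changing = any(
        pt.kind in ("insert_gap_column", "split_column") for pt in perturbations
    )

    if not real:
        return ExpectedOutcome(
            category_counts={CATEGORY_NAMES[c - 1]: v for c, v in counts.items()},
            overall_score=_score_from_counts(counts, n, p),
        )

    translocations = [pt for pt in real if pt.kind == "translocate_rows"]
    if translocations:
        if len(perturbations) != 1:
            return None
        predicted = _predict_translocation(reference, translocations[0])
        if predicted is None:
            return None
        return ExpectedOutcome(
            category_counts={CATEGORY_NAMES[c - 1]: v for c, v in predicted.items()},
            overall_score=_score_from_counts(predicted, n, p),
        )

    # column insertions move comparison indices; later perturbation parameters
    # refer to post-insertion coordinates, so track which current columns are
    # synthetic and map the rest back to reference columns
    synthetic: list[int] = []

    def _record_insert(pos: int) -> None:
        for k, v in enumerate(synthetic):
            if v >= pos:
                synthetic[k] = v + 1
        synthetic.append(pos)

    def _to_ref(col: int) -> Optional[int]:
        if col in synthetic:
            return None
        return col - sum(1 for v in synthetic if v < col)

    if width_changing and (~res).all(axis=0).any():
        # all-gap reference columns tie-match by index, which insertions
        # elsewhere can re-aim; too fragile to predict
        return None

    touched: set[int] = set()
    for pt in perturbations:
        if pt.kind == "insert_gap_column":
            _record_insert(pt.position if pt.position is not None else p + len(synthetic))
            continue

        if pt.kind == "split_column":
            c = _to_ref(int(pt.column))
            if c is None:
                return None
            m = len(pt.rows)
            r = int(res[:, c].sum()) - m
            if r < 0 or {c} & touched:
                return None
            touched.add(c)
            moved = min(m, r)
            counts[Category.MATCH] -= moved
            counts[Category.SPLIT] += moved
            _record_insert(int(pt.column) + 1)

        elif pt.kind == "merge_columns":
            s, t = _to_ref(int(pt.source)), _to_ref(int(pt.target))
            if s is None or t is None or {s, t} & touched:
                return None
            m = len(pt.rows)
            remaining = int(res[:, s].sum()) - m
            r_target = int(res[:, t].sum())
            if remaining < m or (remaining == m and width_changing):
                return None
            if r_target == 0 and width_changing:
                return None
            touched.update({s, t})
            counts[Category.MATCH] -= m
            counts[Category.SPLIT] += m
            counts[Category.CONSERVED_GAP] -= m
            counts[Category.MERGE] += m

        elif pt.kind == "shift_block":
            if width_changing:
                return None  # destination columns tie-match by index
            start, stop, off = int(pt.start), int(pt.stop), int(pt.offset)
            w = stop - start + 1
            if abs(off) < w:  # source and destination must not overlap
                return None
            block_cols = set(range(start, stop + 1))
            dest_cols = set(range(start + off, stop + off + 1))
            if (block_cols | dest_cols) & touched:
                return None
            rows = list(pt.rows)
            m = len(rows)
            if not res[rows][:, sorted(block_cols)].all():
                return None  # block must be fully occupied for the rows moved
            if res[:, sorted(dest_cols)].any():
                return None  # destination must be all-gap columns
            r_c = res[:, sorted(block_cols)].sum(axis=0) - m
            if (r_c < m).any():
                return None
            touched.update(block_cols | dest_cols)
            counts[Category.MATCH] -= m * w
            counts[Category.SPLIT] += m * w
            counts[Category.CONSERVED_GAP] -= m * w
            counts[Category.MERGE] += m * w

    if counts[Category.CONSERVED_GAP] >= n * p:
        return None
    return ExpectedOutcome(
        category_counts={CATEGORY_NAMES[c - 1]: v for c, v in counts.items()},
        overall_score=_score_from_counts(counts, n, p),
    )


def generate_pair(
    base_sequences: Optional[Sequence[str]] = None,
    *,
    n: int = 8,
    length: int = 30,
    alphabet: str = PROTEIN_ALPHABET,
    gap_fraction: float = 0.15,
    cysteine_columns: Sequence[int] = (),
    dense_rows: Sequence[int] = (),
    perturbations: Sequence[Perturbation] = (),
    seed: int = 0,
) -> FixturePair:
    """Build a reference/comparison fixture pair.

    Either supply ``base_sequences`` (ungapped strings; padded with trailing
    gaps into the reference) or sampler parameters for a random reference.
    The comparison starts as a copy of the reference and has the perturbation
    chain applied in order.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if base_sequences is not None:
        seqs = [s.upper().replace("-", "") for s in base_sequences]
        width = max(len(s) for s in seqs)
        rows = [s + GAP * (width - len(s)) for s in seqs]
        ids = [f"seq{i + 1}" for i in range(len(rows))]
        reference = Alignment.from_rows(ids, rows, name="reference")
    else:
        reference = random_alignment(
            rng,
            n=n,
            width=length,
            alphabet=alphabet,
            gap_fraction=gap_fraction,
            cysteine_columns=cysteine_columns,
            dense_rows=dense_rows,
        )
    comparison = Alignment(
        ids=reference.ids, chars=reference.chars.copy(), name="comparison"
    )
    for pt in perturbations:
        comparison = apply_perturbation(comparison, pt)
    expected = predict_expected(reference, perturbations)
    return FixturePair(
        reference=reference,
        comparison=comparison,
        perturbations=tuple(perturbations),
        expected=expected,
        seed=seed,
    )
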