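"""Classical sum-of-pairs (SPS) and total column score (CS).

These are the standard benchmark-style agreement measures between two
alignments of the same sequences, computed independently of the column
matching machinery in :mod:`alncompare.core`:

* SPS — the fraction of within-column residue pairs of the reference that
  co-occur in a single column of the comparison.  Residue instances are
  identified by their ungapped position in the sequence; gap cells never form
  pairs, and columns with fewer than two residues contribute no pairs.
* CS — the fraction of reference columns whose full content (residue
  instances plus gap placement across all rows) is reproduced identically by
  some single comparison column.  All-gap reference columns carry no content
  and count as reproduced, so CS is 1 exactly when the two alignments are
  identical up to insertion or removal of all-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import Alignment, GAP, validate_pair


@dataclass(frozen=True)
class PairScoreResult:
    """Sum-of-pairs and total column score between two alignments.

    ``sps_per_column[i]`` is the retained-pair fraction of reference column i
    (NaN when the column holds fewer than two residues).
    """

    sps_per_column: np.ndarray
    sps_overall: float
    cs_overall: float


def _comparison_columns(reference: Alignment, comparison: Alignment) -> np.ndarray:
    """For each reference cell, the comparison column holding the same residue
    instance (-1 at reference gaps).  Instances correspond by ungapped
    position, which validate_pair guarantees is well defined."""
    n, p = reference.chars.shape
    ref_res = reference.chars != GAP
    comp_res = comparison.chars != GAP
    uidx = np.cumsum(ref_res, axis=1) - 1  # ungapped position of each ref cell
    C = np.full((n, p), -1, dtype=np.int64)
    for x in range(n):
        cols_q = np.flatnonzero(comp_res[x])
        mask = ref_res[x]
        C[x, mask] = cols_q[uidx[x, mask]]
    return C


def sum_of_pairs(
    reference: Alignment,
    comparison: Alignment,
    row_order: Optional[Sequence[int]] = None,
) -> PairScoreResult:
    """Compute SPS and CS of ``comparison`` against ``reference``.

    ``row_order`` may carry a precomputed row correspondence (as produced by
    :func:`alncompare.io.validate_pair`); otherwise the pair is validated
    here.  A reference column's residue pair is *retained* when the same two
    residue instances share a column of the comparison.
    """
    if row_order is None:
        row_order = validate_pair(reference, comparison).row_order
    comp = comparison.reorder(row_order)
    n, p = reference.chars.shape
    C = _comparison_columns(reference, comp)
    comp_res = comp.chars != GAP

    per_col = np.full(p, np.nan)
    total_pairs = 0
    retained_pairs = 0
    cs_hits = 0
    for i in range(p):
        c = C[:, i]
        c = c[c >= 0]
        m = c.size
        pairs = m * (m - 1) // 2
        if pairs:
            _, counts = np.unique(c, return_counts=True)
            kept = int((counts * (counts - 1) // 2).sum())
            per_col[i] = kept / pairs
            total_pairs += pairs
            retained_pairs += kept
        # total column score: all residues land in one comparison column whose
        # gap pattern mirrors the reference column's
        if m == 0:
            cs_hits += 1
        else:
            uniq = np.unique(c)
            if uniq.size == 1:
                j = int(uniq[0])
                if np.array_equal(comp_res[:, j], C[:, i] >= 0):
                    cs_hits += 1
    sps = retained_pairs / total_pairs if total_pairs else float("nan")
    return PairScoreResult(
        sps_per_column=per_col,
        sps_overall=float(sps),
        cs_overall=cs_hits / p,
    )


def plot_sps(result: PairScoreResult, ax=None):
    """Line plot of per-column sum-of-pairs retention over reference columns.

    Columns without a defined value (fewer than two residues) appear as
    breaks in the line.  Delegates to :func:`alncompare.viz.plot_sps`.
    """
    from .viz import plot_sps as _plot

    return _plot(result, ax=ax)
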