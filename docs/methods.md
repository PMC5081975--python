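# Methods

## The comparison model

`alncompare` quantifies the agreement between two alternative multiple
sequence alignments (MSAs) of the same n sequences: a *reference* P (n × p)
and a *comparison* Q (n × q).  There is no objective function for the
biological truth of an alignment, so the package measures consensus and
categorises disagreement rather than judging correctness.

**Occurrence encoding.**  Every residue is labelled by its symbol plus how
many times that symbol has already appeared in its row, counting non-gap
cells left to right: the row `A C - A G` becomes `(A,1) (C,1) · (A,2) (G,1)`.
Within a row every non-gap cell is then unique, so a column that aligns the
*second* alanine of a sequence where the reference has the *first* is
correctly scored as disagreement.  Two encoded cells are *equivalent* when
both are non-gap and identical in symbol and occurrence; two gaps are never
equivalent (gap agreement is handled separately, below).

**Similarity matrix.**  For every column pair (p_i, q_j),

    S_ij = (1/n) · Σ_x ε(P_xi, Q_xj),

the fraction of rows with equivalent cells.  Every entry is a rational with
denominator n.  Each reference column i is matched to the comparison column
j* = argmax_j S_ij.

**Dissimilarity categories.**  Each reference cell, paired with its row's
cell in the matched comparison column, falls in exactly one of five
categories:

| category       | reference cell | comparison cell        |
|----------------|----------------|------------------------|
| match          | residue r      | the same residue instance |
| conserved gap  | gap            | gap                    |
| merge          | gap            | residue                |
| split          | residue        | gap                    |
| shift          | residue        | a different residue instance |

A *merge* means the comparison packed residues into fewer columns than the
reference; a *split* the reverse; a *shift* is a homology reassignment.
The category codes form the n × p matrix D; per-column category proportions
form the 5 × p results matrix R (each column of R sums to 1).

**Scores.**

* overall score = mean match proportion / (1 − mean conserved-gap
  proportion).  Conserved gaps are excluded from the denominator so that
  sparse, gappy alignments do not look artificially similar.
* column score = fraction of reference columns whose every cell is a match
  or conserved gap against the matched column.
* SPS (sum of pairs score) = fraction of within-column residue pairs of the
  reference that co-occur in a single comparison column; CS (total column
  score) = fraction of reference columns reproduced identically (residue
  instances and gap pattern) by some single comparison column.  SPS/CS are
  the classical benchmark measures and are computed independently of the
  argmax matching, so `column_score` (matched-column variant) and
  `cs` (classical variant) are both reported, under distinct names.

## Parameters that matter

* **Tie-breaking of the column match** (the argmax over S): smallest
  |j − i| first, then smallest j.  Ties — including all-zero rows of S,
  which still receive a match so that D is total — are flagged in
  `MatchVector.tie_flags` for auditing.  Any reasonable tie rule gives the
  same scores on non-degenerate data; the flags mark where it mattered.
* **Merge/split orientation** (`swap_merge_split`, default off): the
  default orientation is the one described above; the switch exchanges the
  two labels for compatibility with conventions that orient them from the
  comparison's point of view.
* **Gap normalisation**: `-`, `.` and `~` are all accepted on input and
  unified to `-`; residues are uppercased.  Comparison is case-insensitive.
* **Row pairing**: by identifier when the two id sets agree, otherwise by
  unique ungapped sequence content (with a warning); ambiguity is a hard
  error rather than a guess.
* **Cysteine track** (`cysteine_proportion`): per-column fraction of literal
  `C`, intended for cysteine-rich protein families where alignment quality
  tracks the conserved scaffold.  On nucleotide alignments it reports the
  cytosine fraction — documented caveat, not an error.

## Numerical choices

* S and R entries are rationals with denominator n, computed as integer
  counts divided once by n; tests compare them exactly, not to a tolerance.
* The overall score is evaluated from integer category counts
  (matches / (cells − conserved gaps)), and the normalised per-column
  summaries divide by the summed mass of the four non-conserved-gap
  categories rather than literally by 1 − R₂ᵢ.  Both are identical to the
  defining formulas in exact arithmetic (the categories are exhaustive) and
  guarantee that a self-comparison scores exactly 1.0 in floating point.
* Columns consisting entirely of conserved gaps have undefined normalised
  summaries: they are flagged, reported as NaN, and drawn as breaks in the
  summary plots.  An alignment pair consisting *only* of conserved gaps has
  an undefined overall score and raises `UndefinedScoreError`.
* Computing S by the literal triple loop is O(n·p·q).  Because occurrence
  encoding makes cells unique within a row, each row contributes at most one
  count per column pair, and S is accumulated row-wise by intersecting the
  two rows' encoded cell sets — O(n·(p+q)·log) — before a single division
  by n.  A 1000 × 1000 vs 1000-sequence comparison runs in seconds on one
  CPU.  The exhaustive-loop formulation survives as the test oracle.
* Column indices in all CSV/JSON outputs and figures are 1-based (the
  convention of alignment viewers); the Python API is 0-based.

## The synthetic generator

`alncompare.synthetic` builds alignment pairs with known ground truth: a
reference (random over a protein or nucleotide alphabet, with optional
pinned all-cysteine scaffold columns and per-row density control) and a
comparison derived by gap-rearranging perturbations — column splits, merges,
block shifts, whole-sequence translocations, gap-column insertions — each of
which provably preserves every row's ungapped sequence (a perturbation that
would reorder residues is rejected).  `random_regap` additionally produces a
completely arbitrary re-gapping, the worst-case alternative alignment.

For perturbation chains whose effects are local and provably
non-interacting — pairwise-disjoint affected reference columns, no reliance
on argmax tie-breaking in combination with column insertions, translocation
only on its own and only when every column keeps at least as many anchoring
residues as displaced ones — the per-category cell counts and overall score
are predicted analytically and carried with the fixture.  Chains that cannot
be predicted safely are marked unpredicted rather than guessed, and tests
fall back to the brute-force oracle.

What the generator emulates: the disagreement taxonomy itself (merged
inter-cysteine regions, split scaffold columns, translocated subfamilies)
under controlled geometry.  What it does not emulate: realistic residue
composition, phylogenetic correlation between sequences, or aligner-specific
error patterns.  Passing tests therefore demonstrate that the statistics are
computed exactly as defined for any geometry of disagreement, not that any
particular aligner behaves one way or another on real data.

## Problem sizes used in the checks

The oracle-equivalence suite runs 500 random pairs at n ≤ 6, width ≤ 8 over
a 4-letter alphabet (small enough for exhaustive enumeration to be
obviously correct); the identity law runs 100 random self-comparisons; the
capacity check runs one 1000-sequence × 1000-column perturbed comparison,
which completes in a few seconds.  The demonstration pair used by
`scripts/acceptance.py` has 32 sequences × 48 columns with a six-column
cysteine scaffold, gap fraction 0.15, a compact four-sequence subfamily
translocated four columns to the right, one split scaffold column, and four
adaptive merges and shifts — severities chosen to echo the disagreement
patterns the method is designed to expose while leaving all summary
statistics informative (a full-width translocation would pin both column
scores at zero).

## Known limitations

* Strictly pairwise: no many-vs-many comparison orchestration.
* No statistical significance testing of scores, and no alignment
  construction or refinement.
* The SPS overall mean is undefined (NaN) when no reference column holds
  two or more residues.
* The classical CS counts all-gap reference columns as trivially
  reproduced, so CS equals 1 exactly when the alignments are identical up
  to insertion or removal of all-gap columns.
* Figures are drawn for interpretation, not pixel-specified: tests assert
  the plotted data arrays and legends, and the palette (colour-blind-safe
  five-colour categorical, shared between the D heatmap and the stacked
  summary) is configurable rather than normative.
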