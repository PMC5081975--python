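# alncompare

Statistical comparison of alternative multiple sequence alignments.

Different alignment algorithms make different homology predictions for the
same sequences — especially for families with many insertions and deletions,
such as cysteine-rich proteins — and downstream phylogenetics or structure
modelling inherits those choices.  `alncompare` takes two alignments of the
same sequences, a *reference* P (n × p) and a *comparison* Q (n × q), and
quantifies exactly where and how they agree:

1. Every residue is labelled by per-row **occurrence** (`A C - A G` →
   `(A,1) (C,1) · (A,2) (G,1)`), so repeated residues are distinguished.
2. The **similarity matrix** S_ij = (1/n) Σ_x ε(P_xi, Q_xj) gives, for every
   column pair, the fraction of rows whose cells are equivalent (same
   residue, same occurrence, neither a gap).
3. Each reference column is matched to the comparison column maximising
   S_ij, and every cell is categorised as **match**, **conserved gap**,
   **merge** (reference gap vs comparison residue), **split** (reference
   residue vs comparison gap) or **shift** (two different residues) — the
   n × p dissimilarity matrix D, summarised per column in the 5 × p results
   matrix R.
4. Summary scores: the **overall score**, the mean match proportion over
   columns divided by one minus the mean conserved-gap proportion (conserved
   gaps are excluded so gappy alignments do not look artificially similar);
   a stricter **column score** (fraction of perfectly reproduced columns);
   and the classical **sum-of-pairs score** (SPS) and **total column score**
   (CS).
5. Four standard figures: similarity heatmap, categorical D heatmap,
   normalised per-column match line (optional cysteine-proportion track),
   and a stacked merge/split/shift area plot, plus a per-column SPS plot.

Input formats: FASTA, Clustal, MSF, Phylip (auto-detected or explicit).
Rows are paired by identifier, falling back to ungapped sequence content.

## Worked example

Two alignments of the sequences `ACG` and `AG`:

```
reference        comparison
s1  A C G        s1  A C G
s2  A - G        s2  A G -
```

```sh
alncompare compare ref.fasta comp.fasta --out out --plots none
# overall similarity score: 0.6667
```

`out/S.csv` — the similarity matrix (1-based column labels):

```
,1,2,3
1,1.0,0.0,0.0
2,0.0,0.5,0.0
3,0.0,0.5,0.5
```

Column 1 agrees in both rows (S₁₁ = 1).  Reference column 2 (`C`,`-`) shares
only row 1 with comparison column 2 (S₂₂ = 0.5); reference column 3 (`G`,`G`)
ties between comparison columns 2 and 3 (the tie is resolved towards the
diagonal and reported in `tie_columns`).  `out/D.csv` categorises every
reference cell against its matched column:

```
,1,2,3
s1,match,match,match
s2,match,merge,split
```

Row s2's gap in column 2 faces the comparison's `G` (a *merge*: the
comparison packed the residues more tightly), and its `G` in column 3 faces
a gap (a *split*).  `out/summary.json` collects the scores:

```json
"overall_score": 0.6666666666666666,
"column_score": 0.3333333333333333,
"sum_of_pairs_score": 0.5,
"total_column_score": 0.3333333333333333
```

Four of the six non-conserved-gap cells match (overall score 2/3); only
column 1 is reproduced perfectly (column score 1/3); of the two
within-column residue pairs of the reference, one survives in the
comparison (SPS 0.5).

The same pipeline is available from Python:

```python
from alncompare import read_alignment, compare_alignments
result = compare_alignments(read_alignment("ref.fasta"), read_alignment("comp.fasta"))
result.overall_score   # 0.6666666666666666
result.S, result.D, result.R, result.match
```

## Synthetic fixtures

`alncompare generate` (and `alncompare.synthetic`) builds seeded alignment
pairs with known ground truth: a reference — optionally with pinned
all-cysteine scaffold columns — and a comparison produced by perturbations
(column splits, merges, block shifts, subfamily translocations, gap-column
insertions) that provably preserve every row's ungapped sequence.  For
non-interacting perturbation chains the expected per-category cell counts
and overall score are predicted analytically and written alongside the pair:

```sh
alncompare generate --n 32 --length 48 --cysteine-columns 5,13,21 \
    --perturb 'translocate:rows=29-32,offset=4' --seed 7 --out fixture/
alncompare compare fixture/reference.fasta fixture/comparison.fasta --out out/
```

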