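"""Naive reference implementations used as independent oracles.

Everything here works on plain lists of row strings and uses literal loops
over rows, columns and pairs — no vectorisation and no shared code with the
production package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

GAP = "-"

MATCH, CONSERVED_GAP, MERGE, SPLIT, SHIFT = 1, 2, 3, 4, 5


def encode(rows):
    """Per-row occurrence encoding: (symbol, k) tuples, None for gaps."""
    out = []
    for row in rows:
        seen = {}
        enc = []
        for c in row:
            if c == GAP:
                enc.append(None)
            else:
                seen[c] = seen.get(c, 0) + 1
                enc.append((c, seen[c]))
        out.append(enc)
    return out


def eps(a, b):
    return 1 if (a is not None and b is not None and a == b) else 0


def similarity(P, Q):
    """Triple-loop similarity matrix over encoded alignments."""
    n = len(P)
    p, q = len(P[0]), len(Q[0])
    S = np.zeros((p, q))
    for i in range(p):
        for j in range(q):
            total = 0
            for x in range(n):
                total += eps(P[x][i], Q[x][j])
            S[i, j] = total / n
    return S


def match(S):
    """Argmax per row; ties by smallest |j - i| then smallest j."""
    p, q = S.shape
    out = []
    for i in range(p):
        best = max(S[i])
        candidates = [j for j in range(q) if S[i][j] == best]
        out.append(min(candidates, key=lambda j: (abs(j - i), j)))
    return out


def categories(P, Q, match_vec):
    """Cell-by-cell categorisation of the reference against matched columns."""
    n, p = len(P), len(P[0])
    D = np.zeros((n, p), dtype=int)
    for x in range(n):
        for i in range(p):
            a = P[x][i]
            b = Q[x][match_vec[i]]
            if a is not None and b is not None and a == b:
                D[x, i] = MATCH
            elif a is None and b is None:
                D[x, i] = CONSERVED_GAP
            elif a is None:
                D[x, i] = MERGE
            elif b is None:
                D[x, i] = SPLIT
            else:
                D[x, i] = SHIFT
    return D


def results(D):
    n, p = D.shape
    R = np.zeros((5, p))
    for k in range(1, 6):
        for i in range(p):
            R[k - 1, i] = sum(1 for x in range(n) if D[x, i] == k) / n
    return R


def overall(D):
    """Overall score from the category matrix: matches over all cells that
    are not conserved gaps, as plain integer counting."""
    n, p = D.shape
    matches = gaps = 0
    for x in range(n):
        for i in range(p):
            if D[x, i] == MATCH:
                matches += 1
            elif D[x, i] == CONSERVED_GAP:
                gaps += 1
    return matches / (n * p - gaps)


def column_score(D):
    n, p = D.shape
    good = 0
    for i in range(p):
        if all(D[x, i] in (MATCH, CONSERVED_GAP) for x in range(n)):
            good += 1
    return good / p


def _instance_columns(rows):
    """For each row, map ungapped position -> column index."""
    out = []
    for row in rows:
        cols = [i for i, c in enumerate(row) if c != GAP]
        out.append(cols)
    return out


def sps(ref_rows, comp_rows):
    """Exhaustive sum-of-pairs enumeration over (column, row-pair) combos."""
    n = len(ref_rows)
    p = len(ref_rows[0])
    ref_cols = _instance_columns(ref_rows)
    comp_cols = _instance_columns(comp_rows)
    # ungapped position of each reference cell
    upos = []
    for row in ref_rows:
        u, k = [], 0
        for c in row:
            if c == GAP:
                u.append(None)
            else:
                u.append(k)
                k += 1
        upos.append(u)
    total = retained = 0
    per_col = []
    for i in range(p):
        residents = [x for x in range(n) if ref_rows[x][i] != GAP]
        pairs = kept = 0
        for a in range(len(residents)):
            for b in range(a + 1, len(residents)):
                x, y = residents[a], residents[b]
                pairs += 1
                if comp_cols[x][upos[x][i]] == comp_cols[y][upos[y][i]]:
                    kept += 1
        total += pairs
        retained += kept
        per_col.append(kept / pairs if pairs else None)
    return per_col, (retained / total if total else float("nan"))


def cs(ref_rows, comp_rows):
    """Fraction of reference columns reproduced exactly by one comparison column."""
    n = len(ref_rows)
    p = len(ref_rows[0])
    comp_cols = _instance_columns(comp_rows)
    upos_rows = []
    for row in ref_rows:
        u, k = [], 0
        for c in row:
            if c == GAP:
                u.append(None)
            else:
                u.append(k)
                k += 1
        upos_rows.append(u)
    hits = 0
    for i in range(p):
        residents = [x for x in range(n) if ref_rows[x][i] != GAP]
        if not residents:
            hits += 1
            continue
        target = {comp_cols[x][upos_rows[x][i]] for x in residents}
        if len(target) != 1:
            continue
        j = target.pop()
        comp_residents = [x for x in range(n) if comp_rows[x][j] != GAP]
        if comp_residents == residents:
            hits += 1
    return hits / p
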