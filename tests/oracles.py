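"""Independent oracles used by the test suite.

Everything here is deliberately dumb and kept separate from the library:
rational-arithmetic closed forms for the neutrality statistics, a quadratic
Needleman–Wunsch aligner, and exhaustive/enumerative parsimony scoring.
"""

from fractions import Fraction
import itertools
import math

import numpy as np

MISSING = set("RYSWKMBDHVN-")


def pairwise_diffs_bruteforce(seqs, policy="complete-deletion"):
    """O(n²L) double-loop recount of the pairwise difference matrix."""
    n = len(seqs)
    L = len(seqs[0])
    if policy == "complete-deletion":
        cols = [
            j for j in range(L) if all(s[j] not in MISSING for s in seqs)
        ]
        seqs = ["".join(s[j] for j in cols) for s in seqs]
        L = len(cols)
        mat = [[0] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                mat[i][j] = sum(a != b for a, b in zip(seqs[i], seqs[j]))
        return mat
    mat = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            mat[i][j] = sum(
                a != b
                for a, b in zip(seqs[i], seqs[j])
                if a not in MISSING and b not in MISSING
            )
    return mat


def tajima_d_rational(seqs):
    """Tajima's D via exact rational arithmetic (complete deletion).

    Returns None when undefined (S = 0 or n < 4).
    """
    n = len(seqs)
    cols = list(zip(*[s for s in seqs]))
    cols = [c for c in cols if all(ch not in MISSING for ch in c)]
    S = sum(len(set(c)) > 1 for c in cols)
    if S == 0 or n < 4:
        return None
    ktot = Fraction(0)
    for i in range(n):
        for j in range(i + 1, n):
            ktot += sum(
                1
                for c in cols
                if c[i] != c[j]
            )
    kbar = ktot / (n * (n - 1) // 2)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float(kbar - Fraction(S) / a1) / math.sqrt(float(var))


def r2_rational(seqs):
    """Ramos-Onsins & Rozas R2 via rational arithmetic (complete deletion)."""
    n = len(seqs)
    cols = list(zip(*[s for s in seqs]))
    cols = [c for c in cols if all(ch not in MISSING for ch in c)]
    S = sum(len(set(c)) > 1 for c in cols)
    if S == 0:
        return None
    ktot = Fraction(0)
    for i in range(n):
        for j in range(i + 1, n):
            ktot += sum(1 for c in cols if c[i] != c[j])
    kbar = ktot / (n * (n - 1) // 2)
    U = [0] * n
    for c in cols:
        if len(set(c)) < 2:
            continue
        for i in range(n):
            if sum(1 for ch in c if ch == c[i]) == 1:
                U[i] += 1
    mean_sq = sum((Fraction(u) - kbar / 2) ** 2 for u in U) / n
    return math.sqrt(float(mean_sq)) / S


def needleman_wunsch(a, b, match=1, mismatch=-1, gap=-2):
    """Global alignment score and one optimal pairing (linear gap costs).

    Returns (score, pairs) with pairs a list of (i, j) 0-based index pairs of
    aligned characters.  Tie-break: diagonal > up > left, matching the
    highest-road convention.
    """
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = score[i - 1][j] + gap
            l = score[i][j - 1] + gap
            score[i][j] = max(d, u, l)
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if score[i][j] == d:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif score[i][j] == score[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return score[n][m], pairs


def fitch_length_enumerate(tree_children, tip_states):
    """Minimum number of changes for one site by exhaustive enumeration.

    ``tree_children`` maps internal node id -> (child id, child id); tips map
    to themselves in ``tip_states`` (char or set of chars).  All 4^k internal
    assignments are enumerated with numpy.
    """
    internals = list(tree_children)
    tips = list(tip_states)
    k = len(internals)
    nucs = "ACGT"
    grids = np.indices((4,) * k).reshape(k, -1)  # k × 4^k
    n_assign = grids.shape[1]
    # tip cost: 0 if the tip's observed set contains the state, handled by
    # minimising over the tip's allowed states per assignment
    total = np.zeros(n_assign, dtype=np.int64)
    idx = {nd: i for i, nd in enumerate(internals)}
    for parent, kids in tree_children.items():
        p = grids[idx[parent]]
        for child in kids:
            if child in tree_children:
                total += (grids[idx[child]] != p).astype(np.int64)
            else:
                allowed = set(tip_states[child])
                allowed_idx = np.array([nucs.index(c) for c in allowed])
                # change needed unless parent state is allowed at the tip
                total += (~np.isin(p, allowed_idx)).astype(np.int64)
    return int(total.min())


def fitch_length_pure_python(tree_children, tip_states):
    """Same minimisation via itertools for very small trees (≤ 6 leaves)."""
    internals = list(tree_children)
    nucs = "ACGT"
    best = None
    for assign in itertools.product(nucs, repeat=len(internals)):
        states = dict(zip(internals, assign))
        cost = 0
        for parent, kids in tree_children.items():
            for child in kids:
                if child in tree_children:
                    cost += states[child] != states[parent]
                else:
                    cost += states[parent] not in set(tip_states[child])
        best = cost if best is None else min(best, cost)
    return best


def count_optimal_alignments(a, b, match=1, mismatch=-1, gap=-2):
    """Number of co-optimal global alignments (to certify unique optima)."""
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    C = [[1] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = i * gap
    for j in range(1, m + 1):
        S[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = S[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = S[i - 1][j] + gap
            l = S[i][j - 1] + gap
            best = max(d, u, l)
            S[i][j] = best
            c = 0
            if d == best:
                c += C[i - 1][j - 1]
            if u == best:
                c += C[i - 1][j]
            if l == best:
                c += C[i][j - 1]
            C[i][j] = c
    return C[n][m]
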