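"""Independent hand-written oracles used only by the test suite.

These deliberately avoid the production code paths: alignment scores come
from plain Gotoh dynamic programming written here from the recurrences,
dereplication from a naive matrix-based reimplementation, and tree
monophyly from exhaustive bipartition enumeration by recursive traversal.
Gap semantics match the production scoring: a gap run of length L costs
``open + (L - 1) * extend``.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def _pairmax(*vals):
    """Lexicographic max over (score, tiebreak) pairs."""
    best = vals[0]
    for v in vals[1:]:
        if v > best:
            best = v
    return best


def gotoh_global_endfree(
    a: str,
    b: str,
    gap_open: int = 11,
    gap_extend: int = 1,
    matrix=BLOSUM62,
    ident_sign: int = +1,
):
    """End-gap-free global affine alignment by explicit Gotoh DP.

    Returns ``(score, identities)`` where ``identities`` is the maximum
    (``ident_sign=+1``) or minimum (``ident_sign=-1``) count of identical
    aligned pairs over all co-optimal alignments, found by maximizing the
    pair ``(score, ident_sign * identities)`` lexicographically (both
    objectives are additive, so optimal substructure holds).  Terminal gap
    runs are free.
    """
    n, m = len(a), len(b)
    # Three states per cell: M (residue-residue), X (gap in b), Y (gap in a).
    M = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    Y = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (0.0, 0)  # free leading gap in b
    for j in range(1, m + 1):
        Y[0][j] = (0.0, 0)  # free leading gap in a
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = float(matrix[ai, bj])
            ident = ident_sign if ai == bj else 0
            prev = _pairmax(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (prev[0] + s, prev[1] + ident)
            X[i][j] = _pairmax(
                (M[i - 1][j][0] - gap_open, M[i - 1][j][1]),
                (Y[i - 1][j][0] - gap_open, Y[i - 1][j][1]),
                (X[i - 1][j][0] - gap_extend, X[i - 1][j][1]),
            )
            Y[i][j] = _pairmax(
                (M[i][j - 1][0] - gap_open, M[i][j - 1][1]),
                (X[i][j - 1][0] - gap_open, X[i][j - 1][1]),
                (Y[i][j - 1][0] - gap_extend, Y[i][j - 1][1]),
            )
    # Free trailing gaps: the alignment may stop at the end of either
    # sequence, with the remainder of the other unpenalised.
    best = (NEG, 0)
    for i in range(n + 1):
        best = _pairmax(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = _pairmax(best, M[n][j], X[n][j], Y[n][j])
    return best[0], ident_sign * best[1]


def identity_range(a: str, b: str) -> tuple[float, int, int]:
    """(optimal end-free score, min identities, max identities) over all
    co-optimal global alignments."""
    score_hi, ident_hi = gotoh_global_endfree(a, b, ident_sign=+1)
    score_lo, ident_lo = gotoh_global_endfree(a, b, ident_sign=-1)
    assert score_hi == score_lo
    return score_hi, ident_lo, ident_hi


def gotoh_local(
    a: str, b: str, gap_open: int = 11, gap_extend: int = 1, matrix=BLOSUM62
) -> float:
    """Smith-Waterman optimal local score by explicit affine-gap DP."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = float(matrix[ai, b[j - 1]])
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = prev + s
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                Y[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                X[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
            )
            if M[i][j] > best:
                best = M[i][j]
    return best


def derep_oracle(records, max_identity=85.0, min_len=200, identity_fn=None):
    """Naive dereplication oracle: full identity matrix, then the
    longest-first keep/drop rule applied by explicit iteration.

    The identity function itself is validated separately against the DP
    oracles; this oracle checks the clustering logic.  Returns kept ids in
    input order.
    """
    from rtcrispr.sequence import pairwise_identity

    identity_fn = identity_fn or pairwise_identity
    survivors = [r for r in records if len(r.sequence) >= min_len]
    k = len(survivors)
    matrix = [[0.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if i != j:
                matrix[i][j] = identity_fn(
                    survivors[i].sequence, survivors[j].sequence
                )
    order = sorted(range(k), key=lambda i: (-len(survivors[i].sequence), i))
    kept: list[int] = []
    for i in order:
        drop = False
        for j in kept:
            if matrix[i][j] > max_identity:
                drop = True
        if not drop:
            kept.append(i)
    return [survivors[i].id for i in sorted(kept)]


def tipsets_oracle(node) -> list[frozenset]:
    """Every tip set subtended by a node of the (rooted representation of
    the) tree, by plain recursion — the exhaustive bipartition enumeration
    of the unrooted tree is {side, complement} over these sets."""
    out = []

    def rec(nd) -> frozenset:
        if not nd.children:
            s = frozenset([nd.name])
        else:
            s = frozenset().union(*(rec(c) for c in nd.children))
        out.append(s)
        return s

    rec(node)
    return out


def monophyly_oracle(tree, leafset: frozenset) -> bool:
    """Label monophyletic iff some bipartition side equals the leaf set or
    its complement (exhaustive enumeration)."""
    all_tips = frozenset(t.name for t in tree.tips())
    complement = all_tips - leafset
    for side in tipsets_oracle(tree):
        if side == leafset or side == complement:
            return True
    return False
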