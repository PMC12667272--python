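"""Independent oracles for alignment identity, kept free of package internals.

Two routes:

* ``tuple_dp_stats``: a plain dynamic program over (score, matches,
  -columns) tuples with Python's lexicographic tuple comparison — no
  packing, no vectorisation, structurally unlike the implementation.
* ``enumerate_stats``: exhaustive recursion over *all* alignments
  (feasible for sequences up to ~6 nt), the ground truth the tuple DP is
  itself checked against.

Both use the same alignment convention as the package: match +1,
mismatch -1, gap -2, terminal gaps free and excluded from the column
count, N never a match.
"""

from __future__ import annotations

MATCH, MISMATCH, GAP = 1, -1, -2


def _pair(a: str, b: str) -> tuple[int, int]:
    """(score, is_match) of aligning two residues."""
    if a == b and a != "N":
        return MATCH, 1
    return MISMATCH, 0


def tuple_dp_stats(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, columns), maximising lexicographically
    (score, matches, -columns); free terminal gaps."""
    n, m = len(a), len(b)
    NEG = (-(10**9), 0, 0)
    # dp[i][j]: best (score, matches, -columns) of a path from any free start
    dp = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dp[i][0] = (0, 0, 0)
    for j in range(m + 1):
        dp[0][j] = (0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s, im = _pair(a[i - 1], b[j - 1])
            sc, ma, nc = dp[i - 1][j - 1]
            cand = (sc + s, ma + im, nc - 1)
            for pi, pj in ((i - 1, j), (i, j - 1)):
                sc, ma, nc = dp[pi][pj]
                cand = max(cand, (sc + GAP, ma, nc - 1))
            dp[i][j] = max(dp[i][j], cand)
    best = max(
        [dp[i][m] for i in range(n + 1)] + [dp[n][j] for j in range(m + 1)]
    )
    return best[0], best[1], -best[2]


def enumerate_stats(a: str, b: str) -> tuple[int, int, int]:
    """Ground truth by enumerating every alignment path (tiny inputs only)."""
    n, m = len(a), len(b)
    best = [(-(10**9), 0, 0)]

    def finish(i, j, score, matches, cols):
        # trailing gaps free: stop once either sequence is exhausted
        best[0] = max(best[0], (score, matches, -cols))

    def walk(i, j, score, matches, cols):
        if i == n or j == m:
            finish(i, j, score, matches, cols)
            return
        s, im = _pair(a[i], b[j])
        walk(i + 1, j + 1, score + s, matches + im, cols + 1)
        walk(i + 1, j, score + GAP, matches, cols + 1)
        walk(i, j + 1, score + GAP, matches, cols + 1)

    # free leading gaps: start at any (i, 0) or (0, j)
    for i in range(n + 1):
        walk(i, 0, 0, 0, 0)
    for j in range(1, m + 1):
        walk(0, j, 0, 0, 0)
    score, matches, ncols = best[0]
    return score, matches, -ncols


def oracle_identity(a: str, b: str, min_coverage: float = 0.5) -> float:
    """Identity under the package's convention, from the tuple DP."""
    _, matches, cols = tuple_dp_stats(a, b)
    if cols < min_coverage * min(len(a), len(b)):
        return 0.0
    return matches / cols
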