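"""Independent reference implementations used as test oracles.

These deliberately do not share code with the package: the affine-gap DP is
a from-scratch Gotoh implementation, and enumerate_best_score explores every
alignment of tiny sequences recursively, defining ground truth for the DP
itself.
"""

NEG = float("-inf")


def gotoh_score(a, b, match=1.0, mism=-1.0, go=-4.0, ge=-1.0):
    """Optimal global alignment score; a gap of length L costs
    go + (L-1)*ge."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Iy[0][j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            if j > 0:
                s = match if a[i - 1] == b[j - 1] else mism
                M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + go, Ix[i - 1][j] + ge, Iy[i - 1][j] + go)
            if j > 0:
                Iy[i][j] = max(M[i][j - 1] + go, Iy[i][j - 1] + ge, Ix[i][j - 1] + go)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def enumerate_best_score(a, b, match=1.0, mism=-1.0, go=-4.0, ge=-1.0):
    """Exhaustive enumeration over every global alignment (tiny inputs)."""
    best = NEG

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mism), "M")
        if i < len(a):
            rec(i + 1, j, score + (ge if last == "X" else go), "X")
        if j < len(b):
            rec(i, j + 1, score + (ge if last == "Y" else go), "Y")

    rec(0, 0, 0.0, "M")
    return best
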