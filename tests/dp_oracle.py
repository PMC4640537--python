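"""Brute-force Gotoh dynamic-programming oracles for alignment scores.

Independent of the package's aligner backend: plain-Python three-state
affine-gap DP.  A gap of length L costs open + (L - 1) * extend (the open
score covers the first gap column).
"""

NEG = float("-inf")


def global_score(a: str, b: str, match: float, mismatch: float,
                 open_: float, extend: float) -> float:
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def local_score(a: str, b: str, match: float, mismatch: float,
                open_: float, extend: float) -> float:
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s)
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend)
            best = max(best, M[i][j])
    return best
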