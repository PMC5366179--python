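"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the package's implementations: plain-Python,
step-by-step versions used as references.
"""


def stepwise_median_polish(table, max_iter=20, tol=1e-6):
    """Plain-Python Tukey median polish with the lower-median tie rule.

    Returns (overall, row_effects, col_effects, residuals).
    """

    def low_median(v):
        v = sorted(v)
        return v[(len(v) - 1) // 2]

    z = [list(map(float, row)) for row in table]
    nr, nc = len(z), len(z[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    for _ in range(max_iter):
        delta = 0.0
        for i in range(nr):
            m = low_median(z[i])
            row[i] += m
            delta = max(delta, abs(m))
            for j in range(nc):
                z[i][j] -= m
        m = low_median(row)
        overall += m
        row = [r - m for r in row]
        for j in range(nc):
            m = low_median([z[i][j] for i in range(nr)])
            col[j] += m
            delta = max(delta, abs(m))
            for i in range(nr):
                z[i][j] -= m
        m = low_median(col)
        overall += m
        col = [c - m for c in col]
        if delta < tol:
            break
    return overall, row, col, z
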