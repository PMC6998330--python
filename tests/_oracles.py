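"""Brute-force reference computations kept independent of the package.

Everything here is written with explicit Python loops and math.fsum so
the vectorised implementations can be checked against naive
sums-of-squares arithmetic.
"""

import math


def oneway_mean_squares(matrix):
    """(MSB, MSW) of the one-way subjects ANOVA on a complete n x k table."""
    n = len(matrix)
    k = len(matrix[0])
    grand = math.fsum(math.fsum(row) for row in matrix) / (n * k)
    row_means = [math.fsum(row) / k for row in matrix]
    ssb = math.fsum(k * (m - grand) ** 2 for m in row_means)
    ssw = math.fsum(
        (matrix[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(k)
    )
    return ssb / (n - 1), ssw / (n * (k - 1))


def twoway_mean_squares(matrix):
    """(MS_subjects, MS_raters, MS_error) of the crossed two-way ANOVA."""
    n = len(matrix)
    k = len(matrix[0])
    grand = math.fsum(math.fsum(row) for row in matrix) / (n * k)
    row_means = [math.fsum(row) / k for row in matrix]
    col_means = [math.fsum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    ss_s = math.fsum(k * (m - grand) ** 2 for m in row_means)
    ss_r = math.fsum(n * (m - grand) ** 2 for m in col_means)
    ss_e = math.fsum(
        (matrix[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return ss_s / (n - 1), ss_r / (k - 1), ss_e / ((n - 1) * (k - 1))


def replicated_mean_squares(cube):
    """(MS_S, MS_O, MS_SO, MS_E) of the crossed ANOVA with replication.

    ``cube`` is a nested n x k x m list of raw replicate values.
    """
    n, k, m = len(cube), len(cube[0]), len(cube[0][0])
    total = n * k * m
    grand = math.fsum(v for sub in cube for op in sub for v in op) / total
    mi = [math.fsum(v for op in sub for v in op) / (k * m) for sub in cube]
    mj = [
        math.fsum(cube[i][j][r] for i in range(n) for r in range(m)) / (n * m)
        for j in range(k)
    ]
    mij = [[math.fsum(cube[i][j]) / m for j in range(k)] for i in range(n)]
    ss_s = math.fsum(k * m * (v - grand) ** 2 for v in mi)
    ss_o = math.fsum(n * m * (v - grand) ** 2 for v in mj)
    ss_so = math.fsum(
        m * (mij[i][j] - mi[i] - mj[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ss_e = math.fsum(
        (cube[i][j][r] - mij[i][j]) ** 2
        for i in range(n)
        for j in range(k)
        for r in range(m)
    )
    return (
        ss_s / (n - 1),
        ss_o / (k - 1),
        ss_so / ((n - 1) * (k - 1)),
        ss_e / (n * k * (m - 1)),
    )


def icc_agreement_single(matrix):
    """Absolute-agreement single-measure ICC from the two-way ANOVA.

    Returns None when the matrix is constant (ICC undefined).
    """
    n, k = len(matrix), len(matrix[0])
    ms_s, ms_r, ms_e = twoway_mean_squares(matrix)
    denom = ms_s + (k - 1) * ms_e + (k / n) * (ms_r - ms_e)
    if ms_s + ms_r + ms_e == 0.0 or denom <= 0.0:
        return None
    return (ms_s - ms_e) / denom


def icc_oneway_single(matrix):
    msb, msw = oneway_mean_squares(matrix)
    return (msb - msw) / (msb + (len(matrix[0]) - 1) * msw)
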