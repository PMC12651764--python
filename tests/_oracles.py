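"""Brute-force definitional oracles for the agreement statistics.

Written as plain loops from the formulas, independent of the package and
of scipy, so they can arbitrate both.
"""

# ---------------------------------------------------------------------------
# Brute-force oracles, written from the definitions (loops, no library calls)


def oracle_mae(x, y):
    return sum(abs(a - b) for a, b in zip(y, x)) / len(x)


def oracle_rmse(x, y):
    return (sum((a - b) ** 2 for a, b in zip(y, x)) / len(x)) ** 0.5


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = sum((a - mx) ** 2 for a in x) ** 0.5
    sy = sum((b - my) ** 2 for b in y) ** 0.5
    return sxy / (sx * sy)


def oracle_midranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def oracle_spearman(x, y):
    return oracle_pearson(oracle_midranks(list(x)), oracle_midranks(list(y)))


def oracle_ccc(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((a - mx) ** 2 for a in x) / n
    sy2 = sum((b - my) ** 2 for b in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def oracle_bland_altman(x, y):
    d = [b - a for a, b in zip(x, y)]
    n = len(d)
    bias = sum(d) / n
    sd = (sum((v - bias) ** 2 for v in d) / (n - 1)) ** 0.5
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def oracle_icc_2_1(m):
    n, k = len(m), len(m[0])
    gm = sum(sum(row) for row in m) / (n * k)
    rm = [sum(row) / k for row in m]
    cm = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - gm) ** 2 for r in rm) / (n - 1)
    msc = n * sum((c - gm) ** 2 for c in cm) / (k - 1)
    sse = sum(
        (m[i][j] - rm[i] - cm[j] + gm) ** 2 for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


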