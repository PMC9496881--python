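"""Independent brute-force oracles used by the unit and acceptance suites.

Everything here is a direct, loop-based transcription of the defining
formulas, kept deliberately separate from the library's vectorized paths.
"""

import numpy as np


def oneway_ss_oracle(groups):
    """SSF/SSE/SST by explicit summation."""
    flat = [y for g in groups for y in g]
    grand = sum(flat) / len(flat)
    ssf = sse = sst = 0.0
    for g in groups:
        gm = sum(g) / len(g)
        ssf += len(g) * (gm - grand) ** 2
        for y in g:
            sse += (y - gm) ** 2
            sst += (y - grand) ** 2
    return ssf, sse, sst


def twoway_ss_oracle(Y):
    """SSA/SSB/SSAB/SSE/SST of a balanced (a, b, n) layout by triple loops."""
    a, b, n = Y.shape
    grand = sum(Y[i, j, k] for i in range(a) for j in range(b) for k in range(n)) / (a * b * n)
    cell = [[sum(Y[i, j, k] for k in range(n)) / n for j in range(b)] for i in range(a)]
    mA = [sum(cell[i][j] for j in range(b)) / b for i in range(a)]
    mB = [sum(cell[i][j] for i in range(a)) / a for j in range(b)]
    SSA = b * n * sum((m - grand) ** 2 for m in mA)
    SSB = a * n * sum((m - grand) ** 2 for m in mB)
    SSAB = sum(n * (cell[i][j] - grand) ** 2 for i in range(a) for j in range(b)) - SSA - SSB
    SSE = sum((Y[i, j, k] - cell[i][j]) ** 2
              for i in range(a) for j in range(b) for k in range(n))
    SST = sum((Y[i, j, k] - grand) ** 2
              for i in range(a) for j in range(b) for k in range(n))
    return SSA, SSB, SSAB, SSE, SST


def f_upper_tail_quadrature(F, df1, df2):
    """P(X >= F) for the Fisher-Snedecor distribution by adaptive quadrature
    of its density (transformed to the bounded variable x/(1+x))."""
    from scipy import integrate, special

    lnC = (special.gammaln((df1 + df2) / 2) - special.gammaln(df1 / 2)
           - special.gammaln(df2 / 2) + (df1 / 2) * np.log(df1 / df2))

    def density(x):
        return np.exp(lnC + (df1 / 2 - 1) * np.log(x)
                      - ((df1 + df2) / 2) * np.log(1 + df1 * x / df2))

    value, _ = integrate.quad(density, F, np.inf, limit=400)
    return value


def confusion_loop_oracle(seg, truth):
    tp = fp = fn = tn = 0
    for i in range(seg.shape[0]):
        for j in range(seg.shape[1]):
            s, t = bool(seg[i, j]), bool(truth[i, j])
            if s and t:
                tp += 1
            elif s and not t:
                fp += 1
            elif not s and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def pearson_oracle(a, b):
    """Textbook covariance / sigma formulation with population moments."""
    am, bm = a.mean(), b.mean()
    cov = ((a - am) * (b - bm)).mean()
    return cov / (np.sqrt(((a - am) ** 2).mean()) * np.sqrt(((b - bm) ** 2).mean()))


def rmse_loop_oracle(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return np.sqrt(total / a.size)


def sad_loop_oracle(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += abs(a[i, j] - b[i, j])
    return total
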