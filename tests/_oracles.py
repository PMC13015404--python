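"""Independent oracle implementations shared across test modules."""

import numpy as np

from sexscan.paralogdiag import GAP_EXTEND, GAP_OPEN, MATCH_SCORE, MISMATCH_SCORE


def wc_theta_anova_oracle(genotypes_m, genotypes_f):
    """Independent W&C theta via the nested allele-level ANOVA mean squares
    (variance components from genotype-class counts, not the closed-form
    a/b/c expressions)."""
    pops = [np.asarray(genotypes_m), np.asarray(genotypes_f)]
    r = 2
    n = [len(g) for g in pops]
    N = sum(n)
    p = [g.sum() / (2 * len(g)) for g in pops]
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / N
    ssg = sum(0.5 * (g == 1).sum() for g in pops)
    ssi = sum(
        2.0
        * (
            (g == 2).sum() * (1 - pi) ** 2
            + (g == 0).sum() * pi**2
            + (g == 1).sum() * (0.5 - pi) ** 2
        )
        for g, pi in zip(pops, p)
    )
    ssp = sum(2.0 * ni * (pi - pbar) ** 2 for ni, pi in zip(n, p))
    msg = ssg / N
    msi = ssi / (N - r)
    msp = ssp / (r - 1)
    nbar = N / r
    nc = (N - sum(ni**2 for ni in n) / N) / (r - 1)
    sg = msg
    si = (msi - msg) / 2.0
    sp = (msp - msi) / (2.0 * nc)
    denom = sg + si + sp
    return sp / denom if denom != 0 else np.nan


def affine_dp_oracle(a, b):
    """Gotoh affine-gap global alignment score, written independently:
    gap of length L costs GAP_OPEN + L * GAP_EXTEND."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (deletion from a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + i * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + j * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH_SCORE if a[i - 1] == b[j - 1] else MISMATCH_SCORE
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN + GAP_EXTEND, X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN + GAP_EXTEND, Y[i, j - 1] + GAP_EXTEND)
    return max(M[n, m], X[n, m], Y[n, m])
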