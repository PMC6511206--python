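"""Independent brute-force oracles used by the test suite.

Kept free of any dqaudit statistical code path: Fisher's test is enumerated
with exact integer combinatorics, and the chi-square statistic is computed
directly from its definition.
"""

from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int, tol: float = 1e-7) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Sums the exact hypergeometric point probabilities of every table whose
    probability does not exceed the observed table's (ties judged at
    relative tolerance ``tol``).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = comb(r1, k) * comb(r2, c1 - k) / denom
        if p_k <= p_obs * (1 + tol):
            total += p_k
    return min(total, 1.0)


def chi_square_statistic_oracle(counts) -> float:
    """Pearson chi-square statistic from first principles: sum (O-E)^2/E
    with E = row total * column total / grand total."""
    rows = [list(map(float, r)) for r in counts]
    row_tot = [sum(r) for r in rows]
    col_tot = [sum(r[j] for r in rows) for j in range(len(rows[0]))]
    grand = sum(row_tot)
    stat = 0.0
    for i, r in enumerate(rows):
        for j, obs in enumerate(r):
            expected = row_tot[i] * col_tot[j] / grand
            stat += (obs - expected) ** 2 / expected
    return stat
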