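"""Independent reference implementations used only by the test suite.

These deliberately avoid the code paths they check: the hypergeometric
tail is exact rational arithmetic over binomial coefficients, and the
selection rule is a per-gene Python re-evaluation of the printed
inequalities.
"""

from fractions import Fraction
from math import comb


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def brute_force_select(l_wt: dict, l_ko: dict, q25: float) -> set:
    """Per-gene re-check of: L_KO < 0, L_WT > 0, DIF < DIF_25% (all strict)."""
    out = set()
    for gene in l_wt:
        dif = l_ko[gene] - l_wt[gene]
        if l_ko[gene] < 0 and l_wt[gene] > 0 and dif < q25:
            out.add(gene)
    return out
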