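"""Shared exact-rational enumeration oracle for the HWE exact test.

Kept independent of the package implementation: conditional heterozygote
probabilities are built from integer factorials with Fraction arithmetic,
so any agreement with the log-gamma implementation is a genuine
cross-check rather than a tautology.
"""

import math
from fractions import Fraction


def hwe_enumeration_oracle(n_hom_major: int, n_het: int, n_hom_minor: int) -> Fraction:
    n = n_hom_major + n_het + n_hom_minor
    m = 2 * min(n_hom_major, n_hom_minor) + n_het
    if m == 0:
        return Fraction(1)

    def weight(h: int) -> Fraction:
        a = (m - h) // 2
        b = n - a - h
        return Fraction(2**h, math.factorial(a) * math.factorial(h) * math.factorial(b))

    hets = range(m % 2, m + 1, 2)
    total = sum(weight(h) for h in hets)
    probs = {h: weight(h) / total for h in hets}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)
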