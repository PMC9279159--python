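"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: exact integer
arithmetic for the hypergeometric enumeration, plain-python interpolation
for projections.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums, in exact rational arithmetic, the probabilities of every table
    with the observed margins whose probability does not exceed the
    observed table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    observed = comb(r1, a) * comb(r2, c1 - a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(
        count
        for x in range(lo, hi + 1)
        if (count := comb(r1, x) * comb(r2, c1 - x)) <= observed
    )
    return float(Fraction(total, denom))


def interpolate_between(pos: int, up_end_a: int, down_start_a: int,
                        up_end_b: int, down_start_b: int) -> int:
    """Plain linear interpolation between two '+'-strand anchor inner edges."""
    frac = (pos - up_end_a) / (down_start_a - up_end_a)
    return up_end_b + round(frac * (down_start_b - up_end_b))
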