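"""Closed-form 2x2 chi-square test shared by the allelic-imbalance and
differential-splicing modules.

For the table ``[[a, b], [c, d]]`` the statistic is

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d

with one degree of freedom and no continuity correction.  A zero marginal
yields statistic 0 and p-value 1 (no information about association).
"""

from __future__ import annotations

from scipy import stats

__all__ = ["chi2_2x2"]


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Chi-square statistic and p-value for the 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))
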