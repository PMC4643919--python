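"""Tajima's nonparametric relative-rate test on three-taxon alignments.

Two ingroup lineages evolving at equal rates should accumulate equal
numbers of lineage-specific sites relative to an outgroup. With m1 and m2
the counts of sites unique to ingroup 1 and ingroup 2, the statistic
(m1 − m2)² / (m1 + m2) is asymptotically chi-square with 1 degree of
freedom under rate equality. Columns containing a gap or N in any of the
three taxa are wholly excluded (complete deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .alignment import AlignmentMatrix

__all__ = [
    "SitePatternCounts",
    "RateTestResult",
    "site_pattern_counts",
    "tajima_test",
    "run_rate_tests",
    "format_p",
]


@dataclass(frozen=True)
class SitePatternCounts:
    identical: int
    divergent: int  # all three states distinct
    uniq1: int  # ingroup-1-specific
    uniq2: int  # ingroup-2-specific
    uniq_out: int  # outgroup-specific
    skipped: int  # columns with gap or N in any of the three taxa

    @property
    def total(self) -> int:
        return (
            self.identical
            + self.divergent
            + self.uniq1
            + self.uniq2
            + self.uniq_out
            + self.skipped
        )


@dataclass(frozen=True)
class RateTestResult:
    ingroup1: str
    ingroup2: str
    outgroup: str
    counts: SitePatternCounts | None
    chi_square: float
    p_value: float
    slower: str | None  # lineage with fewer unique sites, when significant
    df: int = 1
    defined: bool = True  # False when m1 + m2 = 0 leaves the test undefined


def site_pattern_counts(
    aln: AlignmentMatrix, ingroup1: str, ingroup2: str, outgroup: str
) -> SitePatternCounts:
    """Classify every column of a three-taxon projection of the alignment."""
    for role in (ingroup1, ingroup2, outgroup):
        if role not in aln.taxa:
            raise ValueError(f"taxon {role!r} not in alignment")
    a = aln.row_array(ingroup1)
    b = aln.row_array(ingroup2)
    c = aln.row_array(outgroup)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    clean = np.isin(a, base_codes) & np.isin(b, base_codes) & np.isin(c, base_codes)

    ab = a == b
    ac = a == c
    bc = b == c
    identical = int((clean & ab & ac).sum())
    uniq1 = int((clean & bc & ~ab).sum())
    uniq2 = int((clean & ac & ~ab).sum())
    uniq_out = int((clean & ab & ~ac).sum())
    divergent = int((clean & ~ab & ~ac & ~bc).sum())
    return SitePatternCounts(
        identical=identical,
        divergent=divergent,
        uniq1=uniq1,
        uniq2=uniq2,
        uniq_out=uniq_out,
        skipped=int((~clean).sum()),
    )


def tajima_test(
    m1: int,
    m2: int,
    ingroup1: str = "ingroup1",
    ingroup2: str = "ingroup2",
    outgroup: str = "outgroup",
    counts: SitePatternCounts | None = None,
    alpha: float = 0.05,
) -> RateTestResult:
    """Tajima 1D relative-rate test from the two unique-site counts.

    chi² = (m1 − m2)² / (m1 + m2), df = 1; the p-value is the upper-tail
    chi-square probability. With m1 = m2 the statistic is 0 and p = 1.
    m1 + m2 = 0 is reported as statistic 0, p = 1, flagged undefined.
    """
    if m1 < 0 or m2 < 0:
        raise ValueError("unique-site counts must be non-negative")
    if m1 + m2 == 0:
        return RateTestResult(
            ingroup1, ingroup2, outgroup, counts, 0.0, 1.0, None, defined=False
        )
    stat = (m1 - m2) ** 2 / (m1 + m2)
    p = float(chi2.sf(stat, df=1))
    slower = None
    if p < alpha:
        slower = ingroup1 if m1 < m2 else ingroup2
    return RateTestResult(ingroup1, ingroup2, outgroup, counts, float(stat), p, slower)


def run_rate_tests(
    aln: AlignmentMatrix,
    pairs: list[tuple[str, str]],
    outgroup: str,
    alpha: float = 0.05,
) -> list[RateTestResult]:
    """One Tajima test per (ingroup1, ingroup2) pair against a shared outgroup."""
    results = []
    for ing1, ing2 in pairs:
        counts = site_pattern_counts(aln, ing1, ing2, outgroup)
        results.append(
            tajima_test(
                counts.uniq1,
                counts.uniq2,
                ingroup1=ing1,
                ingroup2=ing2,
                outgroup=outgroup,
                counts=counts,
                alpha=alpha,
            )
        )
    return results


def format_p(p: float, floor: float = 0.001) -> str:
    """Report a p-value to three significant figures, flooring tiny values
    as '< 0.001' in the conventional table style."""
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3g}"
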