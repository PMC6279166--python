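"""Gene-family enrichment of nonsynonymous change (2x2 chi-square).

Tests whether genes of a family (e.g. odorant receptors) are enriched for
nonsynonymous substitutions relative to all genes of the region, framed as a
2x2 contingency table [family membership x has-nonsynonymous-change].  The
gene universe is an explicit input: after a deletion the family size can
differ between haplotypes, so the universe is never inferred from flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as _scipy_stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[family & flagged, family & not], [other & flagged, other & not]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def has_zero_margin(self) -> bool:
        m = self.as_array()
        return bool((m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any())


def contingency_from_flags(
    flags: Mapping[str, bool], membership: Mapping[str, bool]
) -> ContingencyTable2x2:
    """Cross-tabulate per-gene change flags against family membership.

    Both mappings must cover the same gene universe (family column first).
    """
    if not flags:
        raise ValueError("empty gene universe")
    if set(flags) != set(membership):
        raise ValueError("flags and membership must cover the same gene universe")
    a = sum(1 for g, m in membership.items() if m and flags[g])
    b = sum(1 for g, m in membership.items() if m and not flags[g])
    c = sum(1 for g, m in membership.items() if not m and flags[g])
    d = sum(1 for g, m in membership.items() if not m and not flags[g])
    return ContingencyTable2x2(a, b, c, d)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    pvalue: float
    defined: bool
    continuity: bool


def chisq_enrichment(
    table: ContingencyTable2x2, continuity: bool = False
) -> ChiSquareResult:
    """Pearson chi-square (df=1) on the 2x2 table, upper-tail p.

    Yates continuity correction is off by default.  A zero row or column
    margin leaves the statistic undefined (``defined=False``, NaN values).
    """
    if table.has_zero_margin():
        return ChiSquareResult(float("nan"), float("nan"), False, continuity)
    stat, p, _, _ = _scipy_stats.chi2_contingency(table.as_array(), correction=continuity)
    return ChiSquareResult(float(stat), float(p), True, continuity)
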