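"""Mapping selected sites onto a linear receptor domain architecture.

Insect odorant receptors are 7-transmembrane proteins; a linear architecture
alternates intracellular (IC), transmembrane (TM) and extracellular (EC)
segments with an intracellular N terminus.  Sites of interest (positively
selected sites, haplotype amino-acid differences) are mapped to segments, and
per-segment clustering is tested with an exact upper-tail binomial against
the uniform expectation, Benjamini–Hochberg corrected across the segments of
one run.  Hydropathy profiles use the Kyte–Doolittle index; substitutions are
classified conservative iff their PAM250 score is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class Segment:
    label: str  # e.g. "TM3", "IC3", "ECN"
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered EC/TM/IC segments tiling positions 1..L without gaps or overlap."""

    segments: tuple[Segment, ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("architecture needs at least one segment")
        expected = 1
        for seg in self.segments:
            if seg.start != expected or seg.end < seg.start:
                raise ValueError(
                    f"segments must tile 1..L without gaps/overlaps; "
                    f"{seg.label} starts at {seg.start}, expected {expected}"
                )
            expected = seg.end + 1

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    def segment_of(self, position: int) -> Segment:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg
        raise AssertionError("unreachable: segments tile 1..L")

    @classmethod
    def from_lengths(cls, labelled_lengths: Sequence[tuple[str, int]]) -> "DomainArchitecture":
        segs, pos = [], 1
        for label, n in labelled_lengths:
            segs.append(Segment(label, pos, pos + n - 1))
            pos += n
        return cls(tuple(segs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"label": s.label, "start": s.start, "end": s.end} for s in self.segments]
        )


def default_or_architecture() -> DomainArchitecture:
    """Packaged 390-residue 7-TM odorant-receptor architecture.

    Topology: intracellular N terminus, TM1..TM7 with alternating EC/IC
    loops, extracellular C terminus.  IC3 (the large intracellular loop
    before TM7) is fixed at 24 residues and TM3 at 25; the remaining 13
    segments split the remaining 341 residues as evenly as possible.  The even split
    is a packaged convention — real receptors have unequal loops.
    """
    labels = [
        "ICN", "TM1", "EC1", "TM2", "IC1", "TM3", "EC2", "TM4",
        "IC2", "TM5", "EC3", "TM6", "IC3", "TM7", "ECC",
    ]
    fixed = {"IC3": 24, "TM3": 25}
    free = [l for l in labels if l not in fixed]
    remaining = 390 - sum(fixed.values())
    base, extra = divmod(remaining, len(free))
    lengths = {}
    for i, l in enumerate(free):
        lengths[l] = base + (1 if i < extra else 0)
    lengths.update(fixed)
    return DomainArchitecture.from_lengths([(l, lengths[l]) for l in labels])


def map_sites(sites: pd.DataFrame, arch: DomainArchitecture) -> pd.DataFrame:
    """Per-segment site counts; every site falls in exactly one segment.

    ``sites`` needs a ``position`` column (1-based).  Sites supported by more
    than one branch (multiplicity > 1) still count once.
    """
    counts = {seg.label: 0 for seg in arch.segments}
    for pos in sites["position"]:
        counts[arch.segment_of(int(pos)).label] += 1
    return pd.DataFrame(
        [
            {
                "label": seg.label,
                "start": seg.start,
                "end": seg.end,
                "segment_length": seg.length,
                "observed": counts[seg.label],
            }
            for seg in arch.segments
        ]
    )


def domain_binomial_tests(
    counts: pd.DataFrame, arch: DomainArchitecture, total_sites: int | None = None
) -> pd.DataFrame:
    """Exact upper-tail binomial clustering test per segment, BH-corrected.

    For a segment of length ``m`` in a protein of length ``L`` holding ``x``
    of ``n`` sites, p = P(X >= x), X ~ Binomial(n, m/L).  The q column is the
    Benjamini–Hochberg value over the segments tested in this call.
    """
    if arch.length == 0:
        raise ValueError("architecture of length 0")
    n = int(counts["observed"].sum()) if total_sites is None else int(total_sites)
    if n != int(counts["observed"].sum()):
        raise ValueError("total_sites must equal the sum of observed counts")
    out = counts.copy()
    out["expected"] = [n * seg.length / arch.length for seg in arch.segments]
    pvals = []
    for seg in arch.segments:
        x = int(counts.loc[counts["label"] == seg.label, "observed"].iloc[0])
        p0 = seg.length / arch.length
        pvals.append(1.0 if x == 0 else float(_scipy_stats.binom.sf(x - 1, n, p0)))
    out["p"] = pvals
    out["q"] = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else []
    return out


def hydropathy_profile(
    alignment: Sequence[str], statistic: str = "median"
) -> pd.DataFrame:
    """Per-position Kyte–Doolittle hydropathy of an amino-acid alignment.

    Gaps (``-``) are ignored per position; a column that is entirely gaps
    gets NaN and ``defined=False``.  ``statistic`` is ``median`` (default)
    or ``mean``.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    (length,) = lengths
    reduce = np.median if statistic == "median" else np.mean
    rows = []
    for i in range(length):
        values = []
        for seq in alignment:
            aa = seq[i].upper()
            if aa == "-":
                continue
            if aa not in KYTE_DOOLITTLE:
                raise ValueError(f"nonstandard residue {aa!r} at position {i + 1}")
            values.append(KYTE_DOOLITTLE[aa])
        rows.append(
            {
                "position": i + 1,
                "hydropathy": float(reduce(values)) if values else float("nan"),
                "defined": bool(values),
                "n_residues": len(values),
            }
        )
    return pd.DataFrame(rows)


_PAM250 = substitution_matrices.load("PAM250")

CONSERVATIVE = "conservative"
NONCONSERVATIVE = "nonconservative"


def classify_conservative(aa1: str, aa2: str) -> str:
    """Conservative iff PAM250(aa1, aa2) > 0; identical residues always are."""
    aa1, aa2 = aa1.upper(), aa2.upper()
    for aa in (aa1, aa2):
        if aa not in KYTE_DOOLITTLE:
            raise ValueError(f"nonstandard residue {aa!r}")
    if aa1 == aa2:
        return CONSERVATIVE
    return CONSERVATIVE if _PAM250[aa1, aa2] > 0 else NONCONSERVATIVE
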