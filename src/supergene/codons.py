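"""Nei–Gojobori codon-level primitives.

Counting-based dN/dS estimation splits each codon's mutational opportunity
into synonymous and nonsynonymous *site* fractions and classifies observed
codon differences into synonymous and nonsynonymous *substitution* fractions
by averaging over all single-nucleotide mutational pathways between the two
codons.  These are the two primitives everything else in :mod:`supergene.dnds`
is built from.

Conventions
-----------
* Standard nuclear genetic code; the 61 sense codons.
* Changes to stop codons count as nonsynonymous *opportunities* in site
  fractions, but mutational pathways that pass through a stop codon are
  excluded (and the average renormalized over the surviving pathways).
* A codon containing ``N`` or ``-`` (or any non-ACGT character) is masked and
  rejected by these functions; callers are expected to skip masked codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
GENETIC_CODE = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(GENETIC_CODE))

#: transitions (purine<->purine, pyrimidine<->pyrimidine) for kappa weighting
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def is_masked(codon: str) -> bool:
    """True if the codon contains any character outside ACGT (``N``/``-`` ...)."""
    return len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon)


def translate(codon: str) -> str:
    return GENETIC_CODE[codon]


def _check_sense(codon: str) -> None:
    if is_masked(codon):
        raise ValueError(f"masked or malformed codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon not allowed: {codon!r}")


def neighbors(codon: str):
    """Yield ``(position, new_nucleotide, new_codon)`` for all 9 single-nt changes."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, nt, codon[:pos] + nt + codon[pos + 1 :]


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous/nonsynonymous site counts (denominators)."""

    syn: float = 0.0
    nonsyn: float = 0.0

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.syn + other.syn, self.nonsyn + other.nonsyn)

    def scaled(self, factor: float) -> "SiteCounts":
        return SiteCounts(self.syn * factor, self.nonsyn * factor)

    @property
    def total(self) -> float:
        return self.syn + self.nonsyn


@dataclass(frozen=True)
class DiffCounts:
    """Fractional synonymous/nonsynonymous substitution counts.

    ``blocked_fallback`` marks counts where every mutational pathway between
    the two codons passed through a stop codon, so the stop exclusion was
    waived and the plain all-pathways average used instead.
    """

    syn: float = 0.0
    nonsyn: float = 0.0
    blocked_fallback: bool = False

    def __add__(self, other: "DiffCounts") -> "DiffCounts":
        return DiffCounts(
            self.syn + other.syn,
            self.nonsyn + other.nonsyn,
            self.blocked_fallback or other.blocked_fallback,
        )

    def scaled(self, factor: float) -> "DiffCounts":
        return DiffCounts(self.syn * factor, self.nonsyn * factor, self.blocked_fallback)

    @property
    def total(self) -> float:
        return self.syn + self.nonsyn


def synonymous_site_fractions(codon: str) -> SiteCounts:
    """Synonymous/nonsynonymous site fractions of one sense codon.

    For each of the three positions, the fraction of the three possible
    single-nucleotide changes that are synonymous is the synonymous site
    fraction of that position; fractions sum to 3 per codon exactly.
    Changes creating a stop codon are nonsynonymous opportunities.
    """
    _check_sense(codon)
    return _SITE_CACHE[codon]


def _site_fractions_uncached(codon: str) -> SiteCounts:
    aa = translate(codon)
    syn = 0.0
    for _pos, _nt, alt in neighbors(codon):
        if alt not in STOP_CODONS and translate(alt) == aa:
            syn += 1.0 / 3.0
    return SiteCounts(syn=syn, nonsyn=3.0 - syn)


def pathway_diff_counts(c1: str, c2: str) -> DiffCounts:
    """Pathway-averaged substitution counts between two sense codons.

    For codons differing at ``k`` positions, every one of the ``k!`` orderings
    of single-nucleotide steps is walked and each step classified as
    synonymous or nonsynonymous; counts are averaged over orderings.
    Orderings passing through a stop codon are excluded and the average is
    renormalized over the remainder; if *all* orderings are blocked the plain
    average over every ordering is returned with ``blocked_fallback`` set.
    """
    _check_sense(c1)
    _check_sense(c2)
    return _PATH_CACHE.get((c1, c2)) or _pathway_uncached(c1, c2)


def _pathway_uncached(c1: str, c2: str) -> DiffCounts:
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return DiffCounts(0.0, 0.0)
    open_paths = []
    all_paths = []
    for order in permutations(diff_positions):
        cur = c1
        steps = []  # (is_synonymous,)
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                steps.append(None)
            else:
                steps.append(translate(nxt) == translate(cur) if cur not in STOP_CODONS else None)
            cur = nxt
        syn = sum(1.0 for s in steps if s is True)
        nonsyn = sum(1.0 for s in steps if s is False)
        # steps through/out of a stop are nonsynonymous by convention in the
        # unblocked fallback (a stop<->sense change alters the protein)
        nonsyn += sum(1.0 for s in steps if s is None)
        record = (syn, nonsyn)
        all_paths.append(record)
        if not blocked:
            open_paths.append(record)
    pool, fallback = (open_paths, False) if open_paths else (all_paths, True)
    n = len(pool)
    return DiffCounts(
        syn=sum(p[0] for p in pool) / n,
        nonsyn=sum(p[1] for p in pool) / n,
        blocked_fallback=fallback,
    )


def _build_caches():
    sites = {c: _site_fractions_uncached(c) for c in SENSE_CODONS}
    paths = {}
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            paths[(c1, c2)] = _pathway_uncached(c1, c2)
    return sites, paths


_SITE_CACHE, _PATH_CACHE = _build_caches()


# ---------------------------------------------------------------------------
# Mutational-flux bookkeeping shared with the sequence simulator.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonFlux:
    """Kappa-weighted mutational flux leaving one codon, split by class.

    ``syn_weight``/``nonsyn_weight`` sum proposal weights (kappa for a
    transition, 1 for a transversion) over synonymous and nonsynonymous
    non-stop single-nucleotide changes.  Used by the evolution simulator to
    hold the instantaneous dN/dS of the generating process at a target value.
    """

    syn_weight: float
    nonsyn_weight: float


def sense_change_counts(codon: str) -> tuple[int, int]:
    """Numbers of (synonymous, nonsynonymous) sense single-nt changes of a codon."""
    syn = nonsyn = 0
    aa = translate(codon)
    for _pos, _nt, alt in neighbors(codon):
        if alt in STOP_CODONS:
            continue
        if translate(alt) == aa:
            syn += 1
        else:
            nonsyn += 1
    return syn, nonsyn


def codon_flux(codon: str, kappa: float) -> CodonFlux:
    syn = nonsyn = 0.0
    aa = translate(codon)
    for pos, nt, alt in neighbors(codon):
        if alt in STOP_CODONS:
            continue
        w = kappa if (codon[pos], nt) in TRANSITIONS else 1.0
        if translate(alt) == aa:
            syn += w
        else:
            nonsyn += w
    return CodonFlux(syn, nonsyn)
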