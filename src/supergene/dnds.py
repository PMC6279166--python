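"""Branch-specific dN/dS on haplotype/outgroup codon trios.

Given a codon-aligned trio (haplotype A, haplotype B, outgroup) per gene,
substitutions are placed on the three lineages of the unrooted 3-taxon star by
parsimony, classified into synonymous/nonsynonymous fractions with the
Nei–Gojobori pathway rules, and pooled across genes into per-branch dN/dS
ratios (ratio of sums, not mean of per-gene ratios — many genes carry zero
synonymous substitutions on the short terminal branches).

Branch labels: ``"A"`` and ``"B"`` are the two terminal haplotype branches;
``"presplit"`` is the unpolarized lineage separating the haplotype pair from
the outgroup (internal branch plus outgroup branch — with a single outgroup
the two cannot be told apart).

Ambiguous columns
-----------------
When the three codons in a column are all distinct there can be several
equally parsimonious placements of the changes.  The column-level primitive
averages them with equal weight and flags the column.  At dataset level a
second pass can instead weight the tied reconstructions by the per-branch
substitution rates estimated from the unambiguous columns
(:func:`dataset_branch_counts` with ``policy="rate_weighted"``).  Equal
weighting systematically inflates the short terminal branches whenever the
outgroup is divergent, because a reconstruction putting a change on a
~10^-3-length terminal branch is given the same weight as one putting it on a
~10^-1-length outgroup lineage; rate weighting removes that bias and is the
default for whole-dataset analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as _scipy_stats

from .codons import (
    sense_change_counts,
    DiffCounts,
    SENSE_CODONS,
    SiteCounts,
    STOP_CODONS,
    is_masked,
    pathway_diff_counts,
    synonymous_site_fractions,
)

BRANCHES = ("A", "B", "presplit")


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CodonTrioAlignment:
    """One gene's codon-aligned sequences for haplotype A, B and the outgroup.

    Masking is per-codon: any codon containing ``N`` or ``-`` is skipped as a
    whole.  Unmasked codons must be sense codons of the standard code.
    """

    gene_id: str
    seq_a: str
    seq_b: str
    seq_out: str

    def __post_init__(self):
        lengths = {len(self.seq_a), len(self.seq_b), len(self.seq_out)}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths {lengths}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {length} not divisible by 3")
        for name, seq in (("A", self.seq_a), ("B", self.seq_b), ("out", self.seq_out)):
            for i in range(0, length, 3):
                codon = seq[i : i + 3]
                if not is_masked(codon) and codon in STOP_CODONS:
                    raise ValueError(
                        f"{self.gene_id}: in-frame stop {codon} in sequence {name} "
                        f"at codon {i // 3 + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_column(self, index: int) -> tuple[str, str, str]:
        """Codon triple (A, B, outgroup) at 0-based codon ``index``."""
        i = 3 * index
        return (self.seq_a[i : i + 3], self.seq_b[i : i + 3], self.seq_out[i : i + 3])

    def columns(self):
        for i in range(self.n_codons):
            yield self.codon_column(i)


@dataclass(frozen=True)
class ColumnAssignment:
    """Parsimony placement of one codon column's changes on the 3-taxon star.

    ``reconstructions`` holds the per-branch :class:`DiffCounts` for each
    candidate internal-node state (``nodes``); ``minimal`` marks the
    maximally parsimonious ones.  Non-minimal candidates (one extra step,
    e.g. a pre-split change plus a terminal back-change explaining the same
    column as a single terminal event does) only participate when explicit
    weights are supplied.  ``ambiguous`` marks columns where the three codons
    are pairwise distinct.
    """

    nodes: tuple[str, ...]
    reconstructions: tuple[Mapping[str, DiffCounts], ...]
    minimal: tuple[bool, ...]
    ambiguous: bool

    def averaged(self, weights: Sequence[float] | None = None) -> dict[str, DiffCounts]:
        """Weighted mean of the reconstructions.

        Default (no weights): equal average over the minimally parsimonious
        reconstructions only.  With weights (one per reconstruction): a
        weighted average over all candidates.
        """
        if weights is None:
            weights = [1.0 if m else 0.0 for m in self.minimal]
        total = sum(weights)
        if total <= 0:
            weights = [1.0 if m else 0.0 for m in self.minimal]
            total = sum(weights)
        out = {b: DiffCounts() for b in BRANCHES}
        for w, rec in zip(weights, self.reconstructions):
            if w == 0.0:
                continue
            for b in BRANCHES:
                out[b] = out[b] + rec[b].scaled(w / total)
        return out


def _internal_candidates(ca: str, cb: str, cout: str) -> list[str]:
    """Sense-codon internal states minimizing total nucleotide steps.

    Positionwise majority vote; positions where the three sequences carry
    three different nucleotides are ties among those three.  If every
    positionwise-optimal codon is a stop, fall back to a scan over all sense
    codons (cost penalty of at most one extra step).
    """
    per_pos = []
    for i in range(3):
        nts = (ca[i], cb[i], cout[i])
        uniq = set(nts)
        if len(uniq) < 3:
            per_pos.append([max(uniq, key=nts.count)])
        else:
            per_pos.append(sorted(uniq))
    cands = ["".join(p) for p in product(*per_pos)]
    sense = [c for c in cands if c not in STOP_CODONS]
    if sense:
        return sense
    best_cost, best = None, []
    for c in SENSE_CODONS:
        cost = sum(c[i] != s[i] for s in (ca, cb, cout) for i in range(3))
        if best_cost is None or cost < best_cost:
            best_cost, best = cost, [c]
        elif cost == best_cost:
            best.append(c)
    return best


def _reconstruction_for(node: str, ca: str, cb: str, cout: str) -> dict[str, DiffCounts]:
    return {
        "A": pathway_diff_counts(node, ca),
        "B": pathway_diff_counts(node, cb),
        "presplit": pathway_diff_counts(node, cout),
    }


@lru_cache(maxsize=None)
def assign_branch_substitutions(ca: str, cb: str, cout: str) -> ColumnAssignment:
    """Place one column's substitutions on the A, B and pre-split lineages.

    All three codons must be unmasked sense codons (masked columns are the
    caller's responsibility to skip).  Shared derived states go to the
    pre-split lineage; a change private to one haplotype goes to its terminal
    branch; columns with three distinct codons are averaged over the equally
    parsimonious reconstructions and flagged ambiguous.

    Beyond the minimal reconstructions, the leaf codons themselves are kept
    as extra internal-node candidates (one extra step).  They carry zero
    weight under the default parsimony averaging but let rate-aware callers
    account for e.g. an outgroup-lineage change reverted on one terminal
    branch, which parsimony would otherwise misread as a single event on the
    *other* terminal branch.
    """
    if ca == cb == cout:
        return ColumnAssignment(
            (ca,), ({b: DiffCounts() for b in BRANCHES},), (True,), False
        )
    nodes = list(_internal_candidates(ca, cb, cout))
    minimal = [True] * len(nodes)
    for extra in sorted({ca, cb, cout} - set(nodes) - STOP_CODONS):
        nodes.append(extra)
        minimal.append(False)
    recs = tuple(_reconstruction_for(n, ca, cb, cout) for n in nodes)
    ambiguous = ca != cb and cb != cout and ca != cout
    return ColumnAssignment(tuple(nodes), recs, tuple(minimal), ambiguous)


@dataclass
class GeneBranchStats:
    """Per-gene, per-branch substitution counts with shared site denominators."""

    gene_id: str
    diffs: dict[str, DiffCounts]
    sites: SiteCounts
    n_masked_codons: int = 0
    ambiguous_columns: int = 0
    n_columns: int = 0

    @property
    def all_masked(self) -> bool:
        return self.n_columns == 0

    def dn(self, branch: str) -> float:
        return self.diffs[branch].nonsyn / self.sites.nonsyn if self.sites.nonsyn else 0.0

    def ds(self, branch: str) -> float:
        return self.diffs[branch].syn / self.sites.syn if self.sites.syn else 0.0


def _reconstruction_weights(
    assignment: ColumnAssignment, rates: Mapping[str, Mapping[str, float]] | None
) -> Sequence[float] | None:
    """Posterior-style weights over candidate reconstructions.

    A reconstruction's weight is the product over its steps of the branch's
    per-class substitution rate times the probability that a class-c event
    from the internal codon is that *specific* change (approximated as one
    over the codon's number of sense changes of that class).  Ratios of
    these products mirror the relative probabilities of the competing event
    histories, so reconstructions with an extra step are discounted by a
    realistic factor rather than excluded outright.
    """
    if rates is None or len(assignment.reconstructions) == 1:
        return None
    weights = []
    for node, rec in zip(assignment.nodes, assignment.reconstructions):
        n_syn_changes, n_nonsyn_changes = sense_change_counts(node)
        logw = 0.0
        for b in BRANCHES:
            if rec[b].syn:
                logw += rec[b].syn * (
                    math.log(rates[b]["syn"]) - math.log(max(n_syn_changes, 1))
                )
            if rec[b].nonsyn:
                logw += rec[b].nonsyn * (
                    math.log(rates[b]["nonsyn"]) - math.log(max(n_nonsyn_changes, 1))
                )
        weights.append(logw)
    top = max(weights)
    return [math.exp(w - top) for w in weights]


def gene_branch_counts(
    trio: CodonTrioAlignment,
    branch_rates: Mapping[str, Mapping[str, float]] | None = None,
) -> GeneBranchStats:
    """Column-wise parsimony counts for one trio.

    ``branch_rates`` optionally weights tied reconstructions of ambiguous
    columns by per-branch, per-class (synonymous/nonsynonymous) substitution
    intensities, ``{branch: {"syn": rate, "nonsyn": rate}}`` (see module
    docstring); ``None`` means equal weighting.  The shared site denominator is the mean
    of the Nei–Gojobori site fractions of the three sequences over columns
    unmasked in all of them.
    """
    diffs = {b: DiffCounts() for b in BRANCHES}
    sites = SiteCounts()
    masked = ambiguous = counted = 0
    for ca, cb, cout in trio.columns():
        if is_masked(ca) or is_masked(cb) or is_masked(cout):
            masked += 1
            continue
        counted += 1
        col_sites = SiteCounts()
        for c in (ca, cb, cout):
            col_sites = col_sites + synonymous_site_fractions(c)
        sites = sites + col_sites.scaled(1.0 / 3.0)
        assignment = assign_branch_substitutions(ca, cb, cout)
        if assignment.ambiguous:
            ambiguous += 1
        contrib = assignment.averaged(_reconstruction_weights(assignment, branch_rates))
        for b in BRANCHES:
            diffs[b] = diffs[b] + contrib[b]
    return GeneBranchStats(
        gene_id=trio.gene_id,
        diffs=diffs,
        sites=sites,
        n_masked_codons=masked,
        ambiguous_columns=ambiguous,
        n_columns=counted,
    )


def dataset_branch_counts(
    trios: Iterable[CodonTrioAlignment],
    policy: str = "rate_weighted",
) -> list[GeneBranchStats]:
    """Branch counts for a set of trios with dataset-level ambiguity handling.

    ``policy="equal"`` averages tied reconstructions of ambiguous columns
    with equal weight (the column-level behavior).  ``policy="rate_weighted"``
    (default) first estimates per-branch substitution intensities from the
    unambiguous columns of the whole dataset, then weights tied
    reconstructions by those intensities — the appropriate choice when branch
    lengths are very unequal, as with a divergent outgroup.
    """
    trios = list(trios)
    if policy == "equal":
        return [gene_branch_counts(t) for t in trios]
    if policy != "rate_weighted":
        raise ValueError(f"unknown ambiguity policy: {policy!r}")
    totals = {b: {"syn": 0.0, "nonsyn": 0.0} for b in BRANCHES}
    n_cols = 0
    for t in trios:
        for ca, cb, cout in t.columns():
            if is_masked(ca) or is_masked(cb) or is_masked(cout):
                continue
            n_cols += 1
            assignment = assign_branch_substitutions(ca, cb, cout)
            if assignment.ambiguous:
                continue
            contrib = assignment.averaged()
            for b in BRANCHES:
                totals[b]["syn"] += contrib[b].syn
                totals[b]["nonsyn"] += contrib[b].nonsyn
    # add-quarter smoothing keeps weights finite when a branch shows no
    # unambiguous change of a class at all (tiny datasets)
    denom = max(n_cols, 1)
    rates = {
        b: {c: (totals[b][c] + 0.25) / denom for c in ("syn", "nonsyn")} for b in BRANCHES
    }
    # pass-1 pre-split rates are net differences; inflate by the Jukes-Cantor
    # factor so the priors reflect the actual event intensity on a divergent
    # outgroup lineage (multiple hits collapse, ~uniform-codon site fractions)
    site_per_codon = {"syn": 0.7322, "nonsyn": 2.2678}
    for c in ("syn", "nonsyn"):
        p = rates["presplit"][c] / site_per_codon[c]  # per fractional site
        if 0.0 < p < 0.75:
            rates["presplit"][c] *= _jc_correct(p) / p
    return [gene_branch_counts(t, branch_rates=rates) for t in trios]


@dataclass(frozen=True)
class PooledStats:
    """Pooled per-branch substitution rates: ratio of summed counts to summed sites."""

    branch: str
    pn: float
    ps: float
    dn: float
    ds: float
    ratio: float | None
    defined: bool
    correction: str = "none"


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p:.3f} >= 3/4: Jukes-Cantor distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pooled_dnds(
    stats: Sequence[GeneBranchStats], branch: str, correction: str = "none"
) -> PooledStats:
    """Pooled dN/dS on one branch as a ratio of sums over all genes.

    ``correction="jc"`` applies the Jukes–Cantor multiple-hit transform to the
    pooled proportions before taking the ratio; the default (``"none"``)
    reports raw proportions, adequate on branches of length ~10^-3 but
    downward-biased in dS on lineages with ~0.1+ substitutions per site.
    The ratio is undefined (``defined=False``) when no synonymous
    substitution was observed on the branch.
    """
    if not stats:
        raise ValueError("empty stats set")
    if correction not in ("none", "jc"):
        raise ValueError(f"unknown correction: {correction!r}")
    syn_subs = sum(s.diffs[branch].syn for s in stats)
    nonsyn_subs = sum(s.diffs[branch].nonsyn for s in stats)
    syn_sites = sum(s.sites.syn for s in stats)
    nonsyn_sites = sum(s.sites.nonsyn for s in stats)
    pn = nonsyn_subs / nonsyn_sites if nonsyn_sites else 0.0
    ps = syn_subs / syn_sites if syn_sites else 0.0
    if correction == "jc":
        dn, ds = _jc_correct(pn), _jc_correct(ps)
    else:
        dn, ds = pn, ps
    defined = syn_subs > 0 and ds > 0
    return PooledStats(
        branch=branch,
        pn=pn,
        ps=ps,
        dn=dn,
        ds=ds,
        ratio=(dn / ds) if defined else None,
        defined=defined,
        correction=correction,
    )


def branch_contrast_fisher(
    stats: Sequence[GeneBranchStats], branch1: str, branch2: str
) -> float:
    """Two-sided Fisher exact p for branch1 vs branch2 substitution classes.

    The 2x2 table is [branch x (nonsynonymous, synonymous)] with pooled
    fractional counts rounded half-up to integers.
    """
    table = []
    for b in (branch1, branch2):
        nonsyn = round_half_up(sum(s.diffs[b].nonsyn for s in stats))
        syn = round_half_up(sum(s.diffs[b].syn for s in stats))
        if nonsyn + syn == 0:
            raise ValueError(f"branch {b!r}: no substitutions, empty table row")
        table.append([nonsyn, syn])
    return float(_scipy_stats.fisher_exact(table, alternative="two-sided")[1])


def rank_by_dn(stats: Sequence[GeneBranchStats], branch: str) -> list[str]:
    """Gene ids sorted by descending per-gene dN; ties broken lexically."""
    return [s.gene_id for s in sorted(stats, key=lambda s: (-s.dn(branch), s.gene_id))]


def classify_genes_ns(stats: Sequence[GeneBranchStats]) -> pd.DataFrame:
    """Flag genes whose rounded nonsynonymous count is >= 1 per branch.

    Returns a boolean DataFrame indexed by gene_id with one column per branch
    plus ``both`` (nonsynonymous change on both terminal branches).
    """
    rows = {}
    for s in stats:
        rows[s.gene_id] = {b: round_half_up(s.diffs[b].nonsyn) >= 1 for b in BRANCHES}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "gene_id"
    df["both"] = df["A"] & df["B"]
    return df


def stats_table(stats: Sequence[GeneBranchStats]) -> pd.DataFrame:
    """Long-format per-gene, per-branch summary (one row per gene x branch)."""
    records = []
    for s in stats:
        for b in BRANCHES:
            records.append(
                {
                    "gene_id": s.gene_id,
                    "branch": b,
                    "syn_subs": s.diffs[b].syn,
                    "nonsyn_subs": s.diffs[b].nonsyn,
                    "syn_sites": s.sites.syn,
                    "nonsyn_sites": s.sites.nonsyn,
                    "dN": s.dn(b),
                    "dS": s.ds(b),
                    "n_masked_codons": s.n_masked_codons,
                    "ambiguous_columns": s.ambiguous_columns,
                }
            )
    return pd.DataFrame.from_records(records).sort_values(["gene_id", "branch"]).reset_index(drop=True)
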