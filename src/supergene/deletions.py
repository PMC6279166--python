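"""Gene presence/absence calling in fragmented draft assemblies.

A gene missing from a ~10x draft assembly is as likely an assembly gap as a
real deletion.  The guard used here is flanking synteny: a run of reference
genes absent from a sample is a *reliable* deletion call only if at least
``flank_k`` reference-adjacent genes on each side of the run were assembled
on the same sample scaffold; otherwise the call is marked edge-unsupported
and never contributes to fixed-difference reports.

Gene tables are BED-like long DataFrames with columns
``scaffold, start, end, strand, gene_id, sample_id, haplotype``
(1-based inclusive coordinates), one row per annotated locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as _scipy_stats

RELIABLE = "reliable"
EDGE_UNSUPPORTED = "edge-unsupported"


@dataclass(frozen=True)
class DeletionCall:
    """One maximal run of reference genes missing from one sample."""

    sample_id: str
    genes: tuple[str, ...]
    left_flank: tuple[str, ...]
    right_flank: tuple[str, ...]
    confidence: str  # RELIABLE or EDGE_UNSUPPORTED
    scaffold: str | None = None  # scaffold carrying both flanks, if reliable


def call_missing_genes(
    reference_order: Sequence[str],
    sample_table: pd.DataFrame,
    flank_k: int = 1,
) -> list[DeletionCall]:
    """Call deletions in one sample against the reference gene order.

    ``sample_table`` holds the loci of a single sample.  Maximal runs of
    reference genes absent from the sample are reported; a run is reliable
    iff the ``flank_k`` reference genes on each side exist and are annotated
    on one common sample scaffold.  Presence is any annotated locus with the
    gene_id — partially assembled genes count as present.
    """
    if len(reference_order) == 0:
        raise ValueError("empty reference gene order")
    sample_ids = set(sample_table["sample_id"].unique())
    if len(sample_ids) != 1:
        raise ValueError(f"sample table must hold exactly one sample, got {sorted(sample_ids)}")
    (sample_id,) = sample_ids
    scaffold_of = dict(zip(sample_table["gene_id"], sample_table["scaffold"]))
    present = set(scaffold_of)

    calls = []
    i, n = 0, len(reference_order)
    while i < n:
        if reference_order[i] in present:
            i += 1
            continue
        j = i
        while j < n and reference_order[j] not in present:
            j += 1
        run = tuple(reference_order[i:j])
        left = tuple(reference_order[max(0, i - flank_k) : i])
        right = tuple(reference_order[j : j + flank_k])
        confidence, scaffold = EDGE_UNSUPPORTED, None
        if len(left) == flank_k and len(right) == flank_k:
            flank_scaffolds = {scaffold_of[g] for g in left + right}
            if len(flank_scaffolds) == 1:
                confidence = RELIABLE
                (scaffold,) = flank_scaffolds
        calls.append(
            DeletionCall(
                sample_id=sample_id,
                genes=run,
                left_flank=left,
                right_flank=right,
                confidence=confidence,
                scaffold=scaffold,
            )
        )
        i = j
    return calls


@dataclass
class HaplotypeSummary:
    """Presence/absence matrix plus fixed presence/absence differences."""

    presence: pd.DataFrame  # genes x samples, True = present
    groups: dict[str, str]  # sample_id -> haplotype group
    fixed_differences: list[dict] = field(default_factory=list)


def haplotype_deletion_summary(
    reference_order: Sequence[str],
    sample_table: pd.DataFrame,
    flank_k: int = 1,
) -> HaplotypeSummary:
    """Summarize deletion calls across samples by haplotype group.

    A gene is a fixed presence/absence difference when it is absent from
    every sample of one group, covered by a *reliable* deletion call in at
    least one of them, and present in every sample of the other group.
    (Requiring flanking support in every single sample would make fixed
    calls vanish under realistic fragmentation even when the deletion is
    reliably demonstrated in most samples; one fully supported sample plus
    universal absence is the operative evidence.)
    """
    if sample_table["haplotype"].isna().any():
        raise ValueError("every sample must carry a haplotype label")
    groups = (
        sample_table[["sample_id", "haplotype"]]
        .drop_duplicates()
        .set_index("sample_id")["haplotype"]
        .to_dict()
    )
    samples = sorted(groups)
    presence = pd.DataFrame(True, index=list(reference_order), columns=samples)
    presence.index.name = "gene_id"
    reliably_absent = pd.DataFrame(False, index=list(reference_order), columns=samples)
    for sample_id in samples:
        sub = sample_table[sample_table["sample_id"] == sample_id]
        found = set(sub["gene_id"])
        for gene in reference_order:
            presence.loc[gene, sample_id] = gene in found
        for call in call_missing_genes(reference_order, sub, flank_k=flank_k):
            if call.confidence == RELIABLE:
                for gene in call.genes:
                    reliably_absent.loc[gene, sample_id] = True

    fixed = []
    labels = sorted(set(groups.values()))
    for gene in reference_order:
        for absent_group in labels:
            absent_samples = [s for s in samples if groups[s] == absent_group]
            other_samples = [s for s in samples if groups[s] != absent_group]
            if not absent_samples or not other_samples:
                continue
            if (
                not any(presence.loc[gene, s] for s in absent_samples)
                and any(reliably_absent.loc[gene, s] for s in absent_samples)
                and all(presence.loc[gene, s] for s in other_samples)
            ):
                fixed.append({"gene_id": gene, "absent_in": absent_group})
    return HaplotypeSummary(presence=presence, groups=groups, fixed_differences=fixed)


def deletion_frequency_lower_bound(k: int, n: int, conf: float = 0.95) -> float:
    """One-sided Clopper-Pearson lower bound on a deletion's frequency.

    ``k`` carriers observed among ``n`` sampled haplotypes.  For k = n the
    bound has the closed form (1 - conf)^(1/n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 0.0
    return float(_scipy_stats.beta.ppf(1.0 - conf, k, n - k + 1))
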