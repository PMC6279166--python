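"""Synthetic-data generators with exact ground-truth logs.

Every downstream stage of the package (dN/dS, deletion scan, qPCR, site
clustering) can be exercised end-to-end on data generated here, with a
:class:`TruthLog` recording each planted event so recovery can be checked
exactly.

Codon evolution model
---------------------
Sequences evolve by single-nucleotide proposals with transition/transversion
bias ``kappa``; proposals creating a stop codon are rejected.  The branch
``omega`` parameters are *dN/dS ratios of the generating process*: the
nonsynonymous rate multiplier is continuously calibrated against the current
sequence so that the instantaneous nonsynonymous flux per nonsynonymous
(Nei–Gojobori) site divided by the synonymous flux per synonymous site equals
``omega`` exactly.  (A fixed acceptance probability of ``omega`` for
nonsynonymous proposals would *not* achieve this under kappa != 1, because
transitions are enriched for synonymous changes; the naive scheme yields a
generating dN/dS of ~0.84*omega at kappa=2.)  Branch lengths are expected
substitutions per nucleotide site: the number of accepted substitutions on a
branch of length ``t`` over ``L`` codons is Poisson(3*L*t).

The tree is a symmetric trio: an ancestor evolves along the outgroup branch
(length ``t_presplit``) to the outgroup sequence and along the internal
pre-split branch (also ``t_presplit``) to the haplotype ancestor, which then
splits into the A and B terminal branches.  Events on the outgroup and
internal branches are pooled as "presplit" in the truth log, matching the
unpolarized pre-split lineage that 3-taxon parsimony can measure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codons import (
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    TRANSITIONS,
    GENETIC_CODE,
    synonymous_site_fractions,
)
from .dnds import BRANCHES, CodonTrioAlignment

_STAGE_KEYS = {"trios": 0, "assemblies": 1, "ct": 2, "sites": 3}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for one simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],)))


@dataclass(frozen=True)
class DeletionPlan:
    """A run of ``length`` cluster genes deleted in carriers of one group.

    ``start`` is the 0-based index of the first deleted gene in the reference
    cluster order; ``carrier_fraction`` is the probability that a sample of
    ``group`` carries the deletion.
    """

    start: int
    length: int
    group: str
    carrier_fraction: float = 1.0


@dataclass(frozen=True)
class SimulatorConfig:
    """All knobs of the synthetic study, with defaults set to the study scale.

    The trio scenario defaults emulate 331 single-copy orthologs of 390
    codons with terminal branch lengths 0.00105 (A) and 0.00153 (B)
    substitutions/site, branch dN/dS of 0.099 (pre-split), 0.087 (A) and
    0.209 (B), and an outgroup divergence calibrated so haplotype/outgroup
    protein identity is ~89%.  The cluster scenario plants a fixed two-gene
    deletion (genes 13-14 of a 23-gene head-to-tail cluster) in all 8 B-group
    samples; the qPCR scenario gives heterozygous carriers a 0.5 copy ratio
    at the deleted genes with 0.2-cycle replicate noise.
    """

    n_genes: int = 331
    gene_length: int = 390  # codons
    kappa: float = 2.0
    omega_presplit: float = 0.099
    omega_a: float = 0.087
    omega_b: float = 0.209
    t_presplit: float | None = None  # None: calibrated from presplit_identity
    presplit_identity: float = 0.89
    t_a: float = 0.00105
    t_b: float = 0.00153
    n_samples_a: int = 8
    n_samples_b: int = 8
    cluster_genes: int = 23
    gene_span_bp: int = 1200
    gene_gap_bp: int = 300
    deletion_plan: tuple[DeletionPlan, ...] = (DeletionPlan(12, 2, "B", 1.0),)
    mean_scaffold_genes: float | None = 5.0  # None disables fragmentation
    n_ct_samples: int = 10
    ct_noise_sd: float = 0.2
    ct_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0 or self.gene_length < 1:
            raise ValueError("n_genes must be >= 0 and gene_length >= 1")
        for name in ("omega_presplit", "omega_a", "omega_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("t_a", "t_b", "kappa", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_presplit is not None and self.t_presplit < 0:
            raise ValueError("t_presplit must be >= 0")
        if not 0 < self.presplit_identity <= 1:
            raise ValueError("presplit_identity must be in (0, 1]")
        for plan in self.deletion_plan:
            if not 0 <= plan.carrier_fraction <= 1:
                raise ValueError("carrier fraction must be in [0, 1]")
            if plan.start < 0 or plan.start + plan.length > self.cluster_genes:
                raise ValueError(f"deletion run {plan} outside cluster of {self.cluster_genes}")

    def resolved_t_presplit(self) -> float:
        if self.t_presplit is not None:
            return self.t_presplit
        return calibrate_presplit_length(self.presplit_identity, self.omega_presplit)


def calibrate_presplit_length(identity: float, omega: float) -> float:
    """Per-branch pre-split length giving a target haplotype/outgroup protein identity.

    The haplotype and outgroup sequences are separated by twice the pre-split
    branch length; a codon keeps its amino acid iff it receives no
    nonsynonymous event (back-substitutions are ignored, a <1% effect at the
    divergences used here), so identity ~ exp(-3 * 2t * f_n) with f_n the
    nonsynonymous fraction of the calibrated substitution flux.
    """
    s_u = sum(synonymous_site_fractions(c).syn for c in SENSE_CODONS) / len(SENSE_CODONS)
    n_u = 3.0 - s_u
    f_n = omega * n_u / (s_u + omega * n_u)
    return -math.log(identity) / (6.0 * f_n)


# ---------------------------------------------------------------------------
# Vectorized codon tables for the evolution loop
# ---------------------------------------------------------------------------

class _CodonTables:
    def __init__(self, kappa: float):
        n = len(SENSE_CODONS)
        self.index = {c: i for i, c in enumerate(SENSE_CODONS)}
        self.nb_idx = np.full((n, 9), -1, dtype=np.int64)
        self.nb_syn = np.zeros((n, 9), dtype=bool)
        self.nb_w = np.zeros((n, 9))
        self.s_u = np.zeros(n)
        self.n_u = np.zeros(n)
        for i, c in enumerate(SENSE_CODONS):
            aa = GENETIC_CODE[c]
            k = 0
            for pos in range(3):
                for nt in NUCLEOTIDES:
                    if nt == c[pos]:
                        continue
                    alt = c[:pos] + nt + c[pos + 1 :]
                    if alt not in STOP_CODONS:
                        self.nb_idx[i, k] = self.index[alt]
                        self.nb_syn[i, k] = GENETIC_CODE[alt] == aa
                        self.nb_w[i, k] = kappa if (c[pos], nt) in TRANSITIONS else 1.0
                    k += 1
            sc = synonymous_site_fractions(c)
            self.s_u[i], self.n_u[i] = sc.syn, sc.nonsyn
        self.w_syn = (self.nb_w * self.nb_syn).sum(axis=1)
        self.w_non = (self.nb_w * (~self.nb_syn) * (self.nb_idx >= 0)).sum(axis=1)


_TABLE_CACHE: dict[float, _CodonTables] = {}


def _tables(kappa: float) -> _CodonTables:
    tab = _TABLE_CACHE.get(kappa)
    if tab is None:
        tab = _TABLE_CACHE[kappa] = _CodonTables(kappa)
    return tab


def _weighted_pick(rng: np.random.Generator, weights: np.ndarray) -> int:
    cum = np.cumsum(weights)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def evolve_sequence(
    seq: np.ndarray,
    t: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
    recorder: list | None = None,
) -> tuple[np.ndarray, int, int]:
    """Evolve codon-index array ``seq`` along a branch; return (seq', n_syn, n_nonsyn).

    The number of accepted substitutions is Poisson(3 * len(seq) * t); the
    nonsynonymous rate multiplier is recomputed from the current sequence at
    every event so the instantaneous dN/dS stays exactly ``omega``.
    ``recorder``, if given, receives one ``(codon_index, is_synonymous)``
    tuple per accepted substitution in event order.
    """
    tab = _tables(kappa)
    seq = seq.copy()
    L = len(seq)
    n_events = rng.poisson(3 * L * t)
    if recorder is None:
        record = None
    else:
        record = recorder.append
    ws = tab.w_syn[seq].copy()
    wn = tab.w_non[seq].copy()
    su = float(tab.s_u[seq].sum())
    nu = float(tab.n_u[seq].sum())
    n_syn = n_nonsyn = 0
    for _ in range(n_events):
        ts, tn = float(ws.sum()), float(wn.sum())
        if ts > 0 and tn > 0 and su > 0:
            m = omega * (nu / su) * (ts / tn)
            p_syn = ts / (ts + m * tn)
        else:
            p_syn = 1.0 if tn == 0 else 0.0
        synonymous = rng.random() < p_syn
        pos = _weighted_pick(rng, ws if synonymous else wn)
        c = seq[pos]
        w9 = tab.nb_w[c] * (tab.nb_syn[c] == synonymous) * (tab.nb_idx[c] >= 0)
        new_c = int(tab.nb_idx[c, _weighted_pick(rng, w9)])
        seq[pos] = new_c
        ws[pos] = tab.w_syn[new_c]
        wn[pos] = tab.w_non[new_c]
        su += tab.s_u[new_c] - tab.s_u[c]
        nu += tab.n_u[new_c] - tab.n_u[c]
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
        if record is not None:
            record((int(pos), bool(synonymous)))
    return seq, n_syn, n_nonsyn


# ---------------------------------------------------------------------------
# Truth log
# ---------------------------------------------------------------------------

@dataclass
class TruthLog:
    """Registry of every simulated event, for exact recovery checks.

    ``trio_counts[gene_id][branch]`` holds realized {"syn": n, "nonsyn": n};
    ``deletions`` lists planted runs with their carriers; ``copy_ratios``
    maps group -> gene -> planted copy-number ratio.
    """

    trio_counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    deletions: list[dict] = field(default_factory=list)
    copy_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    site_model: dict = field(default_factory=dict)
    column_events: dict[str, dict[str, list]] = field(default_factory=dict)

    def branch_totals(self, branch: str) -> dict[str, int]:
        tot = {"syn": 0, "nonsyn": 0}
        for counts in self.trio_counts.values():
            tot["syn"] += counts[branch]["syn"]
            tot["nonsyn"] += counts[branch]["nonsyn"]
        return tot

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLog":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Stage 1: codon trio alignments
# ---------------------------------------------------------------------------

def simulate_trio_alignments(
    config: SimulatorConfig,
    detailed: bool = False,
) -> tuple[list[CodonTrioAlignment], TruthLog]:
    """Simulate per-gene haplotype-A/haplotype-B/outgroup codon alignments.

    With ``detailed=True`` the truth log additionally records the codon
    position and class of every event per gene and branch
    (``column_events[gene_id][branch]`` as ``[[codon_index, is_syn], ...]``).
    """
    rng = stage_rng(config.seed, "trios")
    tab = _tables(config.kappa)
    t_pre = config.resolved_t_presplit()
    truth = TruthLog()
    trios = []
    width = max(3, len(str(config.n_genes)))
    to_str = np.array(SENSE_CODONS)
    for g in range(config.n_genes):
        gene_id = f"g{g + 1:0{width}d}"
        recs = {b: [] for b in BRANCHES} if detailed else {b: None for b in BRANCHES}
        ancestor = rng.integers(0, len(SENSE_CODONS), size=config.gene_length)
        out_seq, s1, n1 = evolve_sequence(
            ancestor, t_pre, config.omega_presplit, config.kappa, rng, recs["presplit"]
        )
        node, s2, n2 = evolve_sequence(
            ancestor, t_pre, config.omega_presplit, config.kappa, rng, recs["presplit"]
        )
        a_seq, sa, na = evolve_sequence(node, config.t_a, config.omega_a, config.kappa, rng, recs["A"])
        b_seq, sb, nb = evolve_sequence(node, config.t_b, config.omega_b, config.kappa, rng, recs["B"])
        truth.trio_counts[gene_id] = {
            "presplit": {"syn": s1 + s2, "nonsyn": n1 + n2},
            "A": {"syn": sa, "nonsyn": na},
            "B": {"syn": sb, "nonsyn": nb},
        }
        if detailed:
            truth.column_events[gene_id] = {
                b: [[pos, syn] for pos, syn in recs[b]] for b in BRANCHES
            }
        trios.append(
            CodonTrioAlignment(
                gene_id=gene_id,
                seq_a="".join(to_str[a_seq]),
                seq_b="".join(to_str[b_seq]),
                seq_out="".join(to_str[out_seq]),
            )
        )
    return trios, truth


# ---------------------------------------------------------------------------
# Stage 2: tandem-cluster assemblies with planted deletions
# ---------------------------------------------------------------------------

def _cluster_gene_ids(n: int) -> list[str]:
    return [f"or{i + 1:02d}" for i in range(n)]


def reference_gene_table(config: SimulatorConfig) -> pd.DataFrame:
    """Head-to-tail reference cluster: scaffold, start, end, strand, gene_id."""
    rows = []
    pos = 1
    for gid in _cluster_gene_ids(config.cluster_genes):
        rows.append(
            {
                "scaffold": "ref_scf1",
                "start": pos,
                "end": pos + config.gene_span_bp - 1,
                "strand": "+",
                "gene_id": gid,
                "sample_id": "reference",
                "haplotype": "reference",
            }
        )
        pos += config.gene_span_bp + config.gene_gap_bp
    return pd.DataFrame(rows)


def simulate_cluster_assemblies(
    config: SimulatorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLog]:
    """Per-sample fragmented gene tables with planted deletions.

    Returns ``(reference_table, sample_table, truth)``; the sample table is a
    long BED-like frame (1-based inclusive coordinates) over all samples.
    """
    rng = stage_rng(config.seed, "assemblies")
    gene_ids = _cluster_gene_ids(config.cluster_genes)
    reference = reference_gene_table(config)
    truth = TruthLog()
    samples = [(f"A{i + 1}", "A") for i in range(config.n_samples_a)] + [
        (f"B{i + 1}", "B") for i in range(config.n_samples_b)
    ]
    plan_carriers: list[list[str]] = [[] for _ in config.deletion_plan]
    rows = []
    for sample_id, group in samples:
        deleted: set[str] = set()
        for p_idx, plan in enumerate(config.deletion_plan):
            if group == plan.group and rng.random() < plan.carrier_fraction:
                deleted.update(gene_ids[plan.start : plan.start + plan.length])
                plan_carriers[p_idx].append(sample_id)
        kept = [g for g in gene_ids if g not in deleted]
        # fragmentation: independent breakpoint in each inter-gene gap
        p_break = (
            0.0
            if not config.mean_scaffold_genes or math.isinf(config.mean_scaffold_genes)
            else min(1.0, 1.0 / config.mean_scaffold_genes)
        )
        scaffold_no, pos = 1, 1
        for j, gid in enumerate(kept):
            if j > 0 and rng.random() < p_break:
                scaffold_no += 1
                pos = 1
            rows.append(
                {
                    "scaffold": f"{sample_id}_scf{scaffold_no}",
                    "start": pos,
                    "end": pos + config.gene_span_bp - 1,
                    "strand": "+",
                    "gene_id": gid,
                    "sample_id": sample_id,
                    "haplotype": group,
                }
            )
            pos += config.gene_span_bp + config.gene_gap_bp
    for plan, carriers in zip(config.deletion_plan, plan_carriers):
        truth.deletions.append(
            {
                "genes": gene_ids[plan.start : plan.start + plan.length],
                "group": plan.group,
                "carrier_fraction": plan.carrier_fraction,
                "carriers": carriers,
            }
        )
    return reference, pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Stage 3: qPCR Ct panel
# ---------------------------------------------------------------------------

HOUSEKEEPING_GENES = ("hkg1", "hkg2")


def simulate_ct_panel(
    config: SimulatorConfig,
    target_genes: Sequence[str] | None = None,
    deleted_genes: Sequence[str] | None = None,
    groups: Sequence[str] = ("AA", "AB"),
    het_group: str = "AB",
) -> tuple[pd.DataFrame, TruthLog]:
    """Long-format Ct panel with a planted heterozygous-deletion effect.

    ``het_group`` samples carry copy number 0.5 at ``deleted_genes`` and 1
    elsewhere; all other groups have copy number 1 everywhere.  Per replicate,
    Ct = gene baseline + per-sample offset - log2(copy) + Normal(0, sd); the
    per-sample offset models DNA input differences and is exactly what
    housekeeping normalization removes.  Defaults derive from the cluster
    scenario: targets are the planted deletion run plus its two neighbors.
    """
    rng = stage_rng(config.seed, "ct")
    gene_ids = _cluster_gene_ids(config.cluster_genes)
    if deleted_genes is None:
        deleted_genes = [
            g
            for plan in config.deletion_plan
            for g in gene_ids[plan.start : plan.start + plan.length]
        ]
    if target_genes is None:
        idx = sorted(gene_ids.index(g) for g in deleted_genes)
        lo, hi = (idx[0], idx[-1]) if idx else (0, -1)
        target_genes = [
            gene_ids[i] for i in range(max(0, lo - 1), min(len(gene_ids), hi + 2))
        ] or gene_ids[:1]
    if len(groups) < 2:
        raise ValueError("need >= 2 sample groups")
    truth = TruthLog()
    baselines = {g: 20.0 + 4.0 * rng.random() for g in (*target_genes, *HOUSEKEEPING_GENES)}
    rows = []
    for group in groups:
        truth.copy_ratios[group] = {}
        for gene in target_genes:
            truth.copy_ratios[group][gene] = (
                0.5 if group == het_group and gene in deleted_genes else 1.0
            )
        for s in range(config.n_ct_samples):
            sample_id = f"{group}_{s + 1}"
            offset = rng.normal(0.0, 0.5)
            for gene in (*target_genes, *HOUSEKEEPING_GENES):
                role = "housekeeping" if gene in HOUSEKEEPING_GENES else "target"
                copy = truth.copy_ratios[group].get(gene, 1.0)
                for rep in range(config.ct_replicates):
                    ct = (
                        baselines[gene]
                        + offset
                        - math.log2(copy)
                        + (rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0)
                    )
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "gene_id": gene,
                            "role": role,
                            "replicate": rep + 1,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Stage 4: site annotations on a receptor architecture
# ---------------------------------------------------------------------------

def simulate_site_annotations(
    config: SimulatorConfig,
    architecture=None,
    n_sites: int = 33,
    enriched_segment: str | None = None,
    enrichment_factor: float = 1.0,
    annotation: str = "positively-selected",
) -> tuple[pd.DataFrame, "object", TruthLog]:
    """Draw distinct selected-site positions on a domain architecture.

    Uniform over the protein, or with ``enrichment_factor``-fold higher
    density inside ``enriched_segment``.  Returns (sites, architecture,
    truth); sites is a frame with columns position/annotation/multiplicity.
    """
    from .structure import default_or_architecture

    if architecture is None:
        architecture = default_or_architecture()
    rng = stage_rng(config.seed, "sites")
    L = architecture.length
    if n_sites > L:
        raise ValueError(f"cannot place {n_sites} distinct sites on {L} positions")
    weights = np.ones(L)
    if enriched_segment is not None:
        seg = architecture.segment(enriched_segment)
        weights[seg.start - 1 : seg.end] = enrichment_factor
    weights = weights / weights.sum()
    positions = np.sort(rng.choice(L, size=n_sites, replace=False, p=weights)) + 1
    sites = pd.DataFrame(
        {
            "position": positions.astype(int),
            "annotation": annotation,
            "multiplicity": 1,
        }
    )
    truth = TruthLog(
        site_model={
            "model": "uniform" if enriched_segment is None else "enriched",
            "enriched_segment": enriched_segment,
            "enrichment_factor": enrichment_factor,
            "n_sites": int(n_sites),
        }
    )
    return sites, architecture, truth
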