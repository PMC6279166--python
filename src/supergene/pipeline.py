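"""End-to-end orchestration: simulate -> dnds -> delscan -> qpcr -> enrich -> structmap -> report.

Every stage is a pure function of (inputs, config): rerunning with the same
config and seed reproduces outputs byte for byte.  Each run writes a manifest
with the package version, the seed, the resolved config and SHA-256 hashes of
every artifact, plus stage-level audit counts (masked codons, ambiguous
columns, excluded replicates, edge-unsupported calls).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as _io
from .deletions import EDGE_UNSUPPORTED, RELIABLE, call_missing_genes, haplotype_deletion_summary
from .deletions import deletion_frequency_lower_bound
from .dnds import (
    BRANCHES,
    branch_contrast_fisher,
    classify_genes_ns,
    dataset_branch_counts,
    pooled_dnds,
    rank_by_dn,
    stats_table,
)
from .enrichment import chisq_enrichment, contingency_from_flags
from .qpcr import group_mean_quantities, relative_copy_number, replicate_qc
from .simulate import SimulatorConfig, simulate_cluster_assemblies, simulate_ct_panel
from .simulate import simulate_site_annotations, simulate_trio_alignments
from .structure import default_or_architecture, domain_binomial_tests, map_sites

ALL_STAGES = ("simulate", "dnds", "delscan", "qpcr", "enrich", "structmap", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly to YAML."""

    out_dir: str = "supergene_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    # analysis parameters
    flank_k: int = 1
    continuity: bool = False
    hydropathy_statistic: str = "median"
    conf_level: float = 0.95
    ambiguity_policy: str = "rate_weighted"
    dnds_correction: str = "none"
    # optional external inputs (otherwise the simulate stage provides them)
    trios_dir: str | None = None
    gene_table: str | None = None
    ct_panel: str | None = None
    sites_table: str | None = None
    membership_table: str | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "simulator" in raw and isinstance(raw["simulator"], dict):
            sim_raw = dict(raw["simulator"])
            sim_known = {f.name for f in fields(SimulatorConfig)}
            sim_unknown = set(sim_raw) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulator keys: {sorted(sim_unknown)}")
            if "deletion_plan" in sim_raw:
                from .simulate import DeletionPlan

                sim_raw["deletion_plan"] = tuple(
                    DeletionPlan(**p) if isinstance(p, dict) else DeletionPlan(*p)
                    for p in sim_raw["deletion_plan"]
                )
            raw["simulator"] = SimulatorConfig(**sim_raw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["stages"] = list(self.stages)
        raw["simulator"]["deletion_plan"] = [
            dataclasses.asdict(p) for p in self.simulator.deletion_plan
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages; return the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulator, seed=config.seed)
    report: dict = {"seed": config.seed, "version": __version__}
    audit: dict = {}
    artifacts: list[Path] = []

    trios = truth = None
    if "simulate" in config.stages:
        trios, truth = simulate_trio_alignments(sim)
        trio_dir = out / "trios"
        artifacts += _io.write_trio_dir(trios, trio_dir)
        reference, sample_table, del_truth = simulate_cluster_assemblies(sim)
        _io.write_tsv(reference, out / "reference_genes.tsv")
        _io.write_tsv(sample_table, out / "sample_genes.tsv")
        panel, ct_truth = simulate_ct_panel(sim)
        _io.write_tsv(panel, out / "ct_panel.tsv")
        sites, arch, site_truth = simulate_site_annotations(sim)
        _io.write_tsv(sites, out / "sites.tsv")
        _io.write_tsv(arch.to_frame(), out / "architecture.tsv")
        truth.deletions = del_truth.deletions
        truth.copy_ratios = ct_truth.copy_ratios
        truth.site_model = site_truth.site_model
        truth.to_json(out / "truth.json")
        artifacts += [
            out / "reference_genes.tsv", out / "sample_genes.tsv", out / "ct_panel.tsv",
            out / "sites.tsv", out / "architecture.tsv", out / "truth.json",
        ]

    flags = None
    if "dnds" in config.stages:
        if trios is None:
            trio_dir = Path(config.trios_dir or out / "trios")
            trios = _io.read_trio_dir(trio_dir) if trio_dir.is_dir() else []
            if not trios:
                raise FileNotFoundError(f"no trio FASTA files found in {trio_dir}")
        stats = dataset_branch_counts(trios, policy=config.ambiguity_policy)
        table = stats_table(stats)
        _io.write_tsv(table, out / "dnds_per_gene.tsv")
        pooled = {}
        for b in BRANCHES:
            p = pooled_dnds(stats, b, correction=config.dnds_correction)
            pooled[b] = {
                "pN": p.pn, "pS": p.ps, "dN": p.dn, "dS": p.ds,
                "ratio": p.ratio, "defined": p.defined, "correction": p.correction,
            }
        fisher_p = branch_contrast_fisher(stats, "A", "B")
        flags_df = classify_genes_ns(stats)
        _io.write_tsv(flags_df.reset_index(), out / "gene_flags.tsv")
        pooled_summary = {
            "pooled": pooled,
            "fisher_A_vs_B_p": fisher_p,
            "top_genes_by_dN_B": rank_by_dn(stats, "B")[:10],
        }
        _io.write_json(pooled_summary, out / "dnds_pooled.json")
        report["dnds"] = pooled_summary
        audit["dnds"] = {
            "n_genes": len(stats),
            "masked_codons": int(sum(s.n_masked_codons for s in stats)),
            "ambiguous_columns": int(sum(s.ambiguous_columns for s in stats)),
        }
        flags = flags_df
        artifacts += [out / "dnds_per_gene.tsv", out / "gene_flags.tsv", out / "dnds_pooled.json"]

    if "delscan" in config.stages:
        ref_path = Path(config.gene_table or out / "sample_genes.tsv")
        sample_table = _io.read_gene_table(out / "sample_genes.tsv" if config.gene_table is None else ref_path)
        reference = _io.read_gene_table(out / "reference_genes.tsv") if (out / "reference_genes.tsv").exists() else None
        if reference is None:
            raise FileNotFoundError("delscan needs a reference gene table (run simulate or provide one)")
        ref_order = list(reference.sort_values("start")["gene_id"])
        all_calls = []
        for sample_id, sub in sample_table.groupby("sample_id"):
            all_calls += call_missing_genes(ref_order, sub, flank_k=config.flank_k)
        calls_df = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "genes": ",".join(c.genes),
                    "left_flank": ",".join(c.left_flank),
                    "right_flank": ",".join(c.right_flank),
                    "confidence": c.confidence,
                    "scaffold": c.scaffold or "",
                }
                for c in all_calls
            ]
        )
        _io.write_tsv(calls_df, out / "deletion_calls.tsv")
        summary = haplotype_deletion_summary(ref_order, sample_table, flank_k=config.flank_k)
        fixed = summary.fixed_differences
        n_group = {
            g: sum(1 for s in summary.groups.values() if s == g)
            for g in set(summary.groups.values())
        }
        bounds = {}
        for item in fixed:
            n = n_group[item["absent_in"]]
            bounds[item["gene_id"]] = deletion_frequency_lower_bound(n, n, config.conf_level)
        delscan_summary = {"fixed_differences": fixed, "frequency_lower_bounds": bounds}
        _io.write_json(delscan_summary, out / "deletion_summary.json")
        report["delscan"] = delscan_summary
        audit["delscan"] = {
            "n_calls": len(all_calls),
            "edge_unsupported": sum(1 for c in all_calls if c.confidence == EDGE_UNSUPPORTED),
            "reliable": sum(1 for c in all_calls if c.confidence == RELIABLE),
        }
        artifacts += [out / "deletion_calls.tsv", out / "deletion_summary.json"]

    if "qpcr" in config.stages:
        panel = _io.read_ct_panel(config.ct_panel or out / "ct_panel.tsv")
        qc = replicate_qc(panel)
        rel = relative_copy_number(qc.panel, calibrator_group="AA")
        _io.write_tsv(rel, out / "copy_number.tsv")
        means = group_mean_quantities(rel)
        _io.write_tsv(means, out / "copy_number_groups.tsv")
        report["qpcr"] = {
            row["group"] + ":" + row["gene_id"]: row["mean_quantity"]
            for _, row in means.iterrows()
        }
        audit["qpcr"] = {
            "excluded_replicates": len(qc.excluded_replicates),
            "dropped_measurements": len(qc.dropped_measurements),
        }
        artifacts += [out / "copy_number.tsv", out / "copy_number_groups.tsv"]

    if "enrich" in config.stages and flags is not None:
        if config.membership_table:
            membership_df = pd.read_csv(config.membership_table, sep="\t")
            membership = dict(zip(membership_df["gene_id"], membership_df["family"].astype(bool)))
        else:
            # demo convention for the synthetic run: the first cluster_genes
            # gene ids form the "family"
            genes = sorted(flags.index)
            membership = {g: i < sim.cluster_genes for i, g in enumerate(genes)}
        enrich = {}
        for b in ("A", "B"):
            table = contingency_from_flags(
                {g: bool(flags.loc[g, b]) for g in membership}, membership
            )
            res = chisq_enrichment(table, continuity=config.continuity)
            enrich[b] = {
                "table": [[table.a, table.b], [table.c, table.d]],
                "chi2": res.statistic,
                "p": res.pvalue,
                "defined": res.defined,
            }
        _io.write_json(enrich, out / "enrichment.json")
        report["enrichment"] = enrich
        artifacts.append(out / "enrichment.json")

    if "structmap" in config.stages:
        sites_path = config.sites_table or out / "sites.tsv"
        sites = pd.read_csv(sites_path, sep="\t")
        arch = default_or_architecture()
        counts = map_sites(sites, arch)
        tests = domain_binomial_tests(counts, arch)
        _io.write_tsv(tests, out / "domain_tests.tsv")
        report["structmap"] = {
            row["label"]: {"observed": int(row["observed"]), "p": row["p"], "q": row["q"]}
            for _, row in tests.iterrows()
            if row["observed"] > 0
        }
        artifacts.append(out / "domain_tests.tsv")

    if "report" in config.stages:
        report["audit"] = audit
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stages": list(config.stages),
            "artifacts": {str(p.relative_to(out)): _io.sha256_of(p) for p in sorted(set(artifacts))},
        }
        _io.write_json(manifest, out / "manifest.json")
        _io.write_json(report, out / "report.json")
    return report
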