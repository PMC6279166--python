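"""Calling a fixed two-gene deletion from fragmented draft assemblies.

Simulates a 23-gene tandem cluster in 8 + 8 haploid samples where all B
samples carry a two-gene deletion, fragments each assembly into scaffolds,
then calls deletions with the flanking-synteny rule and bounds the deletion
frequency with a Clopper-Pearson interval.
"""

from supergene import (
    SimulatorConfig,
    call_missing_genes,
    deletion_frequency_lower_bound,
    haplotype_deletion_summary,
    simulate_cluster_assemblies,
)

config = SimulatorConfig(seed=8)
reference, samples, truth = simulate_cluster_assemblies(config)
ref_order = list(reference["gene_id"])
print(f"planted deletion: {truth.deletions[0]['genes']} in all B samples\n")

for sample_id in ("B1", "B2", "A1"):
    sub = samples[samples["sample_id"] == sample_id]
    calls = call_missing_genes(ref_order, sub, flank_k=1)
    shown = [f"{','.join(c.genes)} [{c.confidence}]" for c in calls] or ["none"]
    print(f"{sample_id}: missing runs -> {'; '.join(shown)}")

summary = haplotype_deletion_summary(ref_order, samples, flank_k=1)
print("\nfixed presence/absence differences:", summary.fixed_differences)
n = config.n_samples_b
print(
    f"deletion seen in {n}/{n} B haplotypes -> frequency > "
    f"{deletion_frequency_lower_bound(n, n, 0.95):.3f} (95% one-sided lower bound)"
)
print("Only runs whose flanking genes sit on one scaffold are 'reliable';")
print("runs at scaffold edges stay 'edge-unsupported' and never enter the")
print("fixed-difference report.")
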