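"""Branch-specific dN/dS on simulated haplotype/outgroup trios.

Simulates 60 genes with distinct dN/dS on the pre-split lineage and the two
terminal haplotype branches, then recovers the pooled per-branch ratios and
contrasts the terminals with Fisher's exact test.
"""

from supergene import (
    SimulatorConfig,
    branch_contrast_fisher,
    dataset_branch_counts,
    pooled_dnds,
    simulate_trio_alignments,
)

config = SimulatorConfig(n_genes=60, seed=4)
trios, truth = simulate_trio_alignments(config)
stats = dataset_branch_counts(trios, policy="rate_weighted")

print(f"{len(trios)} genes x {config.gene_length} codons, "
      f"terminal branch lengths {config.t_a}/{config.t_b} subs/site\n")
for branch, configured in [
    ("A", config.omega_a),
    ("B", config.omega_b),
    ("presplit", config.omega_presplit),
]:
    pooled = pooled_dnds(stats, branch, correction="jc")
    print(
        f"branch {branch:9s} dN={pooled.dn:.5f} dS={pooled.ds:.5f} "
        f"dN/dS={pooled.ratio:.3f} (simulated at {configured})"
    )

p = branch_contrast_fisher(stats, "A", "B")
print(f"\nFisher exact, A vs B substitution classes: P = {p:.3g}")
print("dN/dS < 1 on every branch is purifying selection; the B haplotype's")
print("higher ratio reflects its relaxed selection, and the Fisher test asks")
print("whether the two terminal branches differ in their nonsyn:syn balance.")
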