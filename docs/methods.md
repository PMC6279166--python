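# Methods

This note documents the models, estimators and numerical conventions behind
`supergene`, the choices that were genuinely open, and what the synthetic
data do and do not establish about real data.

## 1. Counting-based dN/dS on codon trios

### Sites and differences

Per sense codon (standard nuclear code, 61 sense codons), the synonymous
site count is the sum over the three positions of the fraction of the three
possible single-nucleotide changes that preserve the amino acid; synonymous
plus nonsynonymous sites equal 3 exactly.  Changes producing a stop codon
are counted as nonsynonymous *opportunity* but are excluded as *pathways*:
for a codon pair differing at k positions, the syn/nonsyn classification is
averaged over the k! step orderings, with orderings passing through a stop
excluded and the average renormalized.  If every ordering is blocked the
plain average over all orderings is used and the result flagged
(`blocked_fallback`); stop-crossing steps then count as nonsynonymous.
Masking is per codon: a codon containing `N` or `-` removes the whole
alignment column from counting (and exactly 3 sites from the denominator).

### Branch assignment on the 3-taxon star

Each column (codon in haplotype A, haplotype B, outgroup) is assigned by
parsimony.  Candidate internal-node states come from positionwise majority
vote (a position where all three sequences differ is a three-way tie);
candidate stop codons are discarded, with a full scan over sense codons as a
fallback.  Shared derived states map to the unpolarized "pre-split" lineage —
with a single outgroup, changes on the internal branch and on the outgroup
branch cannot be told apart, so they are pooled and reported as one lineage.
Columns whose three codons are pairwise distinct are flagged ambiguous and,
by default, averaged with equal weight over the minimally parsimonious
reconstructions.

Equal weighting is exact when branch lengths are comparable, but here the
outgroup lineage is ~100× longer than the terminal branches, and two effects
bias plain parsimony at that asymmetry:

1. *Ambiguous columns.*  A reconstruction placing a change on a 10⁻³-length
   terminal branch is far less likely a priori than one placing it on the
   10⁻¹-length outgroup lineage, and the two terminal branches differ both
   in length and in their syn/nonsyn mix.
2. *Back-coincidences.*  A pre-split change followed by a reverting change
   on one terminal branch reproduces the outgroup state there, and parsimony
   then reads the column as a single event on the *other* terminal branch.
   The rate of such columns scales with (outgroup divergence) × (terminal
   branch length), which at this design is the same order as the terminal
   signal itself.

`dataset_branch_counts(policy="rate_weighted")` (the default for
whole-dataset analyses) therefore runs two passes: pass 1 estimates
per-branch, per-class (synonymous/nonsynonymous) substitution intensities
from the unambiguous columns (with +0.25 smoothing, and with the pre-split
intensities inflated by the Jukes–Cantor factor since net differences
undercount events on a divergent lineage); pass 2 weights the candidate
reconstructions of each column by the product over steps of
(branch class-rate) × (probability that a class event from that codon is the
specific observed change, approximated as 1 / number of sense changes of
that class).  The candidate set includes, beyond the minimal
reconstructions, the leaf codons themselves as one-extra-step internal
states, which is what lets the weighting re-apportion back-coincidence
columns.  These weight ratios mirror the relative probabilities of the
competing event histories, so the redistribution is calibrated rather than
heuristic; on study-scale simulations it reduces terminal-branch count
biases from ~+10 % (equal weighting) to within ±3 %.
`policy="equal"` retains pure minimum parsimony.

### Pooling, contrast, ranking

Per-branch dN/dS is a ratio of sums across genes (not a mean of per-gene
ratios — most genes have zero synonymous changes on the terminal branches,
making per-gene ratios undefined): pN = Σ nonsyn subs / Σ nonsyn sites, and
the ratio pN/pS is flagged undefined when no synonymous substitution was
observed.  Site denominators are the mean of the three sequences' site
fractions over unmasked columns, shared across branches (per-branch
denominators would differ negligibly at these divergences).  The optional
`correction="jc"` applies d = −(3/4)·ln(1 − 4p/3) to the pooled proportions;
it is a numerical no-op on the 10⁻³ terminal branches but necessary on the
pre-split lineage (~0.17 substitutions/site, where raw pS is ~26 % low and
the uncorrected ratio ~35 % high).  The library default is uncorrected, the
pipeline and the acceptance experiments use the corrected mode.

The A-vs-B contrast is a two-sided Fisher exact test on
[branch × (nonsyn, syn)] with fractional counts rounded half-up; gene
ranking is by per-gene dN with deterministic lexical tie-breaks; a gene is
flagged "has nonsynonymous change" when its rounded nonsynonymous count is
≥ 1 (so an ambiguity fraction of 0.5 rounds up).

## 2. Synthetic codon evolution

Sequences evolve by single-nucleotide proposals with transition bias κ
(default 2 — a typical nuclear value; the analysis never reads it), rejected
if they create a stop.  The branch parameter ω is defined as the **dN/dS of
the generating process**: at every event the nonsynonymous rate multiplier
is recomputed from the current sequence so that (nonsyn flux / nonsyn
sites) / (syn flux / syn sites) equals ω exactly, with sites counted the
Nei–Gojobori way.  A fixed acceptance probability of ω for nonsynonymous
proposals would *not* have this property under κ ≠ 1 (transitions are
enriched for synonymous changes; the naive scheme's generating dN/dS is
~0.84·ω at κ = 2), and a recovery experiment would then be comparing two
different quantities.  Branch length t is expected substitutions per
nucleotide site; events per branch are Poisson(3·L·t), sampled sequentially
with the rate structure updated after every event.  The truth log records
every event's branch and class (and position, with `detailed=True`), so
recovery checks are exact.

The tree is symmetric: ancestor (uniform over sense codons — no codon-usage
model is imposed) evolves along the outgroup branch and along the internal
pre-split branch, both of length `t_presplit`, and the haplotype ancestor
then splits into the A and B terminals.  By default `t_presplit` is
calibrated analytically so haplotype/outgroup protein identity ≈ 0.89
(measured 0.889 at the default ω of 0.099): identity ≈ exp(−6·t·f_n) with
f_n the nonsynonymous flux fraction; back-substitutions, a <1 % effect
here, are ignored.

Default scale — 331 genes × 390 codons, terminal branch lengths 0.00105 (A)
and 0.00153 (B), ω = 0.099/0.087/0.209 (pre-split/A/B) — matches the study
design this package is built around: a supergene region with ~330
single-copy orthologs against a congeneric outgroup at ~89 % protein
identity.  These defaults are the test conditions, not tuning knobs.

## 3. Deletion scan

The cluster generator lays `cluster_genes` (default 23) genes head-to-tail
(1.2 kb genes, 300 bp gaps — display plumbing only), deletes planted runs in
group-B carriers (default: genes 13–14 in all 8 B samples), and fragments
each sample's gene order into scaffolds with an independent breakpoint in
each inter-gene gap at probability 1/`mean_scaffold_genes` (default 5, the
edge-of-scaffold failure mode of ~10× drafts).

Calling: maximal runs of reference genes absent from a sample are deletion
calls; a call is **reliable** iff the `flank_k` reference-adjacent genes on
each side are present on one common sample scaffold, else
**edge-unsupported**.  `flank_k` defaults to 1 ("flanking genes on the same
scaffold"); `flank_k=2` implements the stricter two-neighbors-per-side
reading, and the two conventions coexist because the source analyses state
both.  Presence is any annotated locus (partial genes count as present).  A
gene is a *fixed* presence/absence difference when it is absent from every
sample of one group, reliably called in at least one of them, and present in
every sample of the other group; requiring flanking support in every sample
would erase fixed calls under realistic fragmentation (the chance that all
8 carriers keep both flanks on one scaffold is ~0.17) even when the deletion
is demonstrated beyond doubt.  Deletion frequency is bounded from below by
the one-sided Clopper–Pearson limit, beta.ppf(1−conf, k, n−k+1), i.e.
(1−conf)^(1/n) when all n sampled haplotypes carry it; for n = 18 at 95 %
this is 0.847.

## 4. qPCR copy number

The generator draws per-gene baselines (Ct 20–24), a per-sample offset
(N(0, 0.5) cycles, modelling DNA input differences — exactly what
housekeeping normalization removes), and per-replicate noise
(N(0, `ct_noise_sd`), default 0.2 cycles); a heterozygous deletion carrier
has copy number ½ at deleted targets, i.e. +1 cycle.  Three technical
replicates per sample × gene.

Replicate QC excludes any replicate reading more than 0.5 cycles *above*
its replicate-group mean (single pass against the unfiltered mean; the rule
is one-sided because the artifact it guards against — short pipetting —
delays amplification); measurements with fewer than two surviving
replicates are dropped, and all exclusions are logged.  Quantification:
ΔCt = mean target Ct − arithmetic mean of the housekeeping genes' mean Cts
(equal to geometric-mean normalization on the linear scale), quantity
= 2^−ΔCt, then divided by the calibrator group's mean quantity per target.
The result is invariant to adding any constant to all Cts of a sample.

## 5. Enrichment and structure

Family enrichment is a Pearson chi-square (df = 1) on
[[family & changed, family & not], [others & changed, others & not]], by
default without Yates correction (a flag enables it; conclusions at the
packaged examples hold either way).  The gene universe is an explicit input
because family size can differ between haplotypes after a deletion.  Zero
margins leave the test undefined rather than raising.

The packaged receptor architecture is a 390-residue 7-TM topology
(intracellular N terminus, TM1–TM7 with alternating loops) with IC3 fixed
at 24 residues and TM3 at 25 — the two domains whose dimensions the
clustering analysis depends on — and the remaining 13 segments tiling the
rest as evenly as possible; the even split is a convention, not biology.
Clustering per segment is the exact binomial upper tail
P(X ≥ x | n, m/L), BH-corrected across the segments tested in one call (the
FDR family is whatever set of segments a run tests).  Sites supported by
two branches count once for clustering; multiplicity is kept as annotation.
Hydropathy profiles use the Kyte–Doolittle index with per-position median
by default (mean available — both conventions are in circulation); gaps are
ignored per position and all-gap columns flagged undefined.  A substitution
is conservative iff PAM250(a, b) > 0 (identity included); the matrix is
standard, the >0 cutoff is this package's operationalization.

## 6. Pipeline and determinism

All randomness flows from `SimulatorConfig.seed` through named
SeedSequence substreams per stage, so stages are independently
reproducible and identical configs give byte-identical outputs (hashed in
each run's manifest).  Outputs are TSV/JSON, UTF-8, 1-based inclusive
coordinates, deterministic row order; every row carries its gene/sample
identifiers.  Stage logs count masked codons, ambiguous columns, excluded
replicates and edge-unsupported calls — the audit trail for every filtering
rule.  The acceptance script runs 12 derived seeds per scenario, a size
chosen so the Monte-Carlo error of the seed-mean is a few percent of each
reported quantity while the whole script stays under two minutes.

## 7. What the synthetic data do not show

The generator omits indels and alignment error (inputs are consumed as
codon-aligned, with uncertainty handled upstream by masking), recombination
(the region is non-recombining by premise), codon-usage and CpG effects,
rate variation across sites and genes beyond the branch-level ω, selection
on synonymous sites, and read-level sequencing artifacts (assembly
fragmentation is modelled only as Poisson scaffold breaks).  Passing
recovery tests therefore demonstrates the correctness of the counting,
assignment, calling and normalization machinery under the stated model —
not robustness to misalignment, annotation error or demography in real
genomes.  The pre-split ω is reported for an unpolarized lineage; with a
single outgroup, asymmetry between the internal and outgroup branches is
undetectable by construction.
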