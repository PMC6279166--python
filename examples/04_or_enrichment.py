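"""Are odorant receptors enriched for nonsynonymous change?

Builds the 2x2 tables from per-gene flags — 9 of 23 receptor-family genes vs
24 of 308 other genes with fixed nonsynonymous substitutions on one
haplotype, 12/21 vs 76/310 on the other — and runs the chi-square test.
"""

from supergene import ContingencyTable2x2, chisq_enrichment

tables = {
    "haplotype A (SB-like)": ContingencyTable2x2(9, 14, 24, 284),
    "haplotype B (Sb-like)": ContingencyTable2x2(12, 9, 76, 234),
}
for name, table in tables.items():
    res = chisq_enrichment(table, continuity=False)
    frac_or = table.a / (table.a + table.b)
    frac_all = (table.a + table.c) / table.total
    print(
        f"{name}: {frac_or:.0%} of receptor genes vs {frac_all:.0%} of all genes "
        f"changed; chi2 = {res.statistic:.1f}, P = {res.pvalue:.2g}"
    )
print("\nBoth tests reject independence: the receptor cluster accumulates")
print("amino-acid-changing substitutions faster than the rest of the region.")
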