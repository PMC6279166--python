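"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive expected values through different mechanisms
than the package (fresh enumeration, textbook formulas, exact fractions)
so that agreement is meaningful.
"""

from fractions import Fraction
from itertools import permutations
from math import comb

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_fractions(codon: str) -> tuple[Fraction, Fraction]:
    """(syn_sites, nonsyn_sites) by enumerating all 9 single-nt neighbors."""
    syn = Fraction(0)
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOPS and aa_of(alt) == aa_of(codon):
                syn += Fraction(1, 3)
    return syn, 3 - syn


def oracle_pathway_counts(c1: str, c2: str) -> tuple[Fraction, Fraction, bool]:
    """(syn, nonsyn, all_blocked) averaged over step orderings, exact fractions."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return Fraction(0), Fraction(0), False
    open_paths, all_paths = [], []
    for order in permutations(diffs):
        cur, syn, nonsyn, blocked = c1, Fraction(0), Fraction(0), False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS or cur in STOPS:
                blocked = blocked or nxt in STOPS
                nonsyn += 1  # stop-crossing steps count nonsynonymous
            elif aa_of(nxt) == aa_of(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not blocked:
            open_paths.append((syn, nonsyn))
    pool = open_paths or all_paths
    n = len(pool)
    return (
        sum(p[0] for p in pool) / n,
        sum(p[1] for p in pool) / n,
        not open_paths,
    )


def oracle_fisher_two_sided(table) -> float:
    """Exact two-sided Fisher p by full enumeration with rational hypergeometrics."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x: int) -> Fraction:
        y = c1 - x
        if y < 0 or y > r2 or x > r1:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, y), comb(n, c1))

    observed = pmf(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = pmf(x)
        if p <= observed * (1 + Fraction(1, 10**9)):
            total += p
    return float(min(total, 1))


def oracle_chi2_statistic(table) -> float:
    """Textbook Pearson statistic sum((O-E)^2/E) without correction."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    stat = 0.0
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            e = r * c / n
            stat += (table[i][j] - e) ** 2 / e
    return stat


def oracle_binom_upper_tail(x: int, n: int, p: Fraction) -> float:
    """P(X >= x) for X ~ Binomial(n, p), exact rational tail sum."""
    q = 1 - p
    total = sum(comb(n, k) * p**k * q ** (n - k) for k in range(x, n + 1))
    return float(total)


def oracle_bh_qvalues(pvals):
    """Benjamini-Hochberg step-up, written independently of statsmodels."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
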