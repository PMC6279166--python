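"""Parsimony branch assignment, pooled dN/dS, Fisher contrast, ranking, flags."""

import numpy as np
import pytest

from supergene.codons import DiffCounts, SiteCounts
from supergene.dnds import (
    BRANCHES,
    CodonTrioAlignment,
    GeneBranchStats,
    assign_branch_substitutions,
    branch_contrast_fisher,
    classify_genes_ns,
    gene_branch_counts,
    pooled_dnds,
    rank_by_dn,
)

from .oracles import oracle_fisher_two_sided


def totals(assignment):
    avg = assignment.averaged()
    return {b: (avg[b].syn, avg[b].nonsyn) for b in BRANCHES}


class TestBranchAssignment:
    def test_identical_column_has_no_events(self):
        assert totals(assign_branch_substitutions("AAA", "AAA", "AAA")) == {
            "A": (0.0, 0.0),
            "B": (0.0, 0.0),
            "presplit": (0.0, 0.0),
        }

    def test_private_change_goes_to_its_terminal_branch(self):
        t = totals(assign_branch_substitutions("AAA", "AAG", "AAA"))
        assert t["B"] == (1.0, 0.0)  # Lys->Lys synonymous
        assert t["A"] == (0.0, 0.0) and t["presplit"] == (0.0, 0.0)

    def test_shared_derived_state_goes_to_presplit(self):
        t = totals(assign_branch_substitutions("AAG", "AAG", "AAA"))
        assert t["presplit"] == (1.0, 0.0)
        assert t["A"] == (0.0, 0.0) and t["B"] == (0.0, 0.0)

    def test_changes_at_different_positions_resolve_unambiguously(self):
        # outgroup differs at pos3 (presplit), B differs at pos1 (terminal):
        # the internal state is fixed by positionwise majority
        assignment = assign_branch_substitutions("AAG", "GAG", "AAA")
        assert sum(assignment.minimal) == 1
        t = totals(assignment)
        assert t["presplit"][0] + t["presplit"][1] == pytest.approx(1.0)
        assert t["B"][0] + t["B"][1] == pytest.approx(1.0)
        assert t["A"] == (0.0, 0.0)

    def test_three_states_at_one_position_is_ambiguous_threeway_tie(self):
        assignment = assign_branch_substitutions("CAA", "GAA", "AAA")
        assert assignment.ambiguous
        assert sum(assignment.minimal) == 3
        t = totals(assignment)
        total_events = sum(s + n for s, n in t.values())
        assert total_events == pytest.approx(2.0)

    def test_branch_conservation_single_event_columns(self):
        # with <=1 event per column, per-branch totals equal the pairwise
        # pathway counts implied by the three pairwise comparisons
        from supergene.codons import pathway_diff_counts

        for ca, cb, cout in [("AAA", "AAG", "AAA"), ("AAG", "AAG", "AAA"), ("TTT", "TTT", "TTC")]:
            t = totals(assign_branch_substitutions(ca, cb, cout))
            assert sum(s + n for s, n in t.values()) == pytest.approx(
                max(
                    pathway_diff_counts(ca, cb).total,
                    pathway_diff_counts(ca, cout).total,
                    pathway_diff_counts(cb, cout).total,
                )
            )


class TestGeneBranchCounts:
    def test_identical_trio_zero_counts_positive_denominator(self):
        trio = CodonTrioAlignment("g1", "ATGGCT", "ATGGCT", "ATGGCT")
        stats = gene_branch_counts(trio)
        assert all(stats.diffs[b].total == 0 for b in BRANCHES)
        assert stats.sites.total == pytest.approx(6.0)
        assert stats.n_columns == 2

    def test_masked_codon_removes_exactly_three_sites(self):
        full = gene_branch_counts(CodonTrioAlignment("g1", "ATGGCT", "ATGGCT", "ATGGCT"))
        masked = gene_branch_counts(CodonTrioAlignment("g1", "ATGNNN", "ATGGCT", "ATGGCT"))
        assert full.sites.total - masked.sites.total == pytest.approx(3.0)
        assert masked.n_masked_codons == 1

    def test_all_masked_flags_zero_denominator(self):
        stats = gene_branch_counts(CodonTrioAlignment("g1", "NNN", "NNN", "NNN"))
        assert stats.all_masked
        assert stats.sites.total == 0.0

    def test_gap_masking_is_per_codon(self):
        stats = gene_branch_counts(CodonTrioAlignment("g1", "A-GGCT", "ATGGCT", "ATGGCT"))
        assert stats.n_masked_codons == 1
        assert stats.n_columns == 1

    def test_rejects_inframe_stop_and_bad_lengths(self):
        with pytest.raises(ValueError):
            CodonTrioAlignment("g1", "TAAGCT", "ATGGCT", "ATGGCT")
        with pytest.raises(ValueError):
            CodonTrioAlignment("g1", "ATGG", "ATGG", "ATGG")
        with pytest.raises(ValueError):
            CodonTrioAlignment("g1", "ATG", "ATGGCT", "ATGGCT")


def _stats(gene_id, branch_counts, syn_sites, nonsyn_sites):
    diffs = {b: DiffCounts() for b in BRANCHES}
    for b, (s, n) in branch_counts.items():
        diffs[b] = DiffCounts(s, n)
    return GeneBranchStats(
        gene_id=gene_id,
        diffs=diffs,
        sites=SiteCounts(syn_sites, nonsyn_sites),
        n_columns=1,
    )


class TestPooled:
    def test_ratio_of_sums_not_mean_of_ratios(self):
        # two genes each with 1 syn over 100 syn sites and 1 nonsyn over 300
        # nonsyn sites: pooled ratio = (2/600)/(2/200) = 1/3
        stats = [
            _stats("g1", {"A": (1.0, 1.0)}, 100, 300),
            _stats("g2", {"A": (1.0, 1.0)}, 100, 300),
        ]
        pooled = pooled_dnds(stats, "A")
        assert pooled.ratio == pytest.approx(1 / 3)

    def test_zero_synonymous_is_flagged_undefined(self):
        stats = [_stats("g1", {"A": (0.0, 2.0)}, 100, 300)]
        pooled = pooled_dnds(stats, "A")
        assert not pooled.defined and pooled.ratio is None

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pooled_dnds([], "A")

    def test_jc_correction_is_negligible_at_small_divergence(self):
        stats = [_stats("g1", {"A": (1.0, 1.0)}, 1000, 3000)]
        raw = pooled_dnds(stats, "A", correction="none")
        jc = pooled_dnds(stats, "A", correction="jc")
        assert jc.ratio == pytest.approx(raw.ratio, rel=1e-3)
        assert jc.ratio != raw.ratio  # but not identical


class TestFisherContrast:
    def test_no_association_gives_p_one(self):
        stats = [_stats("g1", {"A": (5.0, 5.0), "B": (5.0, 5.0)}, 100, 300)]
        assert branch_contrast_fisher(stats, "A", "B") == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        stats = [_stats("g1", {"A": (2.0, 10.0), "B": (15.0, 3.0)}, 100, 300)]
        p = branch_contrast_fisher(stats, "A", "B")
        assert p == pytest.approx(oracle_fisher_two_sided([[10, 2], [3, 15]]), rel=1e-9)

    def test_empty_row_rejected(self):
        stats = [_stats("g1", {"A": (0.0, 0.0), "B": (1.0, 1.0)}, 100, 300)]
        with pytest.raises(ValueError):
            branch_contrast_fisher(stats, "A", "B")


class TestRankingAndFlags:
    def test_all_zero_genes_rank_lexically(self):
        stats = [_stats(g, {}, 10, 30) for g in ("gb", "ga", "gc")]
        assert rank_by_dn(stats, "A") == ["ga", "gb", "gc"]

    def test_high_dn_gene_ranks_first_and_order_is_input_invariant(self):
        stats = [
            _stats("g1", {"B": (0.0, 1.0)}, 10, 30),
            _stats("g2", {"B": (0.0, 5.0)}, 10, 30),
            _stats("g3", {"B": (0.0, 2.0)}, 10, 30),
        ]
        expected = ["g2", "g3", "g1"]
        assert rank_by_dn(stats, "B") == expected
        assert rank_by_dn(stats[::-1], "B") == expected

    def test_flags_round_half_up(self):
        stats = [
            _stats("g1", {"A": (0.0, 0.5)}, 10, 30),  # ambiguity fraction rounds up
            _stats("g2", {"A": (0.0, 0.4)}, 10, 30),
            _stats("g3", {"A": (0.0, 1.0), "B": (0.0, 1.0)}, 10, 30),
        ]
        flags = classify_genes_ns(stats)
        assert bool(flags.loc["g1", "A"]) is True
        assert bool(flags.loc["g2", "A"]) is False
        assert bool(flags.loc["g3", "both"]) is True
        assert bool(flags.loc["g1", "both"]) is False
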