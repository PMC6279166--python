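"""Synthetic-data generator: determinism, truth-log exactness, recovery."""

import dataclasses

import numpy as np
import pytest

from supergene.codons import GENETIC_CODE, STOP_CODONS, SENSE_CODONS, synonymous_site_fractions
from supergene.dnds import dataset_branch_counts, gene_branch_counts
from supergene.simulate import (
    DeletionPlan,
    SimulatorConfig,
    calibrate_presplit_length,
    simulate_cluster_assemblies,
    simulate_ct_panel,
    simulate_site_annotations,
    simulate_trio_alignments,
)


class TestConfigValidation:
    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            SimulatorConfig(gene_length=0)
        with pytest.raises(ValueError):
            SimulatorConfig(omega_a=0.0)
        with pytest.raises(ValueError):
            SimulatorConfig(t_a=-0.1)
        with pytest.raises(ValueError):
            SimulatorConfig(deletion_plan=(DeletionPlan(0, 2, "B", 1.5),))
        with pytest.raises(ValueError):
            SimulatorConfig(deletion_plan=(DeletionPlan(22, 2, "B", 1.0),))


class TestTrioSimulation:
    def test_zero_branch_lengths_reproduce_the_ancestor(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, t_presplit=0.0, t_a=0.0, t_b=0.0)
        trios, truth = simulate_trio_alignments(cfg)
        for trio in trios:
            assert trio.seq_a == trio.seq_b == trio.seq_out
        for counts in truth.trio_counts.values():
            assert all(v == 0 for branch in counts.values() for v in branch.values())

    def test_forbidden_class_never_occurs(self, tiny_config):
        # omega ~ 0 on branch B: no nonsynonymous events recorded there
        cfg = dataclasses.replace(tiny_config, omega_b=1e-12, t_b=0.02)
        _, truth = simulate_trio_alignments(cfg)
        assert truth.branch_totals("B")["nonsyn"] == 0
        assert truth.branch_totals("B")["syn"] > 0

    def test_seed_determinism_bitwise(self, tiny_config):
        t1, truth1 = simulate_trio_alignments(tiny_config)
        t2, truth2 = simulate_trio_alignments(tiny_config)
        assert [(x.seq_a, x.seq_b, x.seq_out) for x in t1] == [
            (x.seq_a, x.seq_b, x.seq_out) for x in t2
        ]
        assert truth1.trio_counts == truth2.trio_counts
        t3, _ = simulate_trio_alignments(dataclasses.replace(tiny_config, seed=43))
        assert [x.seq_a for x in t1] != [x.seq_a for x in t3]

    def test_no_inframe_stop_codons_ever(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, t_presplit=0.3)
        trios, _ = simulate_trio_alignments(cfg)
        for trio in trios:
            for seq in (trio.seq_a, trio.seq_b, trio.seq_out):
                codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
                assert not codons & STOP_CODONS

    def test_truthlog_matches_parsimony_counts_at_tiny_divergence(self):
        # with <=1 event per column parsimony assignment is exact
        cfg = SimulatorConfig(
            n_genes=20, gene_length=150, t_presplit=0.002, t_a=0.002, t_b=0.002, seed=3
        )
        trios, truth = simulate_trio_alignments(cfg)
        stats = {s.gene_id: s for s in (gene_branch_counts(t) for t in trios)}
        for gid, counts in truth.trio_counts.items():
            for b in ("A", "B", "presplit"):
                realized = counts[b]["syn"] + counts[b]["nonsyn"]
                assigned = stats[gid].diffs[b].total
                assert assigned == pytest.approx(realized, abs=1.01)

    def test_generating_flux_ratio_matches_omega(self):
        # realized nonsyn/syn event ratio over opportunity recovers omega
        # (>= 1e5 codon-branch draws pooled across branches with equal omega)
        omega = 0.25
        cfg = SimulatorConfig(
            n_genes=40,
            gene_length=300,
            t_presplit=0.05,
            t_a=0.05,
            t_b=0.05,
            omega_presplit=omega,
            omega_a=omega,
            omega_b=omega,
            seed=5,
        )
        _, truth = simulate_trio_alignments(cfg)
        syn = nonsyn = 0
        for b in ("A", "B", "presplit"):
            tot = truth.branch_totals(b)
            syn, nonsyn = syn + tot["syn"], nonsyn + tot["nonsyn"]
        s_u = np.mean([synonymous_site_fractions(c).syn for c in SENSE_CODONS])
        n_u = 3.0 - s_u
        omega_hat = (nonsyn / n_u) / (syn / s_u)
        se = omega_hat * np.sqrt(1 / syn + 1 / nonsyn)
        assert abs(omega_hat - omega) < 3 * se

    def test_presplit_calibration_hits_target_protein_identity(self):
        cfg = SimulatorConfig(n_genes=40, gene_length=390, seed=9)
        trios, _ = simulate_trio_alignments(cfg)
        idents = []
        for t in trios:
            aa_a = [GENETIC_CODE[t.seq_a[i : i + 3]] for i in range(0, len(t.seq_a), 3)]
            aa_o = [GENETIC_CODE[t.seq_out[i : i + 3]] for i in range(0, len(t.seq_out), 3)]
            idents.append(np.mean([x == y for x, y in zip(aa_a, aa_o)]))
        assert np.mean(idents) == pytest.approx(0.89, abs=0.01)
        assert calibrate_presplit_length(1.0, 0.1) == 0.0


class TestClusterSimulation:
    def test_no_fragmentation_no_deletion_is_identity(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, mean_scaffold_genes=None, deletion_plan=())
        reference, samples, _ = simulate_cluster_assemblies(cfg)
        ref_order = list(reference["gene_id"])
        for _, sub in samples.groupby("sample_id"):
            assert list(sub.sort_values("start")["gene_id"]) == ref_order
            assert sub["scaffold"].nunique() == 1

    def test_planted_deletion_removes_genes_only_in_carriers(self, tiny_config):
        _, samples, truth = simulate_cluster_assemblies(tiny_config)
        deleted = set(truth.deletions[0]["genes"])
        carriers = set(truth.deletions[0]["carriers"])
        assert carriers == {f"B{i+1}" for i in range(tiny_config.n_samples_b)}
        for sample_id, sub in samples.groupby("sample_id"):
            genes = set(sub["gene_id"])
            if sample_id in carriers:
                assert not genes & deleted
            else:
                assert deleted <= genes

    def test_half_carrier_fraction_yields_partial_carriers(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config,
            n_samples_b=40,
            deletion_plan=(DeletionPlan(4, 2, "B", 0.5),),
        )
        _, _, truth = simulate_cluster_assemblies(cfg)
        k = len(truth.deletions[0]["carriers"])
        assert 10 <= k <= 30  # ~Binomial(40, .5), 3+ sd margin


class TestCtSimulation:
    def test_noiseless_unit_ratio_panel_normalizes_to_one(self, tiny_config):
        from supergene.qpcr import relative_copy_number

        cfg = dataclasses.replace(tiny_config, ct_noise_sd=0.0, deletion_plan=())
        panel, truth = simulate_ct_panel(cfg)
        assert all(r == 1.0 for g in truth.copy_ratios.values() for r in g.values())
        rel = relative_copy_number(panel, calibrator_group="AA")
        assert np.allclose(rel["relative_quantity"], 1.0)

    def test_noiseless_half_copy_shifts_delta_ct_by_one_cycle(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, ct_noise_sd=0.0)
        panel, truth = simulate_ct_panel(cfg)
        deleted = [g for g, r in truth.copy_ratios["AB"].items() if r == 0.5]
        assert deleted
        for gene in deleted:
            ab = panel[(panel["group"] == "AB") & (panel["gene_id"] == gene)]
            aa = panel[(panel["group"] == "AA") & (panel["gene_id"] == gene)]
            # remove per-sample offsets via the housekeeping genes
            def normed(rows):
                out = []
                for sample_id, sub in rows.groupby("sample_id"):
                    hkg = panel[(panel["sample_id"] == sample_id) & (panel["role"] == "housekeeping")]
                    out.append(sub["ct"].mean() - hkg["ct"].mean())
                return np.mean(out)

            assert normed(ab) - normed(aa) == pytest.approx(1.0, abs=1e-9)


class TestSiteSimulation:
    def test_uniform_counts_follow_segment_lengths(self, tiny_config):
        from supergene.structure import map_sites

        sites, arch, _ = simulate_site_annotations(tiny_config, n_sites=300)
        counts = map_sites(sites, arch)
        for _, row in counts.iterrows():
            expected = 300 * row["segment_length"] / arch.length
            sd = np.sqrt(expected * (1 - row["segment_length"] / arch.length))
            assert abs(row["observed"] - expected) <= 4 * sd + 2

    def test_empty_site_set_gives_all_p_one(self, tiny_config):
        from supergene.structure import domain_binomial_tests, map_sites

        sites, arch, _ = simulate_site_annotations(tiny_config, n_sites=0)
        assert len(sites) == 0
        tests = domain_binomial_tests(map_sites(sites, arch), arch)
        assert (tests["p"] == 1.0).all()

    def test_enriched_segment_is_detected_in_most_seeds(self):
        from supergene.structure import domain_binomial_tests, map_sites

        hits = 0
        for seed in range(10):
            cfg = SimulatorConfig(seed=seed)
            sites, arch, _ = simulate_site_annotations(
                cfg, n_sites=33, enriched_segment="IC3", enrichment_factor=10.0
            )
            tests = domain_binomial_tests(map_sites(sites, arch), arch)
            q = tests.loc[tests["label"] == "IC3", "q"].iloc[0]
            hits += q < 0.05
        assert hits >= 7
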