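"""Synthetic hybrid generator: determinism, planted truth, coverage model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hybridm6a import io as io_mod
from hybridm6a import motif, peakcall, simdata
from hybridm6a.simdata import (
    BACKGROUNDS,
    SampleKey,
    SimulationConfig,
    generate_genome_pair,
    simulate_experiment,
)


def small_config(**kw):
    base = dict(seed=5, n_genes=6, replicates=2, ko_included=False)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_mixture={"invariable": 0.7})

    def test_substitution_rate_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(substitution_rate=1.5)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_mixture={"banana": 1.0})


class TestGenomePair:
    def test_zero_rate_all_invariable_gives_identical_alleles(self):
        cfg = small_config(substitution_rate=0.0,
                           class_mixture={"invariable": 1.0})
        genomes, _ = generate_genome_pair(cfg)
        assert genomes.variants.empty
        assert genomes.sequences_a == genomes.sequences_b

    def test_fixed_seed_reproduces_fasta_bytes(self, tmp_path):
        cfg = small_config()
        for run in ("x", "y"):
            genomes, _ = generate_genome_pair(cfg)
            io_mod.write_fasta(genomes.sequences_a, tmp_path / f"{run}.fa")
        assert (tmp_path / "x.fa").read_bytes() == (tmp_path / "y.fa").read_bytes()

    def test_variants_consistent_with_sequences(self):
        genomes, _ = generate_genome_pair(small_config())
        for gene in genomes.sequences_a:
            sa, sb = genomes.sequences_a[gene], genomes.sequences_b[gene]
            diff = {(gene, i) for i, (x, y) in enumerate(zip(sa, sb)) if x != y}
            table = {(r.gene, r.position) for r in genomes.variants.itertuples()
                     if r.gene == gene}
            assert diff == table

    def test_variant_count_matches_binomial_oracle(self):
        # no planted sites, so no positions are protected from substitution
        n_seeds, length, rate = 100, 1000, 0.05
        counts = []
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                seed=seed, n_genes=1, gene_length_range=(length, length),
                substitution_rate=rate, sites_per_gene=0.0,
                class_mixture={"invariable": 1.0})
            genomes, _ = generate_genome_pair(cfg)
            counts.append(len(genomes.variants))
        mean_sd = np.sqrt(length * rate * (1 - rate)) / np.sqrt(n_seeds)
        assert abs(np.mean(counts) - length * rate) < 3 * mean_sd

    def test_planted_motifs_present_in_both_alleles(self):
        genomes, truth = generate_genome_pair(small_config(seed=8))
        for _, t in truth.iterrows():
            sa = genomes.sequences_a[t.gene]
            assert motif.is_motif_at(sa, int(t.a_position), "DRAC")
            if t.true_class != "DM-cis-motif":
                sb = genomes.sequences_b[t.gene]
                assert motif.is_motif_at(sb, int(t.a_position_b), "DRAC")

    def test_dm_cis_motif_sites_fail_intactness_in_exactly_one_allele(self):
        cfg = small_config(seed=9, n_genes=20,
                           class_mixture={"DM-cis-motif": 1.0})
        genomes, truth = generate_genome_pair(cfg)
        assert len(truth) > 5
        for _, t in truth.iterrows():
            a = int(t.a_position)
            ctx_a = motif.extract_context(genomes.sequences_a[t.gene], a)
            ctx_b = motif.extract_context(genomes.sequences_b[t.gene], a)
            if t.low_allele == "b":
                flag, _ = motif.is_motif_disrupting(ctx_a, ctx_b, "yeast")
            else:
                flag, _ = motif.is_motif_disrupting(ctx_b, ctx_a, "yeast")
            assert flag

    def test_structure_sites_have_intact_motifs_and_planted_stem(self):
        cfg = small_config(seed=10, n_genes=20,
                           class_mixture={"DM-cis-structure": 1.0})
        genomes, truth = generate_genome_pair(cfg)
        comp = dict(zip("ACGU", "UGCA"))
        for _, t in truth.iterrows():
            a = int(t.a_position)
            low = (genomes.sequences_a if t.low_allele == "a"
                   else genomes.sequences_b)[t.gene]
            assert motif.is_motif_at(low, a, "DRAC")
            arm = low[a + 12:a + 23]
            target = low[a - 5:a + 6]
            assert arm == "".join(comp[c] for c in reversed(target))

    def test_gene_models_are_nested(self):
        genomes, _ = generate_genome_pair(small_config())
        for r in genomes.gene_models.itertuples():
            assert 0 < r.utr5_end < r.cds_end < r.length


class TestSimulateExperiment:
    def test_fragment_coverage_identity(self, small_experiment):
        exp = small_experiment
        for key in list(exp.coverage)[:6]:
            for gene, cov in exp.coverage[key].items():
                recomputed = peakcall.fragment_coverage(
                    exp.fragments[key][gene], len(cov))
                assert np.array_equal(cov, recomputed)

    def test_determinism_bit_identical_coverage(self):
        cfg = small_config(n_genes=3)
        g, t = generate_genome_pair(cfg)
        e1 = simulate_experiment(g, t, cfg)
        e2 = simulate_experiment(g, t, cfg)
        for key in e1.coverage:
            for gene in e1.coverage[key]:
                assert np.array_equal(e1.coverage[key][gene],
                                      e2.coverage[key][gene])

    def test_adding_genes_does_not_shift_existing_draws(self):
        cfg_small = small_config(n_genes=3)
        cfg_big = dataclasses.replace(cfg_small, n_genes=5)
        g1, t1 = generate_genome_pair(cfg_small)
        g2, t2 = generate_genome_pair(cfg_big)
        for gene in g1.sequences_a:
            assert g1.sequences_a[gene] == g2.sequences_a[gene]

    def test_null_methylation_mean_ratio_near_one(self):
        cfg = small_config(mu_high=0.0, class_mixture={"invariable": 1.0},
                           replicates=3)
        exp = simdata.simulate(cfg)
        ratios = []
        for rep in range(cfg.replicates):
            for gene in exp.genomes.sequences_a:
                ip = exp.coverage[SampleKey("parent_a", "wt", "ip", rep)][gene]
                inp = exp.coverage[SampleKey("parent_a", "wt", "input", rep)][gene]
                ratios.append(ip.mean() / inp.mean())
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_summit_ratio_matches_enrichment_monte_carlo(self):
        # mu = 1, 8x maximum enrichment: mean summit IP/input across many
        # simulations approaches 8
        ratios = []
        for seed in range(60):
            cfg = SimulationConfig(
                seed=seed, n_genes=1, gene_length_range=(1500, 1500),
                sites_per_gene=1.0, mu_high=1.0, replicates=1,
                ko_included=False, class_mixture={"invariable": 1.0})
            exp = simdata.simulate(cfg)
            if exp.truth.empty:
                continue
            gene = exp.truth.iloc[0].gene
            a = int(exp.truth.iloc[0].a_position)
            ip = exp.coverage[SampleKey("hybrid_a", "wt", "ip", 0)][gene]
            inp = exp.coverage[SampleKey("hybrid_a", "wt", "input", 0)][gene]
            lo, hi = max(0, a - 5), a + 6
            ratios.append(ip[lo:hi].mean() / max(inp[lo:hi].mean(), 1e-9))
        assert len(ratios) > 20
        assert abs(np.mean(ratios) - 8.0) < 1.6  # +-20%

    def test_all_invariable_truth_centers_hybrid_delta_at_zero(self):
        deltas = []
        for seed in (21, 22, 23):
            cfg = small_config(seed=seed, n_genes=80, replicates=3,
                               class_mixture={"invariable": 1.0})
            exp = simdata.simulate(cfg)
            for _, t in exp.truth.iterrows():
                vals = {}
                for bg in ("hybrid_a", "hybrid_b"):
                    per_rep = []
                    for rep in range(cfg.replicates):
                        ip = exp.coverage[SampleKey(bg, "wt", "ip", rep)][t.gene]
                        inp = exp.coverage[SampleKey(bg, "wt", "input", rep)][t.gene]
                        s = peakcall.score1(ip, inp, int(t.a_position), 81)
                        per_rep.append(s)
                    vals[bg] = np.mean(per_rep)
                deltas.append(np.log2(vals["hybrid_a"] / vals["hybrid_b"]))
        assert len(deltas) > 100
        assert abs(np.mean(deltas)) < 0.1

    def test_ko_samples_have_no_enrichment(self):
        cfg = small_config(ko_included=True, replicates=2, seed=6)
        exp = simdata.simulate(cfg)
        for _, t in exp.truth.iterrows():
            if t.mu_parent_a == 0:
                continue
            a = int(t.a_position)
            ip = exp.coverage[SampleKey("parent_a", "ko", "ip", 0)][t.gene]
            inp = exp.coverage[SampleKey("parent_a", "ko", "input", 0)][t.gene]
            s = peakcall.score1(ip, inp, a, 81)
            assert s < 2.0


class TestExperimentIO:
    def test_bedgraph_round_trip_exact(self, tmp_path, small_experiment):
        exp = small_experiment
        key = exp.sample_keys()[0]
        path = tmp_path / "t.bedGraph"
        io_mod.write_bedgraph(exp.coverage[key], str(path))
        lengths = {g: len(v) for g, v in exp.coverage[key].items()}
        back = io_mod.read_bedgraph(str(path), lengths)
        for gene in lengths:
            assert np.array_equal(back[gene], exp.coverage[key][gene])

    def test_fragment_bed_round_trip(self, tmp_path, small_experiment):
        exp = small_experiment
        key = exp.sample_keys()[0]
        path = tmp_path / "t.bed"
        io_mod.write_fragments_bed(exp.fragments[key], str(path))
        back = io_mod.read_fragments_bed(str(path))
        for gene, frags in exp.fragments[key].items():
            if len(frags):
                assert np.array_equal(np.asarray(back[gene]), np.asarray(frags))

    def test_write_experiment_emits_expected_files(self, tmp_path):
        cfg = small_config(n_genes=2, replicates=1)
        exp = simdata.simulate(cfg)
        io_mod.write_experiment(exp, str(tmp_path))
        names = {p.name for p in tmp_path.iterdir()}
        assert {"genomeA.fa", "genomeB.fa", "genes.tsv", "variants.tsv",
                "truth.tsv"} <= names
        assert "parent_a_wt_ip_rep1.bedGraph" in names
        assert "hybrid_b_wt_input_rep1.bed" in names
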