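import dataclasses

import numpy as np
import pytest

from epistate.chip_enrichment import log2_enrichment
from epistate.genome_io import GenomicInterval
from epistate.synthetic_data import (
    PlantedTruth,
    SimulationConfig,
    child_rng,
    simulate_chip_counts,
    simulate_expression,
    simulate_genome,
    simulate_methylation,
    simulate_repeats,
    simulate_sequences,
)


@pytest.fixture(scope="module")
def small_cfg():
    return SimulationConfig(seed=42, n_genes=200, n_enhancers=60,
                            n_repeat_subfamilies=5, loci_per_subfamily=30)


@pytest.fixture(scope="module")
def genome(small_cfg):
    return simulate_genome(small_cfg)


class TestSimulateGenome:
    def test_gene_count_and_bounds(self, small_cfg, genome):
        ann, _ = genome
        assert len(ann.genes) == small_cfg.n_genes
        for g in ann.genes:
            assert 0 <= g.interval.start < g.interval.end
            assert g.interval.end <= ann.chrom_sizes[g.chrom]

    def test_genes_non_overlapping_within_chromosome(self, genome):
        ann, _ = genome
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda v: v.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_determinism(self, small_cfg):
        ann1, t1 = simulate_genome(small_cfg)
        ann2, t2 = simulate_genome(small_cfg)
        assert [(g.gene_id, g.interval.start) for g in ann1.genes] == \
               [(g.gene_id, g.interval.start) for g in ann2.genes]
        assert t1.gene_marks == t2.gene_marks
        assert t1.de_genes == t2.de_genes

    def test_no_marks_when_fraction_zero(self):
        cfg = SimulationConfig(seed=1, n_genes=100, frac_marked_k9=0.0,
                               frac_marked_k27=0.0, de_from_marked_frac=0.0)
        _, truth = simulate_genome(cfg)
        assert all(m is None for m in truth.gene_marks.values())

    def test_marks_mutually_exclusive_and_fractions(self, small_cfg, genome):
        _, truth = genome
        k9 = sum(1 for m in truth.gene_marks.values() if m == "K9")
        k27 = sum(1 for m in truth.gene_marks.values() if m == "K27")
        assert k9 == round(small_cfg.frac_marked_k9 * small_cfg.n_genes)
        assert k27 == round(small_cfg.frac_marked_k27 * small_cfg.n_genes)

    def test_some_genes_on_chrx(self, genome):
        ann, _ = genome
        frac = np.mean([g.chrom == "chrX" for g in ann.genes])
        assert 0.02 <= frac <= 0.10

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, frac_marked_k9=0.7, frac_marked_k27=0.7)


class TestSimulateChip:
    def _regions(self, n, length=1000):
        return [GenomicInterval("chr1", i * length, (i + 1) * length, ".",
                                f"r{i}") for i in range(n)]

    def test_null_enrichment_near_zero(self):
        cfg = SimulationConfig(seed=2, mean_depth_per_region=100.0)
        table = simulate_chip_counts(self._regions(1500), set(), cfg)
        track = log2_enrichment(table)
        assert abs(track.values.mean()) < 0.05

    def test_planted_log2fc_recovered(self):
        cfg = SimulationConfig(seed=3, mean_depth_per_region=100.0,
                               planted_chip_log2fc=2.0)
        marked = {f"r{i}" for i in range(1000)}
        table = simulate_chip_counts(self._regions(1000), marked, cfg)
        track = log2_enrichment(table)
        assert track.values.mean() == pytest.approx(2.0, abs=0.1)

    def test_zero_depth_all_zero(self):
        cfg = SimulationConfig(seed=4, mean_depth_per_region=0.0)
        table = simulate_chip_counts(self._regions(10), set(), cfg)
        assert table.chip_counts.sum() == 0 and table.input_counts.sum() == 0
        assert table.chip_lib_totals.sum() == 0


class TestSimulateExpression:
    def test_no_de_when_fraction_zero(self):
        cfg = SimulationConfig(seed=5, n_genes=100, frac_de=0.0,
                               de_chrx_bias=0.0, de_from_marked_frac=0.0)
        ann, truth = simulate_genome(cfg)
        assert truth.de_genes == {}

    def test_poisson_limit_variance_over_mean(self):
        cfg = SimulationConfig(seed=6, n_genes=400, nb_dispersion=0.0,
                               baseline_log2_sd=0.0, lib_factor_log_sd=0.0,
                               frac_de=0.0, de_chrx_bias=0.0,
                               n_ctrl_embryos=10, n_ko_embryos=10,
                               de_from_marked_frac=0.0)
        ann, truth = simulate_genome(cfg)
        m = simulate_expression(ann, truth, cfg)
        ratio = m.counts.var(axis=1, ddof=1) / m.counts.mean(axis=1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_seed_determinism(self, small_cfg, genome):
        ann, truth = genome
        m1 = simulate_expression(ann, truth, small_cfg)
        m2 = simulate_expression(ann, truth, small_cfg)
        assert np.array_equal(m1.counts, m2.counts)


class TestSimulateRepeats:
    def test_planted_fractions_within_binomial_error(self, small_cfg, genome):
        _, truth = genome
        reg = truth.regulated_subfamilies
        for name in reg:
            loci = [l for l in truth.repeat_marked if l.startswith(name)]
            f = np.mean([truth.repeat_marked[l] for l in loci])
            # binomial 99% CI around 0.6 with n=30
            assert abs(f - 0.6) < 3 * np.sqrt(0.6 * 0.4 / len(loci))

    def test_zero_regulated_config(self):
        cfg = SimulationConfig(seed=7, n_genes=50, n_regulated_subfamilies=0,
                               n_repeat_subfamilies=3, loci_per_subfamily=20,
                               bg_frac_up=0.0, bg_frac_marked=0.0,
                               de_from_marked_frac=0.0)
        ann, truth = simulate_genome(cfg)
        assert truth.regulated_subfamilies == set()
        assert not any(truth.repeat_up.values())

    def test_seed_determinism(self, small_cfg, genome):
        ann, truth = genome
        m1, pc1 = simulate_repeats(ann, truth, small_cfg)
        m2, pc2 = simulate_repeats(ann, truth, small_cfg)
        assert np.array_equal(m1.counts, m2.counts)
        assert np.array_equal(pc1, pc2)


class TestSimulateSequences:
    def test_planted_positions_recorded_and_correct(self, small_cfg, genome):
        _, truth = genome
        seqs, truth = simulate_sequences(truth, small_cfg)
        motif = small_cfg.motif_consensus
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(motif))
        n_planted = 0
        for eid, positions in truth.motif_positions.items():
            for off in positions:
                found = seqs[eid][off : off + len(motif)]
                assert found in (motif, rc)
                n_planted += 1
        k9 = [e for e, s in truth.enhancer_states.items() if s == "k9_gaining"]
        assert n_planted <= len(k9)
        assert n_planted > 0

    def test_base_composition_uniform(self, small_cfg, genome):
        from scipy.stats import chisquare

        _, truth = genome
        seqs, _ = simulate_sequences(truth, small_cfg)
        s = "".join(seqs.values())
        counts = [s.count(b) for b in "ACGT"]
        _, p = chisquare(counts)
        assert p > 0.001

    def test_no_motif_config(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, planted_motif_rate=0.0)
        ann, truth = simulate_genome(cfg)
        seqs, truth = simulate_sequences(truth, cfg)
        assert all(not v for v in truth.motif_positions.values())


class TestSimulateMethylation:
    def test_group_means_near_beta_expectations(self, small_cfg, genome):
        ann, truth = genome
        meth = simulate_methylation(ann, truth, small_cfg)
        k9 = np.concatenate([meth[f"{g}_promoter"]
                             for g, m in truth.gene_marks.items() if m == "K9"])
        k27 = np.concatenate([meth[f"{g}_promoter"]
                              for g, m in truth.gene_marks.items() if m == "K27"])
        assert k9.mean() == pytest.approx(0.8, abs=0.03)
        assert k27.mean() == pytest.approx(0.2, abs=0.03)

    def test_values_in_unit_interval_and_deterministic(self, small_cfg, genome):
        ann, truth = genome
        m1 = simulate_methylation(ann, truth, small_cfg)
        m2 = simulate_methylation(ann, truth, small_cfg)
        for k, v in m1.items():
            assert np.all((v >= 0) & (v <= 1))
            assert np.array_equal(v, m2[k])


def test_generated_bed_parses_through_genome_io(tmp_path, genome):
    from epistate.genome_io import read_bed, write_bed

    ann, _ = genome
    p = tmp_path / "repeats.bed"
    write_bed(ann.repeats, p)
    back = read_bed(p)
    assert len(back) == len(ann.repeats)
    assert back[0].id == ann.repeats[0].id
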