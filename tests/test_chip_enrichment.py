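from itertools import combinations

import numpy as np
import pytest

from epistate.chip_enrichment import (
    DegenerateInputError,
    EnrichmentTrack,
    RegionCountTable,
    call_marked,
    differential_enrichment,
    kmeans_1d,
    log2_enrichment,
    metagene_profile,
    scale_absolute,
    sliding_track,
    tile_summary,
)
from epistate.genome_io import GeneModel, GenomicInterval
from epistate.synthetic_data import SimulationConfig, simulate_chip_counts


def _table(chip, inp, chip_lib=1e6, input_lib=1e6, length=1000, n=None):
    n = n or len(chip)
    regions = [GenomicInterval("chr1", i * length, (i + 1) * length, ".", f"r{i}")
               for i in range(n)]
    return RegionCountTable(regions, np.asarray(chip).reshape(n, -1),
                            np.asarray(inp).reshape(n, -1),
                            np.atleast_1d(chip_lib), np.atleast_1d(input_lib))


class TestLog2Enrichment:
    def test_equal_counts_give_zero(self):
        track = log2_enrichment(_table([100], [100]))
        assert track.values[0] == pytest.approx(0.0)

    def test_pseudocounted_hand_value(self):
        track = log2_enrichment(_table([400], [100]))
        assert track.values[0] == pytest.approx(np.log2(400.5 / 100.5))

    def test_zero_chip_stays_finite(self):
        track = log2_enrichment(_table([0], [100]))
        assert track.values[0] == pytest.approx(np.log2(0.5 / 100.5))
        assert np.isfinite(track.values[0])

    def test_invariant_under_joint_library_rescaling(self, rng):
        chip = rng.poisson(100, size=(50, 2))
        inp = rng.poisson(100, size=(50, 2))
        t1 = _table(chip, inp, chip_lib=[1e6, 2e6], input_lib=[1e6, 1e6])
        t2 = _table(chip, inp, chip_lib=[3e6, 6e6], input_lib=[3e6, 3e6])
        assert log2_enrichment(t1).values == pytest.approx(
            log2_enrichment(t2).values)

    def test_monotone_in_chip_count(self):
        base = log2_enrichment(_table([100], [100])).values[0]
        more = log2_enrichment(_table([150], [100])).values[0]
        assert more > base

    def test_zero_library_total_errors(self):
        with pytest.raises(ValueError):
            log2_enrichment(_table([10], [10], chip_lib=0))


class TestSlidingTrack:
    def test_window_count_and_constant_coverage(self):
        cov = {"chr1": np.ones(1000)}
        recs = sliding_track(cov, cov, 1e6, 1e6, window=200, step=50)
        # starts 0,50,...,800 full; the last full window reaches 1000
        assert len(recs) == 17
        values = {r[3] for r in recs}
        assert max(values) - min(values) < 1e-12

    def test_agrees_with_direct_per_window_computation(self, rng):
        chip = {"c": rng.poisson(5, 500).astype(float)}
        inp = {"c": rng.poisson(5, 500).astype(float)}
        recs = sliding_track(chip, inp, 1e6, 1e6, window=100, step=30)
        for chrom, s, e, v in recs:
            c, i = chip[chrom][s:e].sum(), inp[chrom][s:e].sum()
            kb = (e - s) / 1000
            want = np.log2(((c + 0.5) / kb) / ((i + 0.5) / kb))
            assert v == pytest.approx(want)


class TestTileSummary:
    def test_single_kind_genome(self):
        regions = [GenomicInterval("c", i * 1000, (i + 1) * 1000, ".", f"t{i}",
                                   "tile") for i in range(10)]
        track = EnrichmentTrack(regions, np.arange(10.0), 1)
        ann = [GenomicInterval("c", 0, 10_000, "+", "g", "gene_body")]
        out = tile_summary(track, ann)
        assert out["top"] == {"gene_body": 1.0}
        assert out["bottom"] == {"gene_body": 1.0}

    def test_fractional_assignment_on_two_kind_overlap(self):
        regions = [GenomicInterval("c", 0, 1000, ".", "t0", "tile"),
                   GenomicInterval("c", 1000, 2000, ".", "t1", "tile")]
        track = EnrichmentTrack(regions, np.array([1.0, 0.0]), 1)
        ann = [GenomicInterval("c", 0, 500, "+", "g", "gene_body"),
               GenomicInterval("c", 400, 900, ".", "p", "promoter")]
        out = tile_summary(track, ann, fraction=0.5)
        # top tile t0 overlaps both kinds -> 1/2 each
        assert out["top"] == {"gene_body": 0.5, "promoter": 0.5}
        assert out["bottom"] == {"intergenic": 1.0}

    def test_selects_twenty_percent(self, rng):
        n = 100
        regions = [GenomicInterval("c", i * 1000, (i + 1) * 1000, ".", f"t{i}",
                                   "tile") for i in range(n)]
        track = EnrichmentTrack(regions, rng.normal(size=n), 1)
        out = tile_summary(track, [])
        assert sum(out["top"].values()) == pytest.approx(1.0)


def brute_force_best_3_partition(values):
    """Enumerate all contiguous 3-partitions of the sorted values; return
    the marked set (top cluster) of the SSE-minimal one."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = (np.inf, None)
    for i, j in combinations(range(1, n), 2):
        parts = [x[:i], x[i:j], x[j:]]
        sse = sum(((p - p.mean()) ** 2).sum() for p in parts)
        if sse < best[0] - 1e-12:
            best = (sse, set(parts[2].tolist()))
    return best


class TestCallMarked:
    def test_three_group_fixture(self):
        vals = np.array([-1.1, -1.0, -0.9, 0.5, 0.6, 3.0, 3.1])
        calls = call_marked([f"r{i}" for i in range(7)], vals)
        assert set(np.array(vals)[calls.marked]) == {3.0, 3.1}

    def test_exactly_three_values(self):
        vals = np.array([0.0, 0.0, 1.0, 1.0, 5.0, 5.0])
        calls = call_marked([f"r{i}" for i in range(6)], vals)
        assert calls.cluster_means == pytest.approx([0.0, 1.0, 5.0])
        assert set(np.where(calls.marked)[0]) == {4, 5}

    def test_two_distinct_values_error(self):
        with pytest.raises(DegenerateInputError):
            call_marked(["a", "b", "c"], np.array([1.0, 2.0, 1.0]))

    def test_matches_exhaustive_partition_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            vals = np.round(rng.normal(size=n), 3)
            if len(np.unique(vals)) < 3:
                continue
            sse_oracle, marked_oracle = brute_force_best_3_partition(vals)
            labels, means = kmeans_1d(vals, 3)
            sse = sum(((vals[labels == c] - vals[labels == c].mean()) ** 2).sum()
                      for c in range(3))
            assert sse == pytest.approx(sse_oracle, abs=1e-9)

    def test_recovery_on_planted_enrichment(self):
        cfg = SimulationConfig(seed=21, mean_depth_per_region=50.0,
                               planted_chip_log2fc=2.0)
        regions = [GenomicInterval("chr1", i * 1000, (i + 1) * 1000, ".",
                                   f"r{i}") for i in range(2000)]
        marked_true = {f"r{i}" for i in range(200)}  # 10%
        table = simulate_chip_counts(regions, marked_true, cfg)
        track = log2_enrichment(table)
        calls = call_marked(track.regions, track.values)
        called = calls.marked_ids()
        tp = len(called & marked_true)
        assert tp / len(called) >= 0.9
        assert tp / len(marked_true) >= 0.9


class TestDifferentialEnrichment:
    def _pair(self, seed=3):
        cfg = SimulationConfig(seed=seed, mean_depth_per_region=50.0)
        regions = [GenomicInterval("chr1", i * 1000, (i + 1) * 1000, ".",
                                   f"r{i}") for i in range(600)]
        a_only = {f"r{i}" for i in range(0, 60)}
        both = {f"r{i}" for i in range(60, 120)}
        b_only = {f"r{i}" for i in range(120, 180)}
        import epistate.synthetic_data as sd

        ta = simulate_chip_counts(regions, a_only | both, cfg, cell_type="A",
                                  rng=sd.child_rng(seed, "A"))
        tb = simulate_chip_counts(regions, b_only | both, cfg, cell_type="B",
                                  rng=sd.child_rng(seed, "B"))
        return ta, tb, a_only, both, b_only

    def test_planted_classes_recovered(self):
        ta, tb, a_only, both, b_only = self._pair()
        ca = call_marked(ta.regions, log2_enrichment(ta).values)
        cb = call_marked(tb.regions, log2_enrichment(tb).values)
        res = differential_enrichment(ta, tb, ca, cb)
        res = res.set_index("region_id")
        for ids, want in ((a_only, "A_only"), (both, "both"),
                          (b_only, "B_only")):
            frac = (res.loc[sorted(ids), "class"] == want).mean()
            assert frac >= 0.9, (want, frac)
        unmarked = [f"r{i}" for i in range(180, 600)]
        assert (res.loc[unmarked, "class"] == "neither").mean() >= 0.95

    def test_identical_tables_never_differential(self):
        ta, _, a_only, both, _ = self._pair()
        ca = call_marked(ta.regions, log2_enrichment(ta).values)
        res = differential_enrichment(ta, ta, ca, ca)
        assert set(res["class"]) <= {"both", "neither"}


class TestMetagene:
    def _gene(self, chrom, start, end, strand, gid):
        return GeneModel(GenomicInterval(chrom, start, end, strand, gid), gid)

    def test_constant_track_gives_flat_profile(self):
        vals = {"c": np.full(40_000, 2.5)}
        genes = [self._gene("c", 10_000, 20_000, "+", "g1")]
        prof = metagene_profile(vals, genes, {"all": ["g1"]})
        assert prof.loc["all"].to_numpy() == pytest.approx(2.5)

    def test_two_gene_average_and_strand_flip(self):
        arr = np.zeros(40_000)
        arr[10_000:20_000] = 1.0  # g1 body
        arr[25_000:30_000] = 3.0  # g2 body
        vals = {"c": arr}
        g1 = self._gene("c", 10_000, 20_000, "+", "g1")
        g2 = self._gene("c", 25_000, 30_000, "-", "g2")
        prof = metagene_profile(vals, [g1, g2], {"both": ["g1", "g2"]},
                                body_bins=10, flank_bp=5000, flank_bins=5)
        body = prof.loc["both"].to_numpy()[5:15]
        assert body == pytest.approx(2.0)  # mean of 1 and 3 per body bin
        # minus-strand flip: g2's downstream flank (genomic left) is the
        # profile's 3' end; both flanks are zero here
        assert prof.loc["both"].to_numpy()[:5] == pytest.approx(0.0)


class TestScaleAbsolute:
    def test_factor_one_is_identity_and_two_adds_one(self):
        regions = [GenomicInterval("c", 0, 10, ".", "r0")]
        tr = EnrichmentTrack(regions, np.array([1.5]), 2)
        assert scale_absolute(tr, 1.0).values == pytest.approx([1.5])
        assert scale_absolute(tr, 2.0).values == pytest.approx([2.5])
        round_trip = scale_absolute(scale_absolute(tr, 2.0), 0.5)
        assert round_trip.values == pytest.approx(tr.values)
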