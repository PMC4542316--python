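import numpy as np
import pandas as pd
import pytest

from epirewire.regions import GenomicRegion, RegionSet, TSSAnnotation
from epirewire.signal import (
    CoverageTrack,
    composite_profile,
    ks_compare,
    methylation_at_regions,
    quantify_regions,
    stratify_by_expression,
    tile_genome,
)


def constant_track(value, genome, library_size=0.0):
    chroms = {
        c: (np.array([0]), np.array([length]), np.array([float(value)]))
        for c, length in genome.items()
    }
    return CoverageTrack("mark", "high", 1, chroms, library_size=library_size)


class TestTiling:
    def test_truncation_at_chrom_end(self):
        tiles = tile_genome({"chr1": 2500}, width=1000)
        assert [(t.start, t.end) for t in tiles] == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_exact_fit_single_window(self):
        assert len(tile_genome({"chr1": 1000}, width=1000)) == 1

    def test_total_count_closed_form(self):
        genome = {f"chr{i}": ln for i, ln in enumerate([2500, 999, 1000, 7300, 5])}
        tiles = tile_genome(genome, width=1000)
        assert len(tiles) == sum(-(-ln // 1000) for ln in genome.values())

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            tile_genome({"chr1": 1000}, width=0)


class TestQuantify:
    def test_hand_arithmetic(self, toy_genome):
        # constant 2 over a 1-kb region, library 1e6:
        # raw = 2*1000 = 2000; normalized = 2000*1e6/1e6/1 = 2000; log2 -> ~10.97
        track = constant_track(2, toy_genome, library_size=1e6)
        regions = RegionSet("r", [GenomicRegion("chr1", 1000, 2000, ".", "r0")], toy_genome)
        raw = quantify_regions(track, regions, log=False, normalize=False)
        assert raw[0] == pytest.approx(2000.0)
        norm = quantify_regions(track, regions, log=False)
        assert norm[0] == pytest.approx(2000.0)
        logged = quantify_regions(track, regions, log=True)
        assert logged[0] == pytest.approx(np.log2(2001.0))

    def test_zero_coverage(self, toy_genome):
        track = constant_track(0, toy_genome, library_size=1e6)
        regions = RegionSet("r", [GenomicRegion("chr1", 0, 1000, ".", "r0")], toy_genome)
        assert quantify_regions(track, regions)[0] == 0.0

    def test_split_coverage_per_bp_mean(self, toy_genome):
        # values 1 and 3 on each half of a region -> per-bp mean 2
        chroms = {
            "chr1": (np.array([0, 500]), np.array([500, 1000]), np.array([1.0, 3.0]))
        }
        track = CoverageTrack("m", "high", 1, chroms, library_size=1e6)
        regions = RegionSet("r", [GenomicRegion("chr1", 0, 1000, ".", "r0")], {"chr1": 1000})
        raw = quantify_regions(track, regions, log=False, normalize=False)
        assert raw[0] / 1000 == pytest.approx(2.0)

    def test_additivity_under_region_split(self):
        rng = np.random.default_rng(0)
        bounds = np.sort(rng.choice(np.arange(1, 5000), size=30, replace=False))
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [5000]))
        values = rng.uniform(0, 5, size=len(starts))
        genome = {"chr1": 5000}
        track = CoverageTrack("m", "high", 1, {"chr1": (starts, ends, values)})
        for split in (1, 1234, 2500, 4999):
            whole = RegionSet("w", [GenomicRegion("chr1", 0, 5000, ".", "w")], genome)
            parts = RegionSet(
                "p",
                [GenomicRegion("chr1", 0, split, ".", "a"),
                 GenomicRegion("chr1", split, 5000, ".", "b")],
                genome,
            )
            w = quantify_regions(track, whole, log=False, normalize=False)[0]
            p = quantify_regions(track, parts, log=False, normalize=False).sum()
            assert p == pytest.approx(w, rel=1e-12)

    def test_missing_chrom_warns_and_zeroes(self, toy_genome, caplog):
        track = CoverageTrack(
            "m", "high", 1,
            {"chr1": (np.array([0]), np.array([10_000]), np.array([1.0]))},
        )
        regions = RegionSet("r", [GenomicRegion("chr2", 0, 1000, ".", "r0")], toy_genome)
        with caplog.at_level("WARNING"):
            out = quantify_regions(track, regions)
        assert out[0] == 0.0
        assert "chr2" in caplog.text


class TestCompositeProfile:
    def test_constant_track_gives_flat_profile(self):
        genome = {"chr1": 100_000}
        track = constant_track(3, genome)
        anchors = [TSSAnnotation("g", "t", "chr1", 50_000, "+")]
        prof = composite_profile(track, anchors, flank=2000, bin_width=100)["all"]
        assert np.allclose(prof.mean_signal, 3.0, atol=1e-9)

    def test_localized_signal_lands_in_first_downstream_bin(self):
        genome = {"chr1": 100_000}
        tss = 50_000
        chroms = {"chr1": (np.array([tss]), np.array([tss + 100]), np.array([7.0]))}
        track = CoverageTrack("m", "high", 1, chroms)
        prof = composite_profile(
            track, [TSSAnnotation("g", "t", "chr1", tss, "+")], flank=1000, bin_width=100
        )["all"]
        nonzero = np.flatnonzero(prof.mean_signal)
        assert nonzero.tolist() == [10]  # first bin at offset [0, 100)
        assert prof.offsets[10] == 50.0

    def test_minus_anchor_is_mirrored(self):
        # signal upstream of a "-" TSS (larger coordinates) must appear downstream
        genome = {"chr1": 100_000}
        tss = 50_000
        chroms = {"chr1": (np.array([tss - 100]), np.array([tss]), np.array([7.0]))}
        track = CoverageTrack("m", "high", 1, chroms)
        prof = composite_profile(
            track, [TSSAnnotation("g", "t", "chr1", tss, "-")], flank=1000, bin_width=100
        )["all"]
        nonzero = np.flatnonzero(prof.mean_signal)
        assert nonzero.tolist() == [10]

    def test_empty_stratum_omitted_with_warning(self):
        genome = {"chr1": 100_000}
        track = constant_track(1, genome)
        anchors = [TSSAnnotation("g", "t", "chr1", 50_000, "+")]
        profs = composite_profile(track, anchors, flank=1000, bin_width=100, strata=["x"])
        assert "x" in profs and len(profs) == 1


class TestExpressionStrata:
    def test_caption_percentages(self):
        expr = pd.Series(np.arange(100, dtype=float), index=[f"g{i}" for i in range(100)])
        labels = stratify_by_expression(expr)
        counts = labels.value_counts()
        assert counts["high"] == 20
        assert counts["moderate"] == 60
        assert counts["low"] == 10
        assert counts["unassigned"] == 10

    def test_sort_oracle_on_random_values(self):
        rng = np.random.default_rng(1)
        expr = pd.Series(rng.normal(size=137), index=[f"g{i}" for i in range(137)])
        labels = stratify_by_expression(expr)
        order = expr.sort_values(ascending=False)
        n = len(expr)
        for i, g in enumerate(order.index):
            frac = (i + 1) / n
            want = (
                "high" if frac <= 0.2 else
                "moderate" if frac <= 0.8 else
                "unassigned" if frac <= 0.9 else "low"
            )
            assert labels[g] == want

    def test_ties_broken_by_input_order(self):
        expr = pd.Series(np.ones(10), index=[f"g{i}" for i in range(10)])
        labels = stratify_by_expression(expr)
        assert labels["g0"] == "high" and labels["g9"] == "low"

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_expression(pd.Series([1.0] * 9))


class TestMethylation:
    def make_meth(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_reads", "total_reads"])
        df["beta"] = df["meth_reads"] / df["total_reads"]
        return df

    def test_mean_beta(self, toy_genome):
        meth = self.make_meth(
            [("chr1", 110, 2, 10), ("chr1", 120, 4, 10), ("chr1", 130, 6, 10)]
        )
        regions = RegionSet("r", [GenomicRegion("chr1", 100, 200, ".", "r0")], toy_genome)
        out = methylation_at_regions(meth, regions, min_cpgs=3)
        assert out["r0"] == pytest.approx(0.4)

    def test_sparse_region_excluded(self, toy_genome):
        meth = self.make_meth([("chr1", 110, 2, 10), ("chr1", 120, 4, 10)])
        regions = RegionSet("r", [GenomicRegion("chr1", 100, 200, ".", "r0")], toy_genome)
        out = methylation_at_regions(meth, regions, min_cpgs=3)
        assert "r0" not in out.index

    def test_unweighted_equals_pooled_on_uniform_coverage(self, toy_genome):
        # with equal total_reads per CpG the unweighted mean equals read pooling
        rng = np.random.default_rng(2)
        rows = [("chr1", 100 + 10 * i, int(rng.integers(0, 21)), 20) for i in range(8)]
        meth = self.make_meth(rows)
        regions = RegionSet("r", [GenomicRegion("chr1", 90, 400, ".", "r0")], toy_genome)
        out = methylation_at_regions(meth, regions)
        pooled = sum(r[2] for r in rows) / sum(r[3] for r in rows)
        assert out["r0"] == pytest.approx(pooled)


class TestKS:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        d, p = ks_compare(x, x)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_compare([1, 2, 3, 4, 4.5], [5, 6, 7, 8, 9])
        assert d == 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([1, 2, 3, 4], [5, 6, 7, 8, 9])

    def test_matches_ecdf_scan_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=50)
        b = rng.normal(0.5, 1.2, size=50)
        d, _ = ks_compare(a, b)
        pooled = np.concatenate((a, b))
        d_brute = max(
            abs((a <= t).mean() - (b <= t).mean()) for t in pooled
        )
        assert d == pytest.approx(d_brute, abs=1e-12)

    def test_null_p_values_are_calibrated(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            _, p = ks_compare(a, b)
            hits += p >= 0.05
        assert hits / n_sim >= 0.94
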