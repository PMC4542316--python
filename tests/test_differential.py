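import numpy as np
import pandas as pd
import pytest

from epirewire.differential import (
    call_de,
    call_diff_peaks,
    foldchange_by_binding,
    promoter_fraction_by_bin,
    rank_and_bin,
    size_factors,
    topn_binding_curve,
)
from epirewire.regions import GenomicRegion, RegionSet


COLS = ["high_rep1", "high_rep2", "low_rep1", "low_rep2"]


def nb_counts(rng, mean, dispersion, size):
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mean), size=size)


def simulate_counts(rng, n_null, n_up, mean=200.0, dispersion=0.05, lfc=2.0):
    """Null features plus features planted higher in the high state."""
    rows = []
    for _ in range(n_null):
        rows.append(nb_counts(rng, mean, dispersion, 4))
    for _ in range(n_up):
        hi = nb_counts(rng, mean * 2 ** (lfc / 2), dispersion, 2)
        lo = nb_counts(rng, mean * 2 ** (-lfc / 2), dispersion, 2)
        rows.append(np.concatenate((hi, lo)))
    idx = [f"f{i}" for i in range(n_null + n_up)]
    return pd.DataFrame(rows, index=idx, columns=COLS)


class TestCallDE:
    def test_identical_counts_are_unchanged(self):
        # every feature constant across samples -> size factors are exactly 1
        rng = np.random.default_rng(0)
        values = rng.integers(10, 1000, size=200)
        counts = pd.DataFrame(
            np.repeat(values[:, None], 4, axis=1),
            columns=COLS, index=[f"f{i}" for i in range(200)],
        )
        out = call_de(counts).set_index("id")
        assert (out["log2fc"] == 0.0).all()
        assert (out["label"] == "unchanged").all()

    def test_state_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        counts = simulate_counts(rng, 300, 100)
        fwd = call_de(counts).set_index("id")
        swapped = counts[["low_rep1", "low_rep2", "high_rep1", "high_rep2"]]
        swapped.columns = COLS
        rev = call_de(swapped).set_index("id")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"], rtol=1e-9)
        flip = {"correlated": "anticorrelated", "anticorrelated": "correlated",
                "unchanged": "unchanged"}
        assert (fwd["label"].map(flip) == rev["label"]).all()

    def test_power_on_planted_fourfold_effect(self):
        # 4-fold change, mean 200, dispersion 0.05, n = 2 vs 2
        rng = np.random.default_rng(2)
        counts = simulate_counts(rng, 2000, 500)
        out = call_de(counts).set_index("id")
        planted = out.iloc[2000:]
        assert (planted["label"] == "correlated").mean() >= 0.95

    def test_null_discoveries_controlled(self):
        rng = np.random.default_rng(3)
        counts = simulate_counts(rng, 3000, 0)
        out = call_de(counts)
        se = np.sqrt(0.05 * 0.95 / len(out))
        assert (out["fdr"] < 0.05).mean() <= 0.05 + 3 * se

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(4)
        counts = simulate_counts(rng, 500, 100)
        strict = call_de(counts, alpha=0.01)
        loose = call_de(counts, alpha=0.05)
        strict_sig = set(strict.loc[strict["label"] != "unchanged", "id"])
        loose_sig = set(loose.loc[loose["label"] != "unchanged", "id"])
        assert strict_sig <= loose_sig

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame(
            [[10, 20, 30]], columns=["high_rep1", "low_rep1", "low_rep2"], index=["f0"]
        )
        with pytest.raises(ValueError):
            call_de(counts)

    def test_size_factors_recover_depth_ratio(self):
        rng = np.random.default_rng(5)
        base = nb_counts(rng, 300, 0.05, size=(2000, 4)).astype(float)
        scaled = base * np.array([1.0, 2.0, 0.5, 1.0])
        sf = size_factors(scaled)
        ratios = sf / sf[3]
        assert np.allclose(ratios, [1.0, 2.0, 0.5, 1.0], rtol=0.05)


class TestDiffPeaks:
    def test_state_swap_flips_labels(self):
        rng = np.random.default_rng(6)
        sig = pd.DataFrame(
            nb_counts(rng, 500, 0.05, size=(200, 4)).astype(float),
            columns=pd.MultiIndex.from_tuples(
                [("high", 1), ("high", 2), ("low", 1), ("low", 2)]
            ),
            index=[f"pk{i}" for i in range(200)],
        )
        sig.iloc[:50, :2] *= 8  # planted correlated
        fwd = call_diff_peaks(sig).set_index("id")
        swapped = sig.copy()
        swapped.columns = pd.MultiIndex.from_tuples(
            [("low", 1), ("low", 2), ("high", 1), ("high", 2)]
        )
        swapped = swapped[[("high", 1), ("high", 2), ("low", 1), ("low", 2)]]
        rev = call_diff_peaks(swapped).set_index("id")
        flip = {"correlated": "anticorrelated", "anticorrelated": "correlated",
                "unchanged": "unchanged"}
        assert (fwd["label"].map(flip) == rev["label"]).all()
        assert (fwd.iloc[:50]["label"] == "correlated").mean() >= 0.9

    def test_zero_signal_peak_unchanged(self):
        rng = np.random.default_rng(7)
        sig = pd.DataFrame(
            nb_counts(rng, 500, 0.05, size=(100, 4)).astype(float),
            columns=pd.MultiIndex.from_tuples(
                [("high", 1), ("high", 2), ("low", 1), ("low", 2)]
            ),
            index=[f"pk{i}" for i in range(100)],
        )
        sig.iloc[0] = 0.0
        out = call_diff_peaks(sig).set_index("id")
        assert out.loc["pk0", "label"] == "unchanged"
        assert out.loc["pk0", "log2fc"] == 0.0

    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(8)
        n = 400
        sig = pd.DataFrame(
            nb_counts(rng, 400, 0.05, size=(n, 4)).astype(float),
            columns=pd.MultiIndex.from_tuples(
                [("high", 1), ("high", 2), ("low", 1), ("low", 2)]
            ),
            index=[f"pk{i}" for i in range(n)],
        )
        sig.iloc[:200, :2] *= 3.0  # correlated, 3-fold
        sig.iloc[200:, 2:] *= 3.0  # anticorrelated
        out = call_diff_peaks(sig).set_index("id")
        sig_calls = out[out["label"] != "unchanged"]
        planted = np.where(
            np.arange(n) < 200, "correlated", "anticorrelated"
        )
        planted = pd.Series(planted, index=out.index)
        agree = (sig_calls["label"] == planted.loc[sig_calls.index]).mean()
        assert agree >= 0.98


def diff_frame(mags, ps=None):
    n = len(mags)
    ps = ps if ps is not None else np.linspace(0.001, 0.01, n)
    return pd.DataFrame(
        {
            "id": [f"pk{i}" for i in range(n)],
            "log2fc": mags,
            "p": ps,
            "fdr": ps,
            "label": ["correlated"] * n,
            "magnitude": np.abs(mags),
        }
    )


class TestRankAndBin:
    def test_even_bins_of_two(self):
        bins = rank_and_bin(diff_frame(np.arange(10, 0, -1.0)), q=5)
        assert bins.table.groupby("bin").size().tolist() == [2, 2, 2, 2, 2]

    def test_bin_order_follows_magnitude(self):
        bins = rank_and_bin(diff_frame(np.array([5.0, 4.0, 3.0, 2.0, 1.5])), q=5)
        assert bins.table["magnitude"].tolist() == [5.0, 4.0, 3.0, 2.0, 1.5]
        assert bins.table["bin"].tolist() == [1, 2, 3, 4, 5]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        mags = rng.uniform(1, 6, size=200)
        bins = rank_and_bin(diff_frame(mags), q=5)
        order = np.argsort(-mags, kind="stable")
        expected_bins = np.concatenate(
            [np.full(len(part), i + 1) for i, part in enumerate(np.array_split(order, 5))]
        )
        by_id = dict(zip([f"pk{i}" for i in order], expected_bins))
        assert all(by_id[r.id] == r.bin for r in bins.table.itertuples())

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            rank_and_bin(diff_frame(np.array([2.0, 3.0])), q=5)


class TestPeakSummaries:
    def make_peaks(self, n, genome, promoter_hits):
        regs = [
            GenomicRegion("chr1", 1000 * i + 100, 1000 * i + 400, ".", f"pk{i}")
            for i in range(n)
        ]
        peaks = RegionSet("peaks", regs, genome)
        proms = RegionSet(
            "promoters",
            [GenomicRegion("chr1", 1000 * i + 100, 1000 * i + 400, ".", f"pr{i}")
             for i in promoter_hits],
            genome,
        )
        return peaks, proms

    def test_promoter_fraction(self):
        genome = {"chr1": 100_000}
        peaks, proms = self.make_peaks(8, genome, promoter_hits=[0])
        bins = rank_and_bin(diff_frame(np.arange(8, 0, -1.0)), q=2)
        frac = promoter_fraction_by_bin(bins, peaks, proms)
        assert frac[1] == pytest.approx(0.25)  # pk0 in the top bin of 4
        assert frac[2] == pytest.approx(0.0)

    def test_topn_curve_example(self):
        genome = {"chr1": 100_000}
        peaks, tf = self.make_peaks(10, genome, promoter_hits=[0, 1, 2])
        bins = rank_and_bin(diff_frame(np.arange(10, 0, -1.0)), q=5)
        curve = topn_binding_curve(bins, peaks, tf, n_grid=[1, 2, 3, 4, 10])
        assert curve["fraction"].tolist() == [1.0, 1.0, 1.0, 0.75, 0.3]

    def test_topn_final_point_is_overall_fraction(self):
        genome = {"chr1": 100_000}
        rng = np.random.default_rng(10)
        hits = sorted(rng.choice(20, size=7, replace=False))
        peaks, tf = self.make_peaks(20, genome, promoter_hits=hits)
        bins = rank_and_bin(diff_frame(rng.uniform(1, 5, size=20)), q=4)
        curve = topn_binding_curve(bins, peaks, tf, n_grid=[20])
        assert curve["fraction"].iloc[-1] == pytest.approx(7 / 20)

    def test_topn_no_binding(self):
        genome = {"chr1": 100_000}
        peaks, tf = self.make_peaks(10, genome, promoter_hits=[])
        tf = RegionSet("tf", [GenomicRegion("chr1", 90_000, 90_100, ".", "t0")], genome)
        bins = rank_and_bin(diff_frame(np.arange(10, 0, -1.0)), q=5)
        curve = topn_binding_curve(bins, peaks, tf, n_grid=[5, 10])
        assert curve["fraction"].tolist() == [0.0, 0.0]

    def test_foldchange_split_matches_overlap_definition(self):
        genome = {"chr1": 100_000}
        peaks, tf = self.make_peaks(20, genome, promoter_hits=list(range(6)))
        diff = diff_frame(np.linspace(1, 4, 20))
        diff.loc[:5, "log2fc"] += 5.0
        diff["magnitude"] = diff["log2fc"].abs()
        out = foldchange_by_binding(diff, peaks, tf)
        assert len(out["bound"]) == 6 and len(out["unbound"]) == 14
        assert out["ks_D"] > 0.5

    def test_foldchange_insufficient_groups_rejected(self):
        genome = {"chr1": 100_000}
        peaks, tf = self.make_peaks(8, genome, promoter_hits=[0])
        with pytest.raises(ValueError):
            foldchange_by_binding(diff_frame(np.arange(8.0) + 1), peaks, tf)
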