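import numpy as np
import pandas as pd
import pytest

from epirewire.chromclust import (
    MARKS,
    binarize_marks,
    classify,
    cluster_transcripts,
    curate_training,
    fit_classifier,
    match_prototype,
    seed_clusters,
    summarize_mark_changes,
)


def planted_vectors(rng, n_per_class, sigma=0.5, mu_present=6.0, mu_absent=1.0):
    """Five-mark signal for the four prototype classes with known truth."""
    patterns = {
        1: [1, 1, 1, 1, 0],
        2: [1, 1, 0, 0, 0],
        3: [0, 1, 0, 0, 0],
        4: [0, 0, 0, 0, 1],  # repressed; K4 marks drawn separately
    }
    rows, truth = [], []
    for cls, pat in patterns.items():
        for _ in range(n_per_class):
            pat_i = list(pat)
            if cls == 4:
                pat_i[0] = int(rng.integers(0, 2))
                pat_i[1] = int(rng.integers(0, 2))
            mu = np.where(np.array(pat_i) == 1, mu_present, mu_absent)
            rows.append(rng.normal(mu, sigma))
            truth.append(cls)
    idx = [f"tx{i}" for i in range(len(rows))]
    return (
        pd.DataFrame(rows, index=idx, columns=list(MARKS)),
        pd.Series(truth, index=idx),
    )


class TestBinarize:
    def test_bimodal_fixture_recovers_presence(self):
        rng = np.random.default_rng(0)
        truth = rng.random(500) < 0.4
        x = np.where(truth, rng.normal(6, 0.5, 500), rng.normal(1, 0.5, 500))
        df = pd.DataFrame({m: x for m in MARKS}, index=[f"t{i}" for i in range(500)])
        calls, thr = binarize_marks(df)
        for m in MARKS:
            assert (calls[m].to_numpy() == truth).mean() >= 0.99
            assert 1.5 < thr[m] < 5.5

    def test_constant_mark_all_absent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {m: (np.zeros(100) if m == "H3K27me3" else rng.normal(3, 1, 100)) for m in MARKS}
        )
        calls, _ = binarize_marks(df)
        assert not calls["H3K27me3"].any()

    def test_shift_invariance_of_calls(self):
        rng = np.random.default_rng(2)
        x = np.where(rng.random(300) < 0.5, rng.normal(6, 0.5, 300), rng.normal(1, 0.5, 300))
        df = pd.DataFrame({m: x for m in MARKS})
        calls_a, _ = binarize_marks(df)
        calls_b, _ = binarize_marks(df + 10.0)
        assert calls_a.equals(calls_b)

    def test_too_few_transcripts_rejected(self):
        df = pd.DataFrame(np.ones((10, 5)), columns=list(MARKS))
        with pytest.raises(ValueError):
            binarize_marks(df)


class TestPrototypes:
    def call(self, **marks):
        base = {m: False for m in MARKS}
        base.update(marks)
        return match_prototype(pd.Series(base))

    def test_k4me1_only_is_cluster3(self):
        assert self.call(H3K4me1=True) == 3

    def test_k4me1_with_k4me3_is_cluster2(self):
        assert self.call(H3K4me3=True, H3K4me1=True) == 2

    def test_repressed_with_k4_methylation_is_cluster4(self):
        assert self.call(H3K27me3=True, H3K4me3=True, H3K4me1=True) == 4
        assert self.call(H3K27me3=True) == 4

    def test_fully_active_is_cluster1(self):
        assert self.call(H3K4me3=True, H3K4me1=True, H3K27ac=True, H3K56ac=True) == 1

    def test_partial_acetylation_matches_nothing(self):
        assert self.call(H3K4me3=True, H3K4me1=True, H3K27ac=True) is None


class TestSeedClusters:
    def test_separated_prototypes_give_pure_groups(self):
        rng = np.random.default_rng(3)
        vec, truth = planted_vectors(rng, 50, sigma=0.3)
        seeds = seed_clusters(vec, k_init=8)
        for g in seeds.unique():
            members = truth[seeds == g]
            purity = members.value_counts().iloc[0] / len(members)
            assert purity >= 0.9

    def test_duplication_stability(self):
        rng = np.random.default_rng(4)
        vec, _ = planted_vectors(rng, 10)
        doubled = pd.concat([vec, vec.set_index(vec.index + "_dup")])
        seeds = seed_clusters(doubled, k_init=4)
        # each row and its duplicate land in the same group
        for t in vec.index:
            assert seeds[t] == seeds[t + "_dup"]

    def test_small_k_rejected(self):
        rng = np.random.default_rng(5)
        vec, _ = planted_vectors(rng, 5)
        with pytest.raises(ValueError):
            seed_clusters(vec, k_init=3)


class TestCuration:
    def test_majority_pattern_members_become_training(self):
        presence = pd.DataFrame(
            [[True, True, False, False, False]] * 9
            + [[True, True, True, True, False]],
            columns=list(MARKS),
            index=[f"t{i}" for i in range(10)],
        )
        seeds = pd.Series(0, index=presence.index)
        # single group, 9/10 match C2 -> those 9 train C2; C1/C3/C4 are empty
        with pytest.raises(ValueError, match="cluster"):
            curate_training(seeds, presence)

    def test_end_to_end_training_covers_all_classes(self):
        rng = np.random.default_rng(6)
        vec, truth = planted_vectors(rng, 60, sigma=0.5)
        presence, _ = binarize_marks(vec)
        seeds = seed_clusters(vec, k_init=8)
        training = curate_training(seeds, presence)
        assert set(training.unique()) == {1, 2, 3, 4}
        agree = (truth.loc[training.index] == training).mean()
        assert agree >= 0.95


class TestClassifier:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(7)
        vec, truth = planted_vectors(rng, 40, sigma=0.3)
        clf = fit_classifier(vec, truth)
        post = clf.posterior(vec)
        acc = (post.argmax(axis=1) + 1 == truth.to_numpy()).mean()
        assert acc >= 0.99

    def test_small_class_rejected(self):
        rng = np.random.default_rng(8)
        vec, truth = planted_vectors(rng, 40)
        truth = truth.copy()
        keep = truth.index[(truth != 4)].tolist() + truth.index[truth == 4][:5].tolist()
        with pytest.raises(ValueError, match="10"):
            fit_classifier(vec.loc[keep], truth.loc[keep])

    def test_k27ac_coefficient_separates_c1_from_c2(self):
        rng = np.random.default_rng(9)
        vec, truth = planted_vectors(rng, 50, sigma=0.5)
        clf = fit_classifier(vec, truth)
        coefs = clf.coefficients
        assert coefs.loc["C1", "H3K27ac"] > coefs.loc["C2", "H3K27ac"]

    def test_imbalance_keeps_posterior_ranking(self):
        rng = np.random.default_rng(10)
        vec, truth = planted_vectors(rng, 60, sigma=0.4)
        clf_bal = fit_classifier(vec, truth)
        # 3:1 imbalance: thin class 2-4 training to 20 rows each
        keep = []
        for cls, cap in [(1, 60), (2, 20), (3, 20), (4, 20)]:
            keep.extend(truth.index[truth == cls][:cap])
        clf_imb = fit_classifier(vec.loc[keep], truth.loc[keep])
        rng2 = np.random.default_rng(11)
        held, held_truth = planted_vectors(rng2, 10, sigma=0.3)
        top_bal = clf_bal.posterior(held).argmax(axis=1)
        top_imb = clf_imb.posterior(held).argmax(axis=1)
        assert (top_bal == top_imb).mean() >= 0.95

    def test_posteriors_sum_to_one_and_rule_applies(self):
        rng = np.random.default_rng(12)
        vec, truth = planted_vectors(rng, 40, sigma=1.5)
        clf = fit_classifier(vec, truth)
        out = classify(clf, vec, p_min=0.5, margin=0.1)
        post = out[["p1", "p2", "p3", "p4"]].to_numpy()
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        srt = np.sort(post, axis=1)
        rule = (srt[:, -1] >= 0.5) & (srt[:, -1] - srt[:, -2] >= 0.1)
        assert (out["unambiguous"].to_numpy() == rule).all()
        assert (out.loc[~out["unambiguous"], "cluster"] == "ambiguous").all()

    def test_mark_order_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        vec, truth = planted_vectors(rng, 40)
        clf = fit_classifier(vec, truth)
        with pytest.raises(ValueError, match="mark order"):
            clf.posterior(vec[list(reversed(MARKS))])


class TestEndToEnd:
    def test_well_separated_recovery(self):
        rng = np.random.default_rng(14)
        vec, truth = planted_vectors(rng, 80, sigma=0.3)
        out, _ = cluster_transcripts(vec, seed=0)
        assert (out["best_cluster"] == truth).mean() >= 0.95
        unamb = out[out["unambiguous"]]
        assert (unamb["best_cluster"] == truth.loc[unamb.index]).mean() >= 0.99

    def test_permutation_invariance(self):
        rng = np.random.default_rng(15)
        vec, _ = planted_vectors(rng, 40, sigma=0.5)
        out1, _ = cluster_transcripts(vec, seed=0)
        perm = vec.sample(frac=1.0, random_state=1)
        out2, _ = cluster_transcripts(perm, seed=0)
        joined = out1.join(out2, lsuffix="_a", rsuffix="_b")
        assert (joined["best_cluster_a"] == joined["best_cluster_b"]).all()


class TestMarkChanges:
    def make_assignments(self, idx, cluster=1):
        return pd.DataFrame(
            {"best_cluster": cluster, "unambiguous": True}, index=idx
        )

    def test_exact_unit_gain(self):
        idx = pd.Index([f"t{i}" for i in range(20)])
        hi = pd.DataFrame(np.full((20, 5), 3.0), index=idx, columns=list(MARKS))
        lo = hi + 1.0
        out = summarize_mark_changes(self.make_assignments(idx), hi, lo)
        k27 = out[(out["cluster"] == 1) & (out["mark"] == "H3K27ac")].iloc[0]
        assert k27["mean_log2_change"] == pytest.approx(1.0)
        assert k27["ci_lo"] == pytest.approx(1.0) and k27["ci_hi"] == pytest.approx(1.0)

    def test_acetylation_loss_is_negative(self):
        # correlated transcripts planted to lose K27ac after knockdown
        rng = np.random.default_rng(16)
        idx = pd.Index([f"t{i}" for i in range(30)])
        hi = pd.DataFrame(rng.normal(6, 0.3, (30, 5)), index=idx, columns=list(MARKS))
        lo = hi.copy()
        lo["H3K27ac"] -= 4.0
        out = summarize_mark_changes(self.make_assignments(idx), hi, lo)
        k27 = out[out["mark"] == "H3K27ac"].iloc[0]
        assert k27["mean_log2_change"] < 0 and k27["ci_hi"] < 0

    def test_bootstrap_ci_coverage(self):
        rng = np.random.default_rng(17)
        idx = pd.Index([f"t{i}" for i in range(40)])
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            hi = pd.DataFrame(np.zeros((40, 5)), index=idx, columns=list(MARKS))
            lo = pd.DataFrame(
                rng.normal(0.7, 1.0, (40, 5)), index=idx, columns=list(MARKS)
            )
            out = summarize_mark_changes(
                self.make_assignments(idx), hi, lo, n_boot=200,
                seed=int(rng.integers(0, 2**31)),
            )
            row = out[out["mark"] == "H3K4me3"].iloc[0]
            covered += row["ci_lo"] <= 0.7 <= row["ci_hi"]
        assert covered / n_rep >= 0.90
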