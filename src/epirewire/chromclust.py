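"""Semi-supervised chromatin-based clustering of regulated transcripts.

Transcripts that respond to the oncogene are grouped into four prototype
promoter-chromatin classes using the five promoter-associated histone marks
(H3K4me3, H3K4me1, H3K27ac, H3K56ac, H3K27me3), measured in the state where
each transcript is more lowly expressed (the low state for correlated
transcripts, the high state for anticorrelated ones):

* cluster 1 — all four active marks, no H3K27me3 (fully active promoter);
* cluster 2 — H3K4me3 and H3K4me1 without the acetylation marks;
* cluster 3 — H3K4me1 only (enhancer-like / poised);
* cluster 4 — H3K27me3 present, with or without H3K4 methylation
  (Polycomb-repressed).

The procedure mechanizes an expert-in-the-loop design: unsupervised Ward
clustering seeds candidate groups, groups are matched to the qualitative
prototypes through per-mark presence calls, the matching members become a
curated training set, and an L2-regularized multinomial logistic model then
assigns every transcript a posterior over the four classes.  Calls whose
posterior is weak or close between two classes are reported "ambiguous".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "MARKS",
    "PROTOTYPES",
    "PrototypePattern",
    "binarize_marks",
    "seed_clusters",
    "curate_training",
    "fit_classifier",
    "classify",
    "cluster_transcripts",
    "summarize_mark_changes",
]

MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K56ac", "H3K27me3")


@dataclass(frozen=True)
class PrototypePattern:
    """Qualitative presence/absence signature of one promoter class."""

    cluster: int
    present: frozenset[str]
    absent: frozenset[str]

    def __post_init__(self) -> None:
        if self.present & self.absent:
            raise ValueError("present/absent mark sets overlap")

    def matches(self, presence: pd.Series) -> bool:
        return all(presence[m] for m in self.present) and not any(
            presence[m] for m in self.absent
        )


# Matching precedence: the repressive class wins whenever H3K27me3 is
# present (its H3K4 marks are explicitly don't-care), then the fully active
# class, then the two partial classes.
PROTOTYPES = (
    PrototypePattern(4, frozenset({"H3K27me3"}), frozenset({"H3K27ac", "H3K56ac"})),
    PrototypePattern(
        1, frozenset({"H3K4me3", "H3K4me1", "H3K27ac", "H3K56ac"}), frozenset({"H3K27me3"})
    ),
    PrototypePattern(2, frozenset({"H3K4me3", "H3K4me1"}), frozenset({"H3K27ac", "H3K56ac"})),
    PrototypePattern(3, frozenset({"H3K4me1"}), frozenset({"H3K4me3"})),
)


def match_prototype(presence: pd.Series) -> int | None:
    """Cluster id whose prototype the presence pattern matches, else None."""
    for proto in PROTOTYPES:
        if proto.matches(presence):
            return proto.cluster
    return None


def binarize_marks(
    vectors: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-mark presence calls from a two-component Gaussian mixture.

    Each mark's log-signal column is fit with a 1-D two-component mixture;
    presence = posterior of the upper-mean component > 0.5.  If the fit is
    degenerate (a component weight < 0.05 or means closer than 0.25) the
    mark falls back to a median split, which is logged.

    Returns (presence calls, effective threshold per mark for diagnostics).
    """
    if len(vectors) < 50:
        raise ValueError("need >= 50 transcripts for stable presence thresholds")
    calls = {}
    thresholds: dict[str, float] = {}
    for mark in vectors.columns:
        x = vectors[mark].to_numpy(dtype=float).reshape(-1, 1)
        if np.ptp(x) < 1e-12:
            logger.warning("mark %s is constant; all calls set absent", mark)
            calls[mark] = np.zeros(len(x), dtype=bool)
            thresholds[mark] = float(x[0, 0])
            continue
        gm = GaussianMixture(n_components=2, n_init=3, random_state=seed).fit(x)
        means = gm.means_.ravel()
        upper = int(np.argmax(means))
        sep = abs(means[1] - means[0])
        pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
        # degenerate: components collapsed onto one mode, or a tiny
        # component that is not actually separated from the main one; a
        # small but well-separated minority mode is a real presence class
        degenerate = sep < 0.25 or (gm.weights_.min() < 0.05 and sep < 2 * pooled_sd)
        if degenerate:
            logger.warning("degenerate mixture for %s; falling back to median split", mark)
            thr = float(np.median(x))
            calls[mark] = vectors[mark].to_numpy() > thr
            thresholds[mark] = thr
        else:
            post_upper = gm.predict_proba(x)[:, upper]
            calls[mark] = post_upper > 0.5
            # report the signal level where the posterior crosses 0.5
            grid = np.linspace(x.min(), x.max(), 512).reshape(-1, 1)
            pg = gm.predict_proba(grid)[:, upper]
            cross = np.argmax(pg > 0.5)
            thresholds[mark] = float(grid[cross, 0])
    return pd.DataFrame(calls, index=vectors.index), thresholds


def seed_clusters(vectors: pd.DataFrame, k_init: int = 8) -> pd.Series:
    """Initial unsupervised grouping: Ward linkage on z-scored mark signal.

    Deterministic given the input; the cut uses ``k_init`` groups (> 4 by
    default so that mixed groups can later be discarded rather than
    force-labeled).
    """
    if k_init < 4:
        raise ValueError("k_init must be >= 4")
    if len(vectors) < k_init:
        raise ValueError("fewer transcripts than initial clusters")
    X = _zscore(vectors.to_numpy(dtype=float))
    model = AgglomerativeClustering(n_clusters=k_init, linkage="ward")
    labels = model.fit_predict(X)
    return pd.Series(labels, index=vectors.index, name="seed_cluster")


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - mu) / sd


def curate_training(
    seed_labels: pd.Series,
    presence: pd.DataFrame,
    purity_min: float = 0.8,
) -> pd.Series:
    """Curated training labels from prototype-consistent seed groups.

    Each seed group is matched to the prototype of its majority presence
    pattern; members whose individual pattern matches that prototype become
    training examples.  Groups below ``purity_min`` agreement, or without a
    matching prototype, contribute nothing.  Raises if any prototype class
    ends up with no training examples.
    """
    member_proto = presence.apply(match_prototype, axis=1)
    train: dict[str, int] = {}
    for g in sorted(seed_labels.unique()):
        members = seed_labels.index[seed_labels == g]
        protos = member_proto.loc[members].dropna()
        if protos.empty:
            continue
        group_proto = int(protos.mode().iloc[0])
        agree = (protos == group_proto).sum() / len(members)
        if agree < purity_min:
            logger.info("seed group %s below purity %.2f; excluded", g, purity_min)
            continue
        for t in protos.index[protos == group_proto]:
            train[t] = group_proto
    labels = pd.Series(train, name="training_cluster", dtype=int)
    missing = [p.cluster for p in PROTOTYPES if p.cluster not in set(labels.values)]
    if missing:
        raise ValueError(
            f"no curated training examples for cluster(s) {missing}; "
            "lower purity_min or k_init, or supply expert labels"
        )
    return labels


@dataclass
class PromoterClassifier:
    """Fitted multinomial logistic model plus its feature standardization."""

    model: LogisticRegression
    marks: tuple[str, ...]
    feature_mean: np.ndarray
    feature_std: np.ndarray

    def posterior(self, vectors: pd.DataFrame) -> np.ndarray:
        if tuple(vectors.columns) != self.marks:
            raise ValueError(
                f"mark order mismatch: model expects {self.marks}, got {tuple(vectors.columns)}"
            )
        X = (vectors.to_numpy(dtype=float) - self.feature_mean) / self.feature_std
        probs = self.model.predict_proba(X)
        # expand to 4 columns in cluster order even if a class is missing
        out = np.zeros((len(X), 4))
        for j, cls in enumerate(self.model.classes_):
            out[:, int(cls) - 1] = probs[:, j]
        return out

    @property
    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.model.coef_, index=[f"C{int(c)}" for c in self.model.classes_],
            columns=self.marks,
        )


def fit_classifier(
    vectors: pd.DataFrame, labels: pd.Series, seed: int = 0, C: float = 1.0
) -> PromoterClassifier:
    """L2-regularized multinomial logistic regression on z-scored mark signal."""
    counts = labels.value_counts()
    too_small = counts[counts < 10]
    if not too_small.empty:
        raise ValueError(
            f"training classes with < 10 examples: {dict(too_small)}"
        )
    X_raw = vectors.loc[labels.index].to_numpy(dtype=float)
    mean = X_raw.mean(axis=0)
    std = X_raw.std(axis=0)
    std[std < 1e-12] = 1.0
    X = (X_raw - mean) / std
    model = LogisticRegression(
        C=C, max_iter=2000, random_state=seed, solver="lbfgs"
    ).fit(X, labels.to_numpy())
    return PromoterClassifier(model, tuple(vectors.columns), mean, std)


def classify(
    clf: PromoterClassifier,
    vectors: pd.DataFrame,
    p_min: float = 0.5,
    margin: float = 0.1,
) -> pd.DataFrame:
    """Posterior cluster assignment with an unambiguity rule.

    A call is unambiguous when the top posterior is at least ``p_min`` and
    exceeds the runner-up by at least ``margin``; otherwise the transcript
    is reported as "ambiguous" (its argmax cluster is still recorded in
    ``best_cluster``).
    """
    post = clf.posterior(vectors)
    order = np.argsort(-post, axis=1)
    top = post[np.arange(len(post)), order[:, 0]]
    second = post[np.arange(len(post)), order[:, 1]]
    unambiguous = (top >= p_min) & (top - second >= margin)
    best = order[:, 0] + 1
    out = pd.DataFrame(
        {
            "best_cluster": best,
            "cluster": np.where(unambiguous, best.astype(object), "ambiguous"),
            "unambiguous": unambiguous,
        },
        index=vectors.index,
    )
    for k in range(4):
        out[f"p{k + 1}"] = post[:, k]
    return out


def cluster_transcripts(
    vectors: pd.DataFrame,
    k_init: int = 8,
    purity_min: float = 0.8,
    p_min: float = 0.5,
    margin: float = 0.1,
    seed: int = 0,
    expert_labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, PromoterClassifier]:
    """End-to-end semi-supervised clustering for one direction of regulation.

    ``vectors`` holds the five-mark promoter signal (rows = transcripts) in
    the state where the transcripts are more lowly expressed.  A
    user-supplied ``expert_labels`` series (transcript -> cluster) replaces
    the automated prototype curation when given.
    """
    vectors = vectors[list(MARKS)]
    if expert_labels is not None:
        training = expert_labels.astype(int)
    else:
        presence, _ = binarize_marks(vectors, seed=seed)
        seeds = seed_clusters(vectors, k_init=k_init)
        training = curate_training(seeds, presence, purity_min=purity_min)
    clf = fit_classifier(vectors, training, seed=seed)
    assignments = classify(clf, vectors, p_min=p_min, margin=margin)
    return assignments, clf


def summarize_mark_changes(
    assignments: pd.DataFrame,
    signal_high: pd.DataFrame,
    signal_low: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster, per-mark mean log2 signal change upon knockdown.

    The change is (low-state minus high-state) log2 signal averaged over the
    unambiguous members of each cluster, with a seeded bootstrap percentile
    CI.  Empty clusters are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    delta = signal_low - signal_high  # log2 change upon knockdown
    rows = []
    for cluster in (1, 2, 3, 4):
        members = assignments.index[
            (assignments["unambiguous"]) & (assignments["best_cluster"] == cluster)
        ]
        members = members.intersection(delta.index)
        if len(members) == 0:
            logger.warning("cluster %d has no unambiguous members; omitted", cluster)
            continue
        sub = delta.loc[members]
        n = len(sub)
        boot_idx = rng.integers(0, n, size=(n_boot, n))
        for mark in sub.columns:
            vals = sub[mark].to_numpy()
            boots = vals[boot_idx].mean(axis=1)
            rows.append(
                {
                    "cluster": cluster,
                    "mark": mark,
                    "mean_log2_change": float(vals.mean()),
                    "ci_lo": float(np.percentile(boots, 2.5)),
                    "ci_hi": float(np.percentile(boots, 97.5)),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
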