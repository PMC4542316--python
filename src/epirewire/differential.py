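"""Differential calling between the oncogene-high and oncogene-low states.

The same engine is used for RNA transcript counts and for per-peak
quantified histone signal: median-of-ratios size factors, a
method-of-moments common dispersion (two replicates per state cannot
support per-feature dispersion), and a negative-binomial score test of the
state effect.  Features are labeled:

* ``correlated``     — significantly higher in the high state (fdr < alpha,
  log2fc > tau); i.e. downregulated upon oncogene knockdown;
* ``anticorrelated`` — significantly higher in the low state;
* ``unchanged``      — everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import RegionSet, overlaps_any
from .signal import ks_compare

__all__ = [
    "size_factors",
    "common_dispersion",
    "nb_score_test",
    "call_de",
    "call_diff_peaks",
    "rank_and_bin",
    "promoter_fraction_by_bin",
    "topn_binding_curve",
    "foldchange_by_binding",
]

LABELS = ("correlated", "anticorrelated", "unchanged")


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample/column).

    The reference is the per-feature geometric mean over samples, computed on
    features with all-positive counts; falls back to column-total scaling if
    fewer than 10 such features exist.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() < 10:
        totals = counts.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    sub = counts[positive]
    log_ref = np.mean(np.log(sub), axis=1)
    sf = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return sf


def common_dispersion(counts: np.ndarray, groups: np.ndarray, sf: np.ndarray) -> float:
    """Method-of-moments common NB dispersion pooled across all features.

    Within each group the NB2 model implies E[var(q)] ~ mean(1/s) * m +
    alpha * m^2 for size-factor-normalized counts q with group mean m, so
    (var - mean(1/s)*m) / m^2 is an unbiased per-feature estimate of alpha
    even at two replicates.  The common value is the pooled mean over
    adequately expressed features (a median would be biased far low: at two
    replicates the per-feature sampling distribution is chi-square-like
    with its median well under its mean).  Clipped to [1e-8, 10].
    """
    q = counts / sf[None, :]
    inv_s = float(np.mean(1.0 / sf))
    ratios = []
    for g in np.unique(groups):
        cols = groups == g
        if cols.sum() < 2:
            continue
        m = q[:, cols].mean(axis=1)
        v = q[:, cols].var(axis=1, ddof=1)
        ok = m > 5.0
        if ok.sum() < 10:
            ok = m > 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (v[ok] - m[ok] * inv_s) / m[ok] ** 2
        ratios.append(r[np.isfinite(r)])
    pooled = np.concatenate(ratios) if ratios else np.array([])
    if pooled.size == 0:
        return 1e-8
    return float(np.clip(np.mean(pooled), 1e-8, 10.0))


def nb_score_test(
    counts: np.ndarray,
    groups: np.ndarray,
    sf: np.ndarray | None = None,
    dispersion: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Vectorized NB score test of a two-group effect, one row per feature.

    Under the null of no group effect the fitted mean for sample j is
    mu_j = s_j * lambda0 with lambda0 the size-factor-weighted common rate.
    With NB2 variance mu(1 + alpha*mu) and log link, the score for the group
    coefficient is U = sum_j x_j (y_j - mu_j) w_j / mu_j with working weight
    w_j = mu_j / (1 + alpha*mu_j), and the statistic U^2 / I_adj is chi^2(1)
    after adjusting the information for the intercept.

    Returns columns: log2fc (high vs low; groups coded 1 = high), p,
    mean_high, mean_low.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    x = (groups == 1).astype(float)
    if x.sum() < 2 or (1 - x).sum() < 2:
        raise ValueError("need >= 2 replicates in each state")
    if sf is None:
        sf = size_factors(counts)
    if np.any(sf <= 0):
        raise ValueError("non-positive size factor; check library totals")
    if dispersion is None:
        dispersion = common_dispersion(counts, groups, sf)

    # null MLE of the common rate per feature: with log link the score for
    # the intercept is sum_j (y_j - mu_j)/(1 + alpha*mu_j) = 0; solve by
    # Newton from the moment estimate (exact zero makes the test invariant
    # to swapping the group coding)
    lam0 = counts.sum(axis=1) / sf.sum()
    if dispersion > 0:
        for _ in range(25):
            mu = lam0[:, None] * sf[None, :]
            denom = 1.0 + dispersion * mu
            g = np.sum((counts - mu) / denom, axis=1)
            gp = -np.sum(sf[None, :] * (1.0 + dispersion * counts) / denom**2, axis=1)
            step = np.where(gp < 0, g / gp, 0.0)
            lam0 = np.maximum(lam0 - step, 0.0)
            if np.max(np.abs(step)) < 1e-12:
                break
    mu = lam0[:, None] * sf[None, :]  # features x samples
    with np.errstate(divide="ignore", invalid="ignore"):
        w = mu / (1.0 + dispersion * mu)  # working weights
        resid = (counts - mu) / (1.0 + dispersion * mu)
    # score and intercept-adjusted information for the group coefficient
    U = np.nansum(resid * x[None, :], axis=1)
    sw = np.nansum(w, axis=1)
    swx = np.nansum(w * x[None, :], axis=1)
    info = swx - swx**2 / np.where(sw > 0, sw, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = U**2 / info
    z2 = np.where((info > 0) & np.isfinite(z2), z2, 0.0)
    p = stats.chi2.sf(z2, df=1)

    q = counts / sf[None, :]
    mean_high = q[:, x == 1].mean(axis=1)
    mean_low = q[:, x == 0].mean(axis=1)
    log2fc = np.log2(mean_high + pseudocount) - np.log2(mean_low + pseudocount)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "mean_high": mean_high, "mean_low": mean_low}
    )


def _label(fdr: np.ndarray, log2fc: np.ndarray, alpha: float, tau: float) -> np.ndarray:
    lab = np.full(len(fdr), "unchanged", dtype=object)
    sig = fdr < alpha
    lab[sig & (log2fc > tau)] = "correlated"
    lab[sig & (log2fc < -tau)] = "anticorrelated"
    return lab


def _finalize_diff_table(
    ids: pd.Index, res: pd.DataFrame, alpha: float, tau: float
) -> pd.DataFrame:
    fdr = multipletests(res["p"].to_numpy(), method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "id": ids,
            "log2fc": res["log2fc"].to_numpy(),
            "p": res["p"].to_numpy(),
            "fdr": fdr,
            "label": _label(fdr, res["log2fc"].to_numpy(), alpha, tau),
        }
    )
    out["magnitude"] = out["log2fc"].abs()
    return out


def call_de(
    counts: pd.DataFrame,
    state_of: dict[str, str] | None = None,
    alpha: float = 0.05,
    tau: float = 1.0,
) -> pd.DataFrame:
    """Differential transcript calling between the two states.

    ``counts`` is transcripts x samples; sample-to-state assignment comes
    from ``state_of`` (column -> "high"/"low") or, by default, from column
    names of the form ``high_rep1`` / ``low_rep2``.
    """
    if state_of is None:
        state_of = {c: str(c).split("_")[0] for c in counts.columns}
    states = np.array([state_of[c] for c in counts.columns])
    if not set(states) == {"high", "low"}:
        raise ValueError("both 'high' and 'low' states are required")
    groups = (states == "high").astype(int)
    res = nb_score_test(counts.to_numpy(), groups)
    return _finalize_diff_table(counts.index, res, alpha, tau)


def call_diff_peaks(
    peak_signal: pd.DataFrame,
    mark: str = "H3K27ac",
    alpha: float = 0.05,
    tau: float = 1.0,
) -> pd.DataFrame:
    """Differential peak calling on quantified (raw, un-logged) peak signal.

    ``peak_signal`` is peaks x (mark, state, replicate); the selected mark's
    raw signal integrals are count-like and go through the same NB engine as
    the RNA counts.  "correlated" = higher signal in the high state.
    """
    if isinstance(peak_signal.columns, pd.MultiIndex) and peak_signal.columns.nlevels == 3:
        sub = peak_signal[mark]  # (mark, state, replicate) columns
    else:
        sub = peak_signal  # already (state, replicate) columns
    cols = list(sub.columns)  # (state, replicate) tuples
    states = np.array([c[0] if isinstance(c, tuple) else str(c).split("_")[0] for c in cols])
    if set(states) != {"high", "low"}:
        raise ValueError("peak signal must cover both states")
    for s in ("high", "low"):
        if (states == s).sum() < 2:
            raise ValueError(f"state {s!r} needs >= 2 replicates")
    groups = (states == "high").astype(int)
    res = nb_score_test(sub.to_numpy(), groups)
    return _finalize_diff_table(sub.index, res, alpha, tau)


@dataclass
class RankedPeakBins:
    """Significant peaks ranked by |log2fc| (descending) and cut into bins."""

    table: pd.DataFrame  # columns: id, log2fc, magnitude, p, rank, bin
    q: int

    @property
    def ranked_ids(self) -> list[str]:
        return list(self.table["id"])

    def bin_ids(self, b: int) -> list[str]:
        return list(self.table.loc[self.table["bin"] == b, "id"])


def rank_and_bin(diff: pd.DataFrame, q: int = 5, significant_only: bool = True) -> RankedPeakBins:
    """Rank peaks by magnitude of change and split into q near-equal bins.

    Bin 1 holds the most differential peaks.  Ties in magnitude break by
    smaller p, then id.  Bin sizes differ by at most one.
    """
    t = diff[diff["label"] != "unchanged"] if significant_only else diff
    if len(t) < q:
        raise ValueError(f"only {len(t)} peaks for {q} bins")
    t = t.sort_values(
        ["magnitude", "p", "id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    bins = np.concatenate([np.full(len(part), i + 1) for i, part in enumerate(np.array_split(np.arange(len(t)), q))])
    t["bin"] = bins
    return RankedPeakBins(t[["id", "log2fc", "magnitude", "p", "rank", "bin"]], q)


def promoter_fraction_by_bin(
    bins: RankedPeakBins, peaks: RegionSet, promoters: RegionSet
) -> pd.Series:
    """Per-bin fraction of peaks overlapping promoter windows (>= 1 bp)."""
    id_to_region = dict(zip(peaks.ids, peaks.regions))
    hit = overlaps_any(
        RegionSet("ranked", [id_to_region[i] for i in bins.ranked_ids], peaks.genome),
        promoters,
    )
    df = pd.DataFrame({"bin": bins.table["bin"].to_numpy(), "hit": hit})
    frac = df.groupby("bin")["hit"].mean()
    if (df.groupby("bin").size() == 0).any():
        raise ValueError("empty bin")
    frac.name = "promoter_fraction"
    return frac


def topn_binding_curve(
    bins: RankedPeakBins,
    peaks: RegionSet,
    tf: RegionSet,
    n_grid: list[int] | None = None,
) -> pd.DataFrame:
    """Fraction of the top-N ranked peaks overlapping TF binding sites.

    The curve is cumulative: its value at N = total peak count equals the
    overall overlap fraction.  N values beyond the ranking are dropped with
    a warning.
    """
    ids = bins.ranked_ids
    if n_grid is None:
        n_grid = sorted(
            {n for n in (10, 25, 50, 100, 250, 500, 1000, 2000, 5000) if n <= len(ids)}
            | {len(ids)}
        )
    kept = [n for n in n_grid if n <= len(ids)]
    if len(kept) < len(n_grid):
        warnings.warn("N values beyond the number of ranked peaks were truncated")
    id_to_region = dict(zip(peaks.ids, peaks.regions))
    hit = overlaps_any(
        RegionSet("ranked", [id_to_region[i] for i in ids], peaks.genome), tf
    ).astype(float)
    cum = np.cumsum(hit)
    return pd.DataFrame(
        {"N": kept, "fraction": [cum[n - 1] / n for n in kept]}
    )


def foldchange_by_binding(
    diff: pd.DataFrame, peaks: RegionSet, tf: RegionSet
) -> dict:
    """Split per-peak log2 fold changes by TF binding and compare with KS.

    Returns bound/unbound fold-change arrays plus the KS statistic and p.
    """
    bound_mask = overlaps_any(peaks, tf)
    by_id = dict(zip(peaks.ids, bound_mask))
    is_bound = diff["id"].map(by_id).to_numpy(dtype=bool)
    bound = diff.loc[is_bound, "log2fc"].to_numpy()
    unbound = diff.loc[~is_bound, "log2fc"].to_numpy()
    if len(bound) < 5 or len(unbound) < 5:
        raise ValueError("need >= 5 bound and >= 5 unbound peaks")
    d, p = ks_compare(bound, unbound)
    return {"bound": bound, "unbound": unbound, "ks_D": d, "ks_p": p}
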