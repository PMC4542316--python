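"""Signal quantification over regions, TSS composite profiles, and
methylation summaries.

Coverage arrives as bedGraph-style interval records (chrom, start, end,
value).  Quantification integrates the piecewise-constant coverage function
over target regions using prefix sums, normalizes to signal-per-million per
kilobase, and applies a log2(x+1) transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicRegion, RegionSet, TSSAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "CompositeProfile",
    "read_bedgraph",
    "tile_genome",
    "quantify_regions",
    "build_signal_matrix",
    "composite_profile",
    "stratify_by_expression",
    "read_methylation",
    "methylation_at_regions",
    "ks_compare",
]


@dataclass
class CoverageTrack:
    """Interval coverage for one (mark, state, replicate) combination.

    Per-chromosome arrays are sorted and non-overlapping; ``library_size``
    defaults to the total signal mass (sum of value x width over the track),
    the denominator for per-million normalization.
    """

    mark: str
    state: str
    replicate: int
    chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # starts, ends, values
    library_size: float = 0.0

    def __post_init__(self) -> None:
        total = 0.0
        for c, (starts, ends, values) in self.chroms.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"empty/inverted coverage interval on {c}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"coverage intervals overlap or are unsorted on {c}")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"coverage values must be finite and >= 0 on {c}")
            self.chroms[c] = (starts, ends, values)
            total += float(np.sum(values * (ends - starts)))
        if self.library_size <= 0:
            self.library_size = total
        # prefix integral of value*width, for O(log n) region sums
        self._cum = {
            c: np.concatenate(([0.0], np.cumsum(v * (e - s))))
            for c, (s, e, v) in self.chroms.items()
        }

    def region_raw_signal(self, chrom: str, start: int, end: int) -> float:
        """Integral of coverage over [start, end) (value x overlap bp)."""
        if chrom not in self.chroms:
            return 0.0
        starts, ends, values = self.chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        cum = self._cum[chrom]
        total = float(cum[hi] - cum[lo])
        # trim partial overlap at both edges
        total -= float(values[lo]) * max(0, start - int(starts[lo]))
        total -= float(values[hi - 1]) * max(0, int(ends[hi - 1]) - end)
        return total

    def binned_means(self, chrom: str, start: int, end: int, nbins: int) -> np.ndarray:
        """Mean coverage in ``nbins`` equal bins over [start, end).

        Bins falling outside the chromosome contribute zeros.
        """
        width = (end - start) / nbins
        out = np.empty(nbins)
        for b in range(nbins):
            s = int(round(start + b * width))
            e = int(round(start + (b + 1) * width))
            e = max(e, s + 1)
            out[b] = self.region_raw_signal(chrom, max(0, s), max(0, e)) / (e - s)
        return out


def read_bedgraph(
    path: str | Path, mark: str, state: str, replicate: int
) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        chroms[str(c)] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["value"].to_numpy(),
        )
    return CoverageTrack(mark, state, replicate, chroms)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(track.chroms):
            starts, ends, values = track.chroms[c]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{c}\t{s}\t{e}\t{v:.10g}\n")


def tile_genome(genome: Mapping[str, int], width: int = 1000) -> RegionSet:
    """Consecutive non-overlapping windows covering every chromosome.

    The last window on each chromosome is truncated at the chromosome end.
    """
    if width <= 0:
        raise ValueError(f"tile width must be positive, got {width}")
    regions: list[GenomicRegion] = []
    for chrom, length in genome.items():
        for i, start in enumerate(range(0, length, width)):
            regions.append(
                GenomicRegion(chrom, start, min(start + width, length), ".", f"{chrom}_tile{i}")
            )
    return RegionSet("tiles", regions, genome)


def quantify_regions(
    track: CoverageTrack, regions: RegionSet, log: bool = True, normalize: bool = True
) -> np.ndarray:
    """Normalized signal per region.

    raw = integral of coverage over the region (value x overlap bp);
    normalized = raw * 1e6 / library_size / region_length_kb;
    log2(x + 1) applied when ``log`` is true.  ``normalize=False`` returns
    the raw count-like integrals (used by the differential engine).
    Regions on chromosomes absent from the track get 0 with a warning.
    """
    missing = sorted({r.chrom for r in regions} - set(track.chroms))
    if missing:
        logger.warning(
            "track %s/%s/r%d lacks chromosomes %s; affected regions get 0",
            track.mark, track.state, track.replicate, ",".join(missing),
        )
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        raw = track.region_raw_signal(r.chrom, r.start, r.end)
        if normalize:
            length_kb = (r.end - r.start) / 1000.0
            out[i] = raw * 1e6 / track.library_size / length_kb
        else:
            out[i] = raw
    if log:
        out = np.log2(out + 1.0)
    return out


def build_signal_matrix(
    tracks: Sequence[CoverageTrack], regions: RegionSet, log: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Region x (mark, state, replicate) matrix of normalized signal."""
    cols = {}
    for t in tracks:
        cols[(t.mark, t.state, t.replicate)] = quantify_regions(
            t, regions, log=log, normalize=normalize
        )
    df = pd.DataFrame(cols, index=pd.Index(regions.ids, name="id"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["mark", "state", "replicate"])
    return df


def average_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse the replicate level by the mean, keeping (mark, state)."""
    return matrix.T.groupby(level=["mark", "state"]).mean().T


@dataclass
class CompositeProfile:
    """Average signal in fixed bins around aligned anchors, per stratum."""

    mark: str
    stratum: str
    offsets: np.ndarray  # bin-center offsets in bp relative to the anchor
    mean_signal: np.ndarray
    n_anchors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_signal": self.mean_signal,
             "mark": self.mark, "stratum": self.stratum}
        )


def composite_profile(
    track: CoverageTrack,
    anchors: Sequence[TSSAnnotation],
    flank: int = 5000,
    bin_width: int = 100,
    strata: Sequence[str] | None = None,
) -> dict[str, CompositeProfile]:
    """TSS composite (metagene) profile: mean binned signal around anchors.

    Signal for "-" anchors is flipped so positive offsets always point
    downstream of transcription.  One profile per stratum label; empty
    strata are omitted with a warning.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin width")
    if strata is None:
        strata = ["all"] * len(anchors)
    if len(strata) != len(anchors):
        raise ValueError("one stratum label per anchor required")
    nbins = 2 * flank // bin_width
    offsets = np.arange(-flank, flank, bin_width) + bin_width / 2.0
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for anchor, label in zip(anchors, strata):
        prof = track.binned_means(anchor.chrom, anchor.tss - flank, anchor.tss + flank, nbins)
        if anchor.strand == "-":
            prof = prof[::-1]
        sums[label] = sums.get(label, np.zeros(nbins)) + prof
        counts[label] = counts.get(label, 0) + 1
    out: dict[str, CompositeProfile] = {}
    for label in dict.fromkeys(strata):
        if counts.get(label, 0) == 0:
            warnings.warn(f"stratum {label!r} has no anchors; omitted")
            continue
        out[label] = CompositeProfile(
            track.mark, label, offsets, sums[label] / counts[label], counts[label]
        )
    return out


def stratify_by_expression(expr: pd.Series) -> pd.Series:
    """Label genes high / moderate / low by expression rank.

    high = top 20%, moderate = (20%, 80%], low = bottom 10%; the (80%, 90%]
    band is labeled "unassigned" (the three named strata deliberately do not
    tile the distribution).  Ties are broken by stable input order.
    """
    if len(expr) < 10:
        raise ValueError("need at least 10 genes to stratify")
    n = len(expr)
    # rank 0 = highest expression; mergesort keeps input order on ties
    order = np.argsort(-expr.to_numpy(), kind="mergesort")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    frac_from_top = (rank + 1) / n
    labels = np.where(
        frac_from_top <= 0.20, "high",
        np.where(frac_from_top <= 0.80, "moderate",
                 np.where(frac_from_top <= 0.90, "unassigned", "low")),
    )
    return pd.Series(labels, index=expr.index, name="expression_stratum")


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read CpG-level methylation calls (chrom, pos, meth_reads, total_reads)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "meth_reads", "total_reads"}
    if not required.issubset(df.columns):
        raise ValueError(f"methylation table needs columns {sorted(required)}")
    if (df["total_reads"] < 1).any() or (df["meth_reads"] > df["total_reads"]).any():
        raise ValueError("invalid read counts in methylation table")
    df = df.copy()
    df["beta"] = df["meth_reads"] / df["total_reads"]
    return df


def methylation_at_regions(
    meth: pd.DataFrame, regions: RegionSet, min_cpgs: int = 3
) -> pd.Series:
    """Unweighted mean CpG beta per region; regions with < min_cpgs CpGs drop out."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    if "beta" not in meth.columns:
        meth = meth.assign(beta=meth["meth_reads"] / meth["total_reads"])
    by_chrom = {
        str(c): (grp["pos"].to_numpy(), grp["beta"].to_numpy())
        for c, grp in meth.sort_values(["chrom", "pos"]).groupby("chrom")
    }
    means: dict[str, float] = {}
    for rid, r in zip(regions.ids, regions):
        if r.chrom not in by_chrom:
            continue
        pos, beta = by_chrom[r.chrom]
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")
        if hi - lo >= min_cpgs:
            means[rid] = float(np.mean(beta[lo:hi]))
    return pd.Series(means, name="mean_beta")


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (D, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample needs n >= 5 for the KS comparison")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
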