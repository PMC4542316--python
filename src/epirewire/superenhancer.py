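"""Super-enhancer annotation from H3K27ac peaks and signal.

Peaks within a stitching distance (default 12.5 kb) are merged into
stitched enhancers, ranked by total normalized H3K27ac signal in the
oncogene-high state, and split at the hockey-stick cutoff: on the curve of
rank-sorted signal with both axes rescaled to [0, 1], the cutoff sits at
the tangent point where the curve's slope reaches 1 — geometrically the
point lying farthest below the diagonal.  Everything above the cutoff is a
super-enhancer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import (
    GenomicRegion,
    RegionSet,
    TSSAnnotation,
    overlaps_any,
    promoter_window,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StitchedEnhancer",
    "SECallSet",
    "stitch",
    "hockey_cutoff",
    "assign_nearest_gene",
    "call_superenhancers",
    "se_dynamics",
]


@dataclass
class StitchedEnhancer:
    region: GenomicRegion
    member_ids: list[str]
    total_signal: float = 0.0
    rank: int = 0  # 1 = highest total signal
    is_super: bool = False
    gene_id: str | None = None


@dataclass
class SECallSet:
    """All stitched enhancers plus the hockey-stick cutoff and summaries."""

    enhancers: list[StitchedEnhancer]
    cutoff: float

    @property
    def supers(self) -> list[StitchedEnhancer]:
        return [e for e in self.enhancers if e.is_super]

    @property
    def typicals(self) -> list[StitchedEnhancer]:
        return [e for e in self.enhancers if not e.is_super]

    def summary(self) -> dict:
        sup = self.supers
        typ = self.typicals
        return {
            "n_super": len(sup),
            "n_typical": len(typ),
            "cutoff": self.cutoff,
            "median_super_length": float(np.median([len(e.region) for e in sup])) if sup else float("nan"),
            "median_typical_length": float(np.median([len(e.region) for e in typ])) if typ else float("nan"),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [e.region.chrom for e in self.enhancers],
                "start": [e.region.start for e in self.enhancers],
                "end": [e.region.end for e in self.enhancers],
                "id": [e.region.id for e in self.enhancers],
                "n_peaks": [len(e.member_ids) for e in self.enhancers],
                "total_signal": [e.total_signal for e in self.enhancers],
                "rank": [e.rank for e in self.enhancers],
                "is_super": [e.is_super for e in self.enhancers],
                "gene_id": [e.gene_id for e in self.enhancers],
                "member_ids": [",".join(e.member_ids) for e in self.enhancers],
            }
        )


def stitch(
    peaks: RegionSet,
    stitch_bp: int = 12500,
    tss_exclude: RegionSet | None = None,
) -> list[StitchedEnhancer]:
    """Merge peaks whose gaps are <= ``stitch_bp`` into stitched enhancers.

    Merging is transitive per chromosome.  When ``tss_exclude`` is given,
    peaks fully contained in an exclusion window are removed before
    stitching.
    """
    if stitch_bp < 0:
        raise ValueError("stitch distance must be non-negative")
    kept = list(zip(peaks.ids, peaks.regions))
    if tss_exclude is not None:
        excl = tss_exclude._sorted_index()
        def contained(r: GenomicRegion) -> bool:
            if r.chrom not in excl:
                return False
            for w in tss_exclude:
                if w.chrom == r.chrom and w.start <= r.start and r.end <= w.end:
                    return True
            return False
        kept = [(i, r) for i, r in kept if not contained(r)]
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for rid, r in kept:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, rid))
    out: list[StitchedEnhancer] = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0][0], ivs[0][1]
        cur_members = [ivs[0][2]]
        for s, e, rid in ivs[1:]:
            if s - cur_e <= stitch_bp:  # gap (possibly negative) within range
                cur_e = max(cur_e, e)
                cur_members.append(rid)
            else:
                out.append(
                    StitchedEnhancer(
                        GenomicRegion(c, cur_s, cur_e, ".", f"stitched_{len(out)}"),
                        cur_members,
                    )
                )
                cur_s, cur_e, cur_members = s, e, [rid]
        out.append(
            StitchedEnhancer(
                GenomicRegion(c, cur_s, cur_e, ".", f"stitched_{len(out)}"), cur_members
            )
        )
    return out


def hockey_cutoff(signals: Sequence[float]) -> float:
    """Hockey-stick signal cutoff separating super- from typical enhancers.

    Signals are sorted ascending; ranks and signals are each rescaled to
    [0, 1].  The cutoff is the signal at the point farthest *below* the
    diagonal (minimum of scaled signal minus scaled rank) — for a convex
    rank-signal profile this is the point where the tangent slope reaches
    1, the standard geometric rule.  Ties take the highest rank, so a
    profile with no elbow (e.g. a linear ramp) yields a cutoff at the
    maximum and no super-enhancers.  Enhancers with signal strictly above
    the cutoff are super.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 10:
        raise ValueError("need >= 10 stitched enhancers for a cutoff")
    if s[-1] - s[0] < 1e-12:
        warnings.warn("constant stitched signal; cutoff set to the maximum")
        return float(s[-1])
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    gap = y - x
    # argmin with ties (within float tolerance) resolved to the highest rank,
    # so an elbow-free profile (gap ~ 0 everywhere) cuts at the maximum
    ties = np.flatnonzero(gap <= gap.min() + 1e-9)
    best = int(ties[-1])
    return float(s[best])


def assign_nearest_gene(
    enhancers: Sequence[StitchedEnhancer], tss_list: Sequence[TSSAnnotation]
) -> None:
    """Annotate each stitched enhancer with its nearest gene (in place).

    Distance 0 when a TSS falls inside the enhancer; ties break toward the
    smaller TSS coordinate.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    from .regions import nearest_tss_distance

    genome: dict[str, int] = {}
    for e in enhancers:
        genome[e.region.chrom] = max(genome.get(e.region.chrom, 0), e.region.end)
    for t in tss_list:
        genome[t.chrom] = max(genome.get(t.chrom, 0), t.tss + 1)
    rs = RegionSet("stitched", [e.region for e in enhancers], genome)
    _, genes = nearest_tss_distance(rs, tss_list)
    for e, g in zip(enhancers, genes):
        e.gene_id = g


def call_superenhancers(
    peaks: RegionSet,
    peak_signal: Mapping[str, float],
    stitch_bp: int = 12500,
    tss_exclude: RegionSet | None = None,
    tss_list: Sequence[TSSAnnotation] | None = None,
) -> SECallSet:
    """Full ROSE-style call: stitch, rank by total signal, apply the cutoff.

    ``peak_signal`` maps peak id to normalized signal in the high state; a
    stitched enhancer's signal is the sum over its member peaks.
    """
    enhancers = stitch(peaks, stitch_bp=stitch_bp, tss_exclude=tss_exclude)
    for e in enhancers:
        e.total_signal = float(sum(peak_signal.get(m, 0.0) for m in e.member_ids))
    cutoff = hockey_cutoff([e.total_signal for e in enhancers])
    for rank, e in enumerate(
        sorted(enhancers, key=lambda e: -e.total_signal), start=1
    ):
        e.rank = rank
        e.is_super = e.total_signal > cutoff
    if tss_list:
        assign_nearest_gene(enhancers, tss_list)
    return SECallSet(enhancers, cutoff)


def se_dynamics(
    calls: SECallSet,
    diff_peaks: pd.DataFrame,
    peaks: RegionSet,
    tf: RegionSet,
    widespread_min: float = 0.75,
) -> pd.DataFrame:
    """Knockdown response class per super-enhancer.

    A super-enhancer shows *widespread loss* when at least ``widespread_min``
    of its member peaks are correlated (lose acetylation upon knockdown),
    a *localized change* when at least one but fewer than that fraction are,
    and is *stable* otherwise.  ``tf_bound`` flags any member peak
    overlapping a TF binding site.
    """
    label_of = dict(zip(diff_peaks["id"], diff_peaks["label"]))
    bound = dict(zip(peaks.ids, overlaps_any(peaks, tf)))
    rows = []
    for e in calls.supers:
        assert e.member_ids, "stitched enhancer without member peaks"
        labels = [label_of.get(m, "unchanged") for m in e.member_ids]
        frac_corr = sum(l == "correlated" for l in labels) / len(labels)
        if frac_corr >= widespread_min:
            cls = "widespread_loss"
        elif frac_corr > 0:
            cls = "localized_change"
        else:
            cls = "stable"
        rows.append(
            {
                "se_id": e.region.id,
                "n_peaks": len(e.member_ids),
                "fraction_correlated": frac_corr,
                "tf_bound": bool(any(bound.get(m, False) for m in e.member_ids)),
                "dynamics": cls,
                "gene_id": e.gene_id,
            }
        )
    return pd.DataFrame(rows)
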