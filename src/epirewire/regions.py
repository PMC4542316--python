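"""Genomic interval model and BED I/O.

All coordinates are 0-based, half-open (``[start, end)``), the native BED
convention; every other module builds on the types and overlap/nearest
queries defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "TSSAnnotation",
    "read_bed",
    "read_chrom_sizes",
    "read_tss_bed",
    "count_overlaps",
    "overlaps_any",
    "nearest_tss_distance",
    "nearest_region_distance",
    "assign_distance_bin",
    "promoter_window",
    "merge_regions",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A strand-aware half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive; ``end > start``
    is enforced.  ``score`` is optional and carried through BED round trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for region {self.id}: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start for region {self.id}: "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class TSSAnnotation:
    """A transcription start site: a single stranded base position."""

    gene_id: str
    transcript_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS position {self.tss}")


class RegionSet:
    """A named, ordered collection of regions tied to a chromosome-sizes map.

    Regions keep their input order; per-chromosome sorted coordinate arrays
    are built lazily for overlap and nearest-feature queries.
    """

    def __init__(
        self,
        name: str,
        regions: Iterable[GenomicRegion],
        genome: Mapping[str, int],
    ) -> None:
        self.name = name
        self.regions: list[GenomicRegion] = list(regions)
        self.genome = dict(genome)
        seen: set[str] = set()
        for r in self.regions:
            if r.chrom not in self.genome:
                raise ValueError(
                    f"region {r.id} on {r.chrom!r} absent from genome map"
                )
            if r.end > self.genome[r.chrom]:
                raise ValueError(
                    f"region {r.id} extends past end of {r.chrom} "
                    f"({r.end} > {self.genome[r.chrom]})"
                )
            if r.id is not None:
                if r.id in seen:
                    raise ValueError(f"duplicate region id {r.id!r} in set {name!r}")
                seen.add(r.id)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    @property
    def ids(self) -> list[str]:
        return [r.id or f"{self.name}_{i}" for i, r in enumerate(self.regions)]

    def _sorted_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted starts, sorted ends) arrays.

        The two arrays are sorted independently; this supports the standard
        counting identity ``#overlapping [s,e) = #(start < e) - #(end <= s)``
        which holds for any interval collection.
        """
        if self._index is None:
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for r in self.regions:
                idx.setdefault(r.chrom, ([], []))
                idx[r.chrom][0].append(r.start)
                idx[r.chrom][1].append(r.end)
            self._index = {
                c: (np.sort(np.asarray(s, dtype=np.int64)),
                    np.sort(np.asarray(e, dtype=np.int64)))
                for c, (s, e) in idx.items()
            }
        return self._index

    def subset(self, keep: Sequence[bool] | np.ndarray, name: str | None = None) -> "RegionSet":
        keep = np.asarray(keep, dtype=bool)
        if len(keep) != len(self.regions):
            raise ValueError("mask length mismatch")
        return RegionSet(
            name or self.name,
            [r for r, k in zip(self.regions, keep) if k],
            self.genome,
        )

    def to_bed(self, path: str | Path) -> None:
        write_bed(self, path)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom-sizes TSV into an ordered mapping."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            genome[parts[0]] = int(parts[1])
    return genome


def read_bed(path: str | Path, name: str, genome: Mapping[str, int]) -> RegionSet:
    """Read a BED3+ file (columns 4-6 optional: name, score, strand).

    Missing strand becomes ``.``; missing names become ``<name>_<index>``.
    Malformed lines raise ``ValueError`` naming the offending line number.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            rid = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else f"{name}_{len(regions)}"
            score: float | None = None
            if len(parts) > 4 and parts[4] not in ("", "."):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in VALID_STRANDS else "."
            regions.append(GenomicRegion(parts[0], start, end, strand, rid, score))
    return RegionSet(name, regions, genome)


def write_bed(regions: RegionSet | Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED6 (score blank written as 0)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            rid = r.id or f"region_{i}"
            score = 0.0 if r.score is None else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{rid}\t{score:g}\t{r.strand}\n")


def read_tss_bed(path: str | Path) -> list[TSSAnnotation]:
    """Read TSS annotation from a BED6-like file.

    The interval is a single base at the TSS; column 4 holds
    ``gene_id|transcript_id`` (or a bare id used for both).
    """
    out: list[TSSAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: TSS BED needs 6 columns")
            ident = parts[3]
            gene_id, _, tx_id = ident.partition("|")
            out.append(
                TSSAnnotation(gene_id, tx_id or gene_id, parts[0], int(parts[1]), parts[5])
            )
    return out


def write_tss_bed(tss_list: Sequence[TSSAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tss_list:
            fh.write(
                f"{t.chrom}\t{t.tss}\t{t.tss + 1}\t{t.gene_id}|{t.transcript_id}\t0\t{t.strand}\n"
            )


def _check_same_genome(a: RegionSet, b: RegionSet) -> None:
    for c in set(r.chrom for r in a) | set(r.chrom for r in b):
        if c not in a.genome or c not in b.genome:
            raise ValueError(f"chromosome {c!r} missing from one genome map")


def count_overlaps(query: RegionSet, subject: RegionSet) -> np.ndarray:
    """Number of subject regions overlapping each query region (>= 1 bp)."""
    _check_same_genome(query, subject)
    idx = subject._sorted_index()
    counts = np.zeros(len(query), dtype=np.int64)
    for i, r in enumerate(query):
        if r.chrom not in idx:
            continue
        starts, ends = idx[r.chrom]
        counts[i] = np.searchsorted(starts, r.end, side="left") - np.searchsorted(
            ends, r.start, side="right"
        )
    return counts


def overlaps_any(query: RegionSet, subject: RegionSet) -> np.ndarray:
    """Boolean per-query: does it overlap at least one subject region."""
    return count_overlaps(query, subject) > 0


def _point_to_interval_distance(point: int, start: int, end: int) -> int:
    """Unsigned distance from a base position to a half-open interval.

    Zero inside the interval; otherwise the gap to the nearest covered base
    (``end - 1`` on the right side).
    """
    if start <= point < end:
        return 0
    if point < start:
        return start - point
    return point - (end - 1)


def nearest_tss_distance(
    peaks: RegionSet, tss_list: Sequence[TSSAnnotation]
) -> tuple[np.ndarray, list[str | None]]:
    """Per-peak distance to the nearest TSS and that TSS's gene id.

    Distance is unsigned and measured from the TSS base to the nearest peak
    base.  Peaks on chromosomes with no TSS get ``inf`` and gene ``None``.
    Ties are broken by smaller TSS coordinate.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for c in set(t.chrom for t in tss_list):
        pairs = sorted(
            ((t.tss, t.gene_id) for t in tss_list if t.chrom == c),
            key=lambda p: p[0],
        )
        by_chrom[c] = (np.asarray([p[0] for p in pairs], dtype=np.int64), [p[1] for p in pairs])
    dists = np.full(len(peaks), np.inf)
    genes: list[str | None] = [None] * len(peaks)
    for i, r in enumerate(peaks):
        if r.chrom not in by_chrom:
            continue
        pos, ids = by_chrom[r.chrom]
        lo = int(np.searchsorted(pos, r.start, side="left"))
        hi = int(np.searchsorted(pos, r.end, side="left"))
        if hi > lo:  # at least one TSS inside the peak
            dists[i] = 0.0
            genes[i] = ids[lo]
            continue
        best_d, best_j = math.inf, -1
        if lo - 1 >= 0:  # nearest TSS left of the peak
            best_d, best_j = r.start - int(pos[lo - 1]), lo - 1
        if lo < len(pos):  # nearest TSS right of the peak
            d = int(pos[lo]) - (r.end - 1)
            if d < best_d:  # on ties keep the smaller (left) coordinate
                best_d, best_j = d, lo
        dists[i] = best_d
        genes[i] = ids[best_j] if best_j >= 0 else None
    return dists, genes


def nearest_region_distance(
    tss_list: Sequence[TSSAnnotation], regions: RegionSet
) -> np.ndarray:
    """Per-TSS unsigned distance to the nearest region (symmetric query).

    TSS on chromosomes without regions get ``inf``.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in set(r.chrom for r in regions):
        rs = sorted((r.start, r.end) for r in regions if r.chrom == c)
        by_chrom[c] = (
            np.asarray([p[0] for p in rs], dtype=np.int64),
            np.asarray([p[1] for p in rs], dtype=np.int64),
        )
    # prefix max of ends (by start order) answers left-side queries exactly:
    # among intervals starting at or before the point, the one with the
    # largest end is nearest (covers the point or ends closest to it)
    prefix: dict[str, np.ndarray] = {
        c: np.maximum.accumulate(e) for c, (_, e) in by_chrom.items()
    }
    out = np.full(len(tss_list), np.inf)
    for i, t in enumerate(tss_list):
        if t.chrom not in by_chrom:
            continue
        starts, _ = by_chrom[t.chrom]
        pmax = prefix[t.chrom]
        j = int(np.searchsorted(starts, t.tss, side="right"))
        best = math.inf
        if j > 0:
            max_end = int(pmax[j - 1])
            best = 0 if max_end > t.tss else t.tss - (max_end - 1)
        if j < len(starts):
            best = min(best, int(starts[j]) - t.tss)
        out[i] = best
    return out


def assign_distance_bin(distance_bp: float) -> str:
    """Bin a TSS-to-peak distance: proximal (<5 kb), distal (5-40 kb), none (>40 kb)."""
    if distance_bp < 0:
        raise ValueError(f"negative distance {distance_bp}")
    if distance_bp < 5000:
        return "proximal"
    if distance_bp <= 40000:
        return "distal"
    return "none"


def promoter_window(
    tss: TSSAnnotation,
    upstream_bp: int,
    downstream_bp: int,
    genome: Mapping[str, int],
) -> GenomicRegion:
    """Strand-aware promoter window around a TSS, clipped to the chromosome.

    For "+" the window is ``[tss - up, tss + down)``; for "-" it mirrors to
    ``[tss - down, tss + up)`` so "upstream" follows transcription direction.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be non-negative")
    if upstream_bp == 0 and downstream_bp == 0:
        raise ValueError("empty promoter window")
    chrom_len = genome[tss.chrom]
    if not (0 <= tss.tss < chrom_len):
        raise ValueError(f"TSS {tss.transcript_id} off chromosome {tss.chrom}")
    if tss.strand == "+":
        start, end = tss.tss - upstream_bp, tss.tss + downstream_bp
    else:
        start, end = tss.tss - downstream_bp, tss.tss + upstream_bp
    start, end = max(0, start), min(chrom_len, end)
    if end <= start:  # fully clipped away; keep a 1-bp stub at the boundary
        start, end = max(0, end - 1), max(1, end)
    return GenomicRegion(tss.chrom, start, end, tss.strand, tss.transcript_id)


def promoter_regions(
    tss_list: Sequence[TSSAnnotation],
    genome: Mapping[str, int],
    upstream_bp: int = 2000,
    downstream_bp: int = 0,
    name: str = "promoters",
) -> RegionSet:
    """Promoter windows for a TSS list as a RegionSet (ids = transcript ids)."""
    return RegionSet(
        name,
        [promoter_window(t, upstream_bp, downstream_bp, genome) for t in tss_list],
        genome,
    )


def merge_regions(
    regions: Iterable[GenomicRegion],
    genome: Mapping[str, int],
    name: str = "merged",
    min_gap: int = 0,
) -> RegionSet:
    """Merge intervals that overlap or sit within ``min_gap`` bp of each other.

    With the default ``min_gap=0`` only >=1 bp overlaps merge: abutting
    half-open intervals such as [0,10) and [10,20) share no base and stay
    separate.  With ``min_gap=g > 0`` a gap of up to g bp is bridged
    (abutting intervals have gap 0 and merge).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged: list[GenomicRegion] = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e or (min_gap > 0 and s - cur_e <= min_gap):
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicRegion(c, cur_s, cur_e, ".", f"{name}_{len(merged)}"))
                cur_s, cur_e = s, e
        merged.append(GenomicRegion(c, cur_s, cur_e, ".", f"{name}_{len(merged)}"))
    return RegionSet(name, merged, genome)
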