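"""Region-set and gene-set overlap enrichment (location overlap analysis).

A query region set is tested against every set in a region database via a
2x2 Fisher's exact test over a *universe* of countable genomic units: for
each database set, a = universe units overlapping both query and set,
b = query only, c = set only, d = neither.  Odds ratios use a
Haldane-Anscombe +0.5 correction when a cell is zero (the correction never
touches the p-value).  Gene-set enrichment applies the same machinery to
gene memberships, including the three background schemes used for the
promoter clusters.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import RegionSet, merge_regions, overlaps_any

logger = logging.getLogger(__name__)

__all__ = [
    "RegionDatabase",
    "build_universe",
    "region_enrichment",
    "gene_set_enrichment",
    "run_background_schemes",
    "read_gmt",
    "fisher_table",
]


class RegionDatabase:
    """Named collection of region sets sharing one genome map."""

    def __init__(self, sets: Mapping[str, RegionSet]):
        if not sets:
            raise ValueError("empty region database")
        names = list(sets)
        if len(set(names)) != len(names):
            raise ValueError("duplicate database set names")
        self.sets = dict(sets)

    @classmethod
    def from_directory(cls, directory: str | Path, genome: Mapping[str, int]) -> "RegionDatabase":
        from .regions import read_bed

        directory = Path(directory)
        sets = {
            p.stem: read_bed(p, p.stem, genome) for p in sorted(directory.glob("*.bed"))
        }
        return cls(sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


def build_universe(
    query: RegionSet,
    database: RegionDatabase,
    user_universe: RegionSet | None = None,
) -> RegionSet:
    """The background collection of countable units for region enrichment.

    A user-supplied universe is sorted/merged and returned; otherwise the
    default is the >=1 bp-overlap merge of the query and every database set.
    """
    if user_universe is not None:
        out = merge_regions(user_universe.regions, user_universe.genome, name="universe")
    else:
        pool = list(query.regions)
        for _, s in database:
            pool.extend(s.regions)
        out = merge_regions(pool, query.genome, name="universe")
    if len(out) == 0:
        raise ValueError("empty universe")
    return out


def fisher_table(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> tuple[float, float]:
    """(odds ratio, Fisher p) for a 2x2 table.

    The odds ratio gets a +0.5 Haldane-Anscombe correction when any cell is
    zero; the p-value is always computed on the uncorrected table.
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p)


def _rank_results(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(
            ["p", "odds_ratio", "set"], ascending=[True, False, True], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    return df


def region_enrichment(
    query: RegionSet,
    database: RegionDatabase,
    universe: RegionSet,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-database-set overlap enrichment of a query region set.

    Universe units are the countable elements; membership in the query or a
    database set means >=1 bp overlap.  Query regions that overlap no
    universe unit are dropped with a warning.
    """
    if len(database) == 0:
        raise ValueError("empty database")
    n_orphans = int((~overlaps_any(query, universe)).sum())
    if n_orphans:
        logger.warning(
            "%d query regions overlap no universe unit and are ignored", n_orphans
        )
    in_query = overlaps_any(universe, query)
    rows = []
    for name, dbset in database:
        in_set = overlaps_any(universe, dbset)
        a = int(np.sum(in_query & in_set))
        b = int(np.sum(in_query & ~in_set))
        c = int(np.sum(~in_query & in_set))
        d = int(np.sum(~in_query & ~in_set))
        orr, p = fisher_table(a, b, c, d, alternative=alternative)
        rows.append(
            {"query": query.name, "set": name, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": orr, "p": p}
        )
    return _rank_results(pd.DataFrame(rows))


def gene_set_enrichment(
    study_genes: Sequence[str],
    background_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    query_name: str = "study",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher's exact enrichment of a study gene list against gene sets.

    Counts are restricted to the background; gene sets with no member in the
    background are skipped with a warning.  The study must be a subset of
    the background.
    """
    study = set(study_genes)
    background = set(background_genes)
    stray = sorted(study - background)
    if stray:
        raise ValueError(f"study genes outside the background: {stray[:10]}")
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & background
        if not inset:
            logger.warning("gene set %s has no genes in the background; skipped", name)
            continue
        a = len(study & inset)
        b = len(study - inset)
        c = len(inset - study)
        d = len(background) - a - b - c
        orr, p = fisher_table(a, b, c, d, alternative=alternative)
        rows.append(
            {"query": query_name, "set": name, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": orr, "p": p}
        )
    return _rank_results(pd.DataFrame(rows))


def run_background_schemes(
    assignments: Mapping[str, pd.DataFrame],
    gene_sets: Mapping[str, Sequence[str]],
    all_genes: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Gene-set enrichment of each (cluster, direction) under three backgrounds.

    ``assignments`` maps direction ("correlated"/"anticorrelated") to the
    per-transcript assignment frame from :func:`classify`.  Schemes:

    1. background = every gene tested for differential expression;
    2. background = same direction, the three other clusters;
    3. background = same cluster, both directions (direction-specific
       enrichment within a chromatin class).

    Returns one concatenated result frame per scheme; (study, background)
    pairs that are empty or degenerate are skipped with a warning.
    """
    def members(direction: str, cluster: int) -> set[str]:
        df = assignments[direction]
        return set(df.index[(df["unambiguous"]) & (df["best_cluster"] == cluster)])

    out: dict[str, list[pd.DataFrame]] = {"scheme1": [], "scheme2": [], "scheme3": []}
    for direction in assignments:
        for cluster in (1, 2, 3, 4):
            study = members(direction, cluster)
            name = f"{direction}_C{cluster}"
            if not study:
                logger.warning("empty study set for %s; skipped", name)
                continue
            # scheme 1: all tested genes
            bg1 = set(all_genes) | study
            out["scheme1"].append(
                gene_set_enrichment(study, bg1, gene_sets, query_name=name)
            )
            # scheme 2: other clusters, same direction
            others = set().union(*(members(direction, c) for c in (1, 2, 3, 4) if c != cluster))
            if others:
                out["scheme2"].append(
                    gene_set_enrichment(study, study | others, gene_sets, query_name=name)
                )
            else:
                logger.warning("scheme 2 background empty for %s; skipped", name)
            # scheme 3: same cluster, opposite direction
            opposite = set().union(
                *(members(d, cluster) for d in assignments if d != direction)
            )
            if opposite:
                out["scheme3"].append(
                    gene_set_enrichment(study, study | opposite, gene_sets, query_name=name)
                )
            else:
                logger.warning("scheme 3 background empty for %s; skipped", name)
    return {
        k: (pd.concat(v, ignore_index=True) if v else pd.DataFrame())
        for k, v in out.items()
    }


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
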