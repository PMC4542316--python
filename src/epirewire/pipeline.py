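"""End-to-end pipeline orchestration.

``run_pipeline`` drives every analysis stage on a set of study inputs —
differential expression, promoter chromatin clustering, gene-set
enrichment, differential peaks with ranking/binning summaries,
super-enhancer calling, cell-type specificity, methylation contrasts and
the per-cluster treatment-response report — and optionally writes each
stage's tables to an output directory.  Inputs come either from the
synthetic generator (in memory) or from an on-disk dataset directory laid
out as produced by :meth:`epirewire.synthetic.SyntheticDataset.write`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import chromclust, differential, enrichment, regions, signal, specificity, superenhancer
from .regions import RegionSet, TSSAnnotation, promoter_regions
from .signal import CoverageTrack
from .specificity import CellTypePanel

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "StudyInputs", "load_inputs", "run_pipeline", "response_report"]


@dataclass
class PipelineParams:
    """Every tunable pipeline parameter, with defaults matching the methods."""

    alpha: float = 0.05
    tau: float = 1.0
    promoter_upstream: int = 2000  # promoter-overlap definition for peaks
    cluster_flank: int = 2000  # promoter window half-width for clustering signal
    q_bins: int = 5
    stitch_bp: int = 12500
    tss_exclusion: bool = False
    tss_exclusion_bp: int = 2500
    k_init: int = 8
    purity_min: float = 0.8
    p_min: float = 0.5
    margin: float = 0.1
    min_cpgs: int = 3
    composite_flank: int = 5000
    composite_bin: int = 100
    n_boot: int = 1000
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class StudyInputs:
    """All per-study inputs the pipeline consumes."""

    genome: dict[str, int]
    tss_list: list[TSSAnnotation]
    expression: pd.DataFrame
    tracks: list[CoverageTrack]
    peaks_high: RegionSet
    peaks_low: RegionSet
    tf_sites: RegionSet
    panel: CellTypePanel
    methylation: pd.DataFrame
    response: pd.DataFrame
    gene_sets: dict[str, list[str]]

    @classmethod
    def from_synthetic(cls, ds) -> "StudyInputs":
        return cls(
            ds.genome, ds.tss_list, ds.expression, ds.tracks, ds.peaks_high,
            ds.peaks_low, ds.tf_sites, ds.panel, ds.methylation, ds.response,
            ds.gene_sets,
        )


def load_inputs(indir: str | Path) -> StudyInputs:
    """Load a dataset directory (the generator's on-disk layout)."""
    indir = Path(indir)
    for required in ("genome.chrom.sizes", "annotation.tss.bed", "expression.tsv"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"required input missing: {indir / required}")
    genome = regions.read_chrom_sizes(indir / "genome.chrom.sizes")
    tss_list = regions.read_tss_bed(indir / "annotation.tss.bed")
    expression = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    tracks = []
    for p in sorted((indir / "tracks").glob("*.bedgraph")):
        mark, state, rep = p.stem.rsplit("_", 2)
        tracks.append(signal.read_bedgraph(p, mark, state, int(rep.removeprefix("rep"))))
    peaks_high = regions.read_bed(indir / "peaks" / "h3k27ac_high.bed", "h3k27ac_high", genome)
    peaks_low = regions.read_bed(indir / "peaks" / "h3k27ac_low.bed", "h3k27ac_low", genome)
    tf_sites = regions.read_bed(indir / "peaks" / "tf.bed", "tf_sites", genome)
    panel = CellTypePanel.from_directory(indir / "panel", genome)
    methylation = signal.read_methylation(indir / "methylation.tsv")
    response = pd.read_csv(indir / "response.tsv", sep="\t")
    gmt = indir / "gene_sets.gmt"
    gene_sets = enrichment.read_gmt(gmt) if gmt.exists() else {}
    return StudyInputs(
        genome, tss_list, expression, tracks, peaks_high, peaks_low, tf_sites,
        panel, methylation, response, gene_sets,
    )


def _write_tsv(df: pd.DataFrame, path: Path, digest: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# epirewire config {digest}\n")
        df.to_csv(fh, sep="\t", index=index)


def cluster_both_directions(
    inputs: StudyInputs,
    de_table: pd.DataFrame,
    params: PipelineParams,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Semi-supervised chromatin clustering for each regulation direction.

    Promoter five-mark vectors are measured in the state where a transcript
    is more lowly expressed: the low state for correlated transcripts, the
    high state for anticorrelated ones.  Returns (assignments per direction,
    replicate-averaged per-state mark matrices keyed "high"/"low").
    """
    prom = promoter_regions(
        inputs.tss_list, inputs.genome,
        upstream_bp=params.cluster_flank, downstream_bp=params.cluster_flank,
        name="cluster_promoters",
    )
    mat = signal.build_signal_matrix(inputs.tracks, prom, log=True)
    by_state = signal.average_replicates(mat)  # columns (mark, state)
    state_frames = {
        st: by_state.xs(st, axis=1, level="state")[list(chromclust.MARKS)]
        for st in ("high", "low")
    }
    assignments: dict[str, pd.DataFrame] = {}
    for direction, sel_state in (("correlated", "low"), ("anticorrelated", "high")):
        ids = de_table.loc[de_table["label"] == direction, "id"]
        vectors = state_frames[sel_state].loc[ids]
        assign, _ = chromclust.cluster_transcripts(
            vectors, k_init=params.k_init, purity_min=params.purity_min,
            p_min=params.p_min, margin=params.margin, seed=params.seed,
        )
        assignments[direction] = assign
    return assignments, state_frames


def differential_peak_stage(
    inputs: StudyInputs, params: PipelineParams
) -> tuple[RegionSet, pd.DataFrame]:
    """Merge the two states' peak calls and test for differential signal.

    The tested units are the >=1 bp-overlap merge of the high-state and
    low-state peak calls; raw per-peak H3K27ac signal integrals feed the
    negative-binomial engine.
    """
    merged = regions.merge_regions(
        list(inputs.peaks_high.regions) + list(inputs.peaks_low.regions),
        inputs.genome, name="k27ac_union",
    )
    k27 = [t for t in inputs.tracks if t.mark == "H3K27ac"]
    cols = {
        (t.state, t.replicate): signal.quantify_regions(t, merged, log=False, normalize=False)
        for t in k27
    }
    sig = pd.DataFrame(cols, index=pd.Index(merged.ids, name="id"))
    diff = differential.call_diff_peaks(sig, alpha=params.alpha, tau=params.tau)
    return merged, diff


def run_pipeline(
    inputs: StudyInputs,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage in dependency order; returns a dict of result tables.

    With ``outdir`` set, each table is also written as TSV (header comment
    carries the parameter digest, so identical configurations rerun to
    byte-identical outputs).
    """
    params = params or PipelineParams()
    results: dict = {"params": params}

    # 1. differential expression
    de = differential.call_de(inputs.expression, alpha=params.alpha, tau=params.tau)
    results["de_table"] = de

    # 2. chromatin clustering per direction + per-cluster mark changes
    assignments, state_frames = cluster_both_directions(inputs, de, params)
    results["assignments"] = assignments
    results["mark_changes"] = {
        d: chromclust.summarize_mark_changes(
            assignments[d], state_frames["high"].loc[assignments[d].index],
            state_frames["low"].loc[assignments[d].index],
            n_boot=params.n_boot, seed=params.seed,
        )
        for d in assignments
    }

    # 3. gene-set enrichment under the three background schemes
    if inputs.gene_sets:
        results["enrichment"] = enrichment.run_background_schemes(
            assignments, inputs.gene_sets, list(de["id"])
        )

    # 4. differential peaks, ranking and summaries
    merged_peaks, diff_peaks = differential_peak_stage(inputs, params)
    results["peaks_tested"] = merged_peaks
    results["diff_peaks"] = diff_peaks
    promoters = promoter_regions(
        inputs.tss_list, inputs.genome, upstream_bp=params.promoter_upstream,
        downstream_bp=0, name="peak_promoters",
    )
    bins = {}
    for direction in ("correlated", "anticorrelated"):
        sub = diff_peaks[diff_peaks["label"] == direction]
        if len(sub) >= params.q_bins:
            b = differential.rank_and_bin(sub, q=params.q_bins)
            bins[direction] = b
    results["bins"] = bins
    results["promoter_fraction"] = {
        d: differential.promoter_fraction_by_bin(b, merged_peaks, promoters)
        for d, b in bins.items()
    }
    results["topn_curve"] = {
        d: differential.topn_binding_curve(b, merged_peaks, inputs.tf_sites)
        for d, b in bins.items()
    }
    results["foldchange_by_binding"] = differential.foldchange_by_binding(
        diff_peaks, merged_peaks, inputs.tf_sites
    )

    # 5. super-enhancers from the high-state peaks
    k27_high = [t for t in inputs.tracks if t.mark == "H3K27ac" and t.state == "high"]
    high_sig = np.mean(
        [signal.quantify_regions(t, inputs.peaks_high, log=False) for t in k27_high],
        axis=0,
    )
    tss_excl = None
    if params.tss_exclusion:
        tss_excl = promoter_regions(
            inputs.tss_list, inputs.genome, upstream_bp=params.tss_exclusion_bp,
            downstream_bp=params.tss_exclusion_bp, name="tss_exclusion",
        )
    se_calls = superenhancer.call_superenhancers(
        inputs.peaks_high, dict(zip(inputs.peaks_high.ids, high_sig)),
        stitch_bp=params.stitch_bp, tss_exclude=tss_excl, tss_list=inputs.tss_list,
    )
    results["se_calls"] = se_calls
    results["se_dynamics"] = superenhancer.se_dynamics(
        se_calls, diff_peaks_for_members(diff_peaks, merged_peaks, inputs.peaks_high),
        inputs.peaks_high, inputs.tf_sites,
    )

    # 6. cell-type specificity
    profile = specificity.score_specificity(merged_peaks, inputs.panel)
    results["specificity_profile"] = profile
    if "correlated" in bins:
        results["specificity_by_bin"] = specificity.specificity_by_bin(
            profile, bins["correlated"], n_boot=params.n_boot, seed=params.seed
        )
        top_ids = bins["correlated"].bin_ids(1)
        anti_ids = list(diff_peaks.loc[diff_peaks["label"] == "anticorrelated", "id"])
        if top_ids and anti_ids:
            results["exclusivity"] = specificity.exclusivity_test(
                profile.loc[top_ids, "exclusive_to_matched"],
                profile.loc[anti_ids, "exclusive_to_matched"],
            )
        corr_ids = list(diff_peaks.loc[diff_peaks["label"] == "correlated", "id"])
        se_members = set()
        for e in se_calls.supers:
            se_members.update(e.member_ids)
        se_map = map_ids_by_overlap(inputs.peaks_high, merged_peaks)
        se_corr = [i for i in corr_ids if i in {se_map.get(m) for m in se_members}]
        if len(corr_ids) >= 10 and len(se_corr) >= 10:
            results["qq_specificity"] = specificity.qq_compare(
                profile.loc[corr_ids, "share"], profile.loc[se_corr, "share"]
            )

    # 7. methylation at peaks split by TF binding
    meth = signal.methylation_at_regions(
        inputs.methylation, merged_peaks, min_cpgs=params.min_cpgs
    )
    bound = regions.overlaps_any(merged_peaks, inputs.tf_sites)
    bound_ids = set(np.asarray(merged_peaks.ids)[bound])
    m_bound = meth[meth.index.isin(bound_ids)]
    m_unbound = meth[~meth.index.isin(bound_ids)]
    if len(m_bound) >= 5 and len(m_unbound) >= 5:
        d, p = signal.ks_compare(m_bound, m_unbound)
        results["methylation"] = {
            "bound_mean": float(m_bound.mean()), "unbound_mean": float(m_unbound.mean()),
            "ks_D": d, "ks_p": p, "n_bound": len(m_bound), "n_unbound": len(m_unbound),
        }

    # 8. per-cluster treatment-response report
    results["response_report"] = response_report(
        inputs.response, assignments
    )

    if outdir is not None:
        _write_outputs(results, Path(outdir), params)
    return results


def diff_peaks_for_members(
    diff_peaks: pd.DataFrame, merged: RegionSet, member_peaks: RegionSet
) -> pd.DataFrame:
    """Re-key the merged-peak differential labels onto member peak ids.

    Stitched-enhancer members are the state-specific peak calls; each one
    inherits the label of the merged tested unit it overlaps.
    """
    mapping = map_ids_by_overlap(member_peaks, merged)
    by_merged = dict(zip(diff_peaks["id"], diff_peaks["label"]))
    rows = [
        {"id": mid, "label": by_merged.get(mapping.get(mid), "unchanged"),
         "log2fc": 0.0}
        for mid in member_peaks.ids
    ]
    return pd.DataFrame(rows)


def map_ids_by_overlap(a: RegionSet, b: RegionSet) -> dict[str, str]:
    """Map each region id in ``a`` to the id of an overlapping region in ``b``."""
    b_idx: dict[str, list[tuple[int, int, str]]] = {}
    for rid, r in zip(b.ids, b.regions):
        b_idx.setdefault(r.chrom, []).append((r.start, r.end, rid))
    for c in b_idx:
        b_idx[c].sort()
    out: dict[str, str] = {}
    for rid, r in zip(a.ids, a.regions):
        ivs = b_idx.get(r.chrom, [])
        starts = [s for s, _, _ in ivs]
        import bisect

        j = bisect.bisect_right(starts, r.start)
        for k in (j - 1, j):
            if 0 <= k < len(ivs):
                s, e, bid = ivs[k]
                if s < r.end and r.start < e:
                    out[rid] = bid
                    break
    return out


def response_report(
    response: pd.DataFrame,
    assignments: Mapping[str, pd.DataFrame],
    min_covered: int = 5,
) -> pd.DataFrame:
    """Per-(cluster, direction) treatment-response summary.

    For each cluster and direction: the median response log2 fold change of
    its unambiguous members, a Wilcoxon rank-sum test against all other
    covered transcripts, and BH FDR across groups.  Groups covering fewer
    than ``min_covered`` transcripts are omitted with a warning.
    """
    resp = response.set_index("transcript_id")["response_log2fc"]
    covered_total = set(resp.index)
    rows = []
    for direction, assign in assignments.items():
        for cluster in (1, 2, 3, 4):
            members = assign.index[
                assign["unambiguous"] & (assign["best_cluster"] == cluster)
            ]
            vals = resp.loc[resp.index.intersection(members)]
            if len(vals) < min_covered:
                logger.warning(
                    "cluster %d (%s): %d covered transcripts < %d; omitted",
                    cluster, direction, len(vals), min_covered,
                )
                continue
            others = resp.loc[list(covered_total - set(vals.index))]
            stat = stats.mannwhitneyu(vals, others, alternative="two-sided")
            rows.append(
                {
                    "direction": direction,
                    "cluster": cluster,
                    "n": len(vals),
                    "median_response": float(vals.median()),
                    "p": float(stat.pvalue),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def _write_outputs(results: dict, outdir: Path, params: PipelineParams) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    digest = params.digest()
    _write_tsv(results["de_table"], outdir / "de_table.tsv", digest)
    for d, a in results["assignments"].items():
        _write_tsv(a, outdir / f"assignments_{d}.tsv", digest, index=True)
        _write_tsv(results["mark_changes"][d], outdir / f"mark_changes_{d}.tsv", digest)
    for scheme, df in results.get("enrichment", {}).items():
        _write_tsv(df, outdir / f"enrichment_{scheme}.tsv", digest)
    _write_tsv(results["diff_peaks"], outdir / "diff_peaks.tsv", digest)
    for d, b in results["bins"].items():
        _write_tsv(b.table, outdir / f"ranked_bins_{d}.tsv", digest)
        _write_tsv(
            results["promoter_fraction"][d].reset_index(),
            outdir / f"promoter_fraction_{d}.tsv", digest,
        )
        _write_tsv(results["topn_curve"][d], outdir / f"topn_curve_{d}.tsv", digest)
    _write_tsv(results["se_calls"].to_frame(), outdir / "superenhancers.tsv", digest)
    _write_tsv(results["se_dynamics"], outdir / "se_dynamics.tsv", digest)
    _write_tsv(
        results["specificity_profile"], outdir / "specificity_profile.tsv", digest,
        index=True,
    )
    if "specificity_by_bin" in results:
        _write_tsv(results["specificity_by_bin"], outdir / "specificity_by_bin.tsv", digest)
    if "qq_specificity" in results:
        _write_tsv(results["qq_specificity"], outdir / "qq_specificity.tsv", digest)
    _write_tsv(results["response_report"], outdir / "response_report.tsv", digest)
    scalars = {}
    if "exclusivity" in results:
        scalars["exclusivity"] = results["exclusivity"]
    if "methylation" in results:
        scalars["methylation"] = results["methylation"]
    fk = results.get("foldchange_by_binding")
    if fk:
        scalars["foldchange_by_binding"] = {"ks_D": fk["ks_D"], "ks_p": fk["ks_p"]}
    scalars["se_summary"] = results["se_calls"].summary()
    with open(outdir / "summary.json", "w") as fh:
        json.dump({"config": digest, **scalars}, fh, indent=1, default=float)
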