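"""Self-contained synthetic two-state epigenome study with planted truth.

The generator lays out a small genome and plants every structure the
pipeline analyzes, so each stage can be validated against known truth
without external data:

* transcripts with a regulation direction (correlated / anticorrelated /
  unchanged) and, for regulated transcripts, one of the four promoter
  chromatin prototype classes realized in the state where the transcript
  is more lowly expressed;
* five-mark promoter coverage per state and replicate: a present mark's
  log2 rectangle level draws from Normal(mu_present, sigma), an absent
  mark's from Normal(mu_absent, sigma);
* H3K27ac peaks with planted direction and fold-change magnitude,
  promoter co-location biased toward weakly changing correlated peaks,
  and super-enhancers as compact agglomerates of high-signal peaks;
* TF (fusion oncoprotein) binding sites strongly enriched on the most
  differential correlated peaks;
* CpG methylation depleted at TF-bound peaks;
* a K-cell-type open-chromatin panel with one matched cell type and
  planted matched-exclusivity on the strongest correlated bound peaks;
* expression counts (negative binomial), a treatment-response table, and
  gene sets containing one planted cluster-specific set.

Everything is driven by one ``numpy`` Generator, so a seed reproduces the
dataset bit-identically; the planted truth is persisted in a ledger.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromclust import MARKS
from .regions import GenomicRegion, RegionSet, TSSAnnotation, write_bed, write_tss_bed
from .signal import CoverageTrack, write_bedgraph
from .specificity import CellTypePanel

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "generate_null"]

STATES = ("high", "low")

# presence of (H3K4me3, H3K4me1, H3K27ac, H3K56ac, H3K27me3) per prototype;
# None marks the repressed class's don't-care H3K4 positions (Bernoulli 0.5)
PROTOTYPE_PRESENCE: dict[int, tuple] = {
    1: (1, 1, 1, 1, 0),
    2: (1, 1, 0, 0, 0),
    3: (0, 1, 0, 0, 0),
    4: (None, None, 0, 0, 1),
}
ACTIVE_PATTERN = PROTOTYPE_PRESENCE[1]


@dataclass
class SyntheticConfig:
    """Sizes, rates and signal parameters of the synthetic study."""

    n_chroms: int = 5
    chrom_length: int = 10_000_000
    n_transcripts: int = 2000
    n_peaks: int = 4000
    n_superenhancers: int = 40
    n_celltypes: int = 12
    n_replicates: int = 2

    frac_correlated: float = 0.30
    frac_anticorrelated: float = 0.30

    expr_base_mean: float = 200.0
    expr_log2fc: float = 2.0
    expr_dispersion: float = 0.05

    mark_mu_present: float = 6.0
    mark_mu_absent: float = 1.0
    mark_sigma: float = 1.0

    peak_base_log2: float = 6.0
    peak_base_sd: float = 0.7
    peak_rep_sd: float = 0.5
    peak_lfc_floor: float = 1.1
    se_base_log2: float = 7.5

    tf_top_decile_rate: float = 0.80
    tf_other_correlated_rate: float = 0.12
    tf_anticorrelated_rate: float = 0.01
    tf_unchanged_rate: float = 0.02

    exclusivity_rate: float = 0.37
    background_value: float = 0.1
    response_effect: float = 1.0
    response_sd: float = 0.3
    null: bool = False

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class TruthLedger:
    """Persisted record of everything the generator planted."""

    seed: int
    params: dict
    transcripts: pd.DataFrame  # direction, cluster, expr_log2fc, tss info
    peaks: pd.DataFrame  # direction, lfc, tf_bound, se_id, promoter_colocated, exclusive
    superenhancers: pd.DataFrame  # se_id, member ids, dynamics class

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "transcripts": self.transcripts.reset_index().to_dict(orient="list"),
            "peaks": self.peaks.reset_index().to_dict(orient="list"),
            "superenhancers": self.superenhancers.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


@dataclass
class SyntheticDataset:
    """In-memory synthetic study; ``write`` emits the on-disk layout."""

    config: SyntheticConfig
    seed: int
    genome: dict[str, int]
    tss_list: list[TSSAnnotation]
    expression: pd.DataFrame
    tracks: list[CoverageTrack]
    peaks: RegionSet
    peaks_high: RegionSet
    peaks_low: RegionSet
    tf_sites: RegionSet
    panel: CellTypePanel
    methylation: pd.DataFrame
    response: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: TruthLedger

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.chrom.sizes", "w") as fh:
            for c, ln in self.genome.items():
                fh.write(f"{c}\t{ln}\n")
        write_tss_bed(self.tss_list, out / "annotation.tss.bed")
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="transcript_id")
        self.methylation.to_csv(out / "methylation.tsv", sep="\t", index=False)
        self.response.to_csv(out / "response.tsv", sep="\t", index=False)
        (out / "peaks").mkdir(exist_ok=True)
        write_bed(self.peaks, out / "peaks" / "h3k27ac_all.bed")
        write_bed(self.peaks_high, out / "peaks" / "h3k27ac_high.bed")
        write_bed(self.peaks_low, out / "peaks" / "h3k27ac_low.bed")
        write_bed(self.tf_sites, out / "peaks" / "tf.bed")
        (out / "tracks").mkdir(exist_ok=True)
        for t in self.tracks:
            write_bedgraph(t, out / "tracks" / f"{t.mark}_{t.state}_rep{t.replicate}.bedgraph")
        (out / "panel").mkdir(exist_ok=True)
        rows = []
        for name, rs in self.panel.sets.items():
            write_bed(rs, out / "panel" / f"{name}.bed")
            rows.append({"name": name, "path": f"{name}.bed", "matched": name == self.panel.matched})
        pd.DataFrame(rows).to_csv(out / "panel" / "manifest.tsv", sep="\t", index=False)
        with open(out / "gene_sets.gmt", "w") as fh:
            for name, genes in self.gene_sets.items():
                fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
        self.truth.to_json(out / "truth.json")
        return out


def _draw_presence(cluster: int, rng: np.random.Generator) -> np.ndarray:
    pattern = PROTOTYPE_PRESENCE[cluster]
    return np.array(
        [rng.integers(0, 2) if p is None else p for p in pattern], dtype=int
    )


def _flatten_rectangles(
    rects: list[tuple[int, int, float]], chrom_length: int, background: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant track from rectangles: max where they overlap,
    background elsewhere, merged runs of equal value."""
    if not rects:
        return (
            np.array([0], dtype=np.int64),
            np.array([chrom_length], dtype=np.int64),
            np.array([background]),
        )
    edges = sorted({0, chrom_length} | {s for s, _, _ in rects} | {e for _, e, _ in rects})
    edges = [e for e in edges if 0 <= e <= chrom_length]
    bounds = np.asarray(edges, dtype=np.int64)
    seg = np.full(len(bounds) - 1, background)
    for s, e, v in rects:
        i0 = np.searchsorted(bounds, max(0, s))
        i1 = np.searchsorted(bounds, min(chrom_length, e))
        np.maximum(seg[i0:i1], v, out=seg[i0:i1])
    # merge adjacent equal-value runs
    keep = np.concatenate(([True], seg[1:] != seg[:-1]))
    starts = bounds[:-1][keep]
    values = seg[keep]
    ends = np.concatenate((starts[1:], [chrom_length]))
    return starts, ends, values


def generate(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate the full synthetic study for a seed.

    Raises on infeasible configurations (more super-enhancers than a tenth
    of the peaks, or a genome too small to place every feature).
    """
    cfg = config or SyntheticConfig()
    if cfg.n_superenhancers > cfg.n_peaks // 10:
        raise ValueError("more super-enhancers than peaks/10; infeasible config")
    rng = np.random.default_rng(seed)
    genome = cfg.genome
    chrom_names = list(genome)

    # ---- transcript truth -------------------------------------------------
    n = cfg.n_transcripts
    if cfg.null:
        directions = np.full(n, "unchanged", dtype=object)
    else:
        n_corr = int(round(n * cfg.frac_correlated))
        n_anti = int(round(n * cfg.frac_anticorrelated))
        directions = np.array(
            ["correlated"] * n_corr + ["anticorrelated"] * n_anti
            + ["unchanged"] * (n - n_corr - n_anti),
            dtype=object,
        )
        rng.shuffle(directions)
    clusters = np.where(
        directions == "unchanged",
        rng.choice([1, 2, 3, 4], size=n, p=[0.6, 0.2, 0.1, 0.1]),
        rng.integers(1, 5, size=n),
    )
    expr_lfc = np.where(
        directions == "correlated", cfg.expr_log2fc,
        np.where(directions == "anticorrelated", -cfg.expr_log2fc, 0.0),
    )

    # ---- super-enhancer composition --------------------------------------
    # the null study keeps the agglomerate geometry but plants neither a
    # signal boost nor member effects, so no rank-signal elbow exists
    n_se = cfg.n_superenhancers
    se_sizes = rng.integers(8, 15, size=n_se)
    n_se_peaks = int(se_sizes.sum())
    se_classes = (
        np.full(n_se, "stable", dtype=object)
        if cfg.null
        else rng.choice(
            ["widespread_loss", "localized_change", "stable"],
            size=n_se, p=[0.60, 0.25, 0.15],
        )
    )

    # ---- free (non-SE) peak truth ----------------------------------------
    n_free = cfg.n_peaks - n_se_peaks
    if n_free <= 0:
        raise ValueError("super-enhancer members exceed the peak budget")
    if cfg.null:
        free_dir = np.full(n_free, "unchanged", dtype=object)
    else:
        n_pc = int(round(n_free * 0.35))
        n_pa = int(round(n_free * 0.35))
        free_dir = np.array(
            ["correlated"] * n_pc + ["anticorrelated"] * n_pa
            + ["unchanged"] * (n_free - n_pc - n_pa),
            dtype=object,
        )
        rng.shuffle(free_dir)
    free_mag = np.where(
        free_dir == "unchanged", 0.0,
        cfg.peak_lfc_floor + rng.gamma(1.5, 1.0, size=n_free),
    )
    free_lfc = np.where(free_dir == "anticorrelated", -free_mag, free_mag)

    # promoter co-location probability: weak correlated peaks sit in
    # promoters far more often than the strongest ones (emulating the
    # 62% -> 10% gradient); anticorrelated peaks are flat and rare there
    mag_pct = np.zeros(n_free)
    corr_mask = free_dir == "correlated"
    if corr_mask.sum() > 1:
        ranks = free_mag[corr_mask].argsort().argsort()
        mag_pct[corr_mask] = ranks / (corr_mask.sum() - 1)
    prom_p = np.where(
        corr_mask, 0.62 - 0.52 * mag_pct,
        np.where(free_dir == "anticorrelated", 0.06, 0.15),
    )
    promoter_flag = rng.random(n_free) < prom_p
    # promoter peaks are hosted at promoters that carry K27ac in the state
    # used for chromatin clustering (prototype class 1) or at promoters of
    # unregulated transcripts: a promoter H3K27ac peak is the promoter's own
    # acetylation, so it cannot sit where the mark is planted absent
    host_pool = np.flatnonzero((directions == "unchanged") | (clusters == 1))
    if promoter_flag.sum() > len(host_pool):
        excess = np.flatnonzero(promoter_flag)
        drop = rng.choice(excess, size=promoter_flag.sum() - len(host_pool), replace=False)
        promoter_flag[drop] = False

    # ---- genome layout ----------------------------------------------------
    # units: promoters (span 5 kb, TSS centered), SE agglomerates, and
    # distal peak groups of 1-3 peaks separated by >stitch gaps
    free_idx = np.arange(n_free)
    distal_idx = free_idx[~promoter_flag].copy()
    rng.shuffle(distal_idx)
    distal_idx = [int(x) for x in distal_idx]
    groups: list[list[int]] = []
    i = 0
    while i < len(distal_idx):
        size = int(rng.choice([1, 2, 3], p=[0.70, 0.25, 0.05]))
        groups.append(distal_idx[i : i + size])
        i += size

    units: list[tuple] = (
        [("promoter", t) for t in range(n)]
        + [("se", s) for s in range(n_se)]
        + [("group", g) for g in range(len(groups))]
    )
    units = [units[j] for j in rng.permutation(len(units))]

    tss_pos = np.zeros(n, dtype=np.int64)
    tss_chrom = np.empty(n, dtype=object)
    tss_strand = np.where(rng.random(n) < 0.5, "+", "-")
    peak_iv = np.zeros((cfg.n_peaks, 2), dtype=np.int64)
    peak_chrom = np.empty(cfg.n_peaks, dtype=object)
    se_of_peak = np.full(cfg.n_peaks, -1, dtype=np.int64)
    se_members: list[list[int]] = [[] for _ in range(n_se)]

    se_peak_cursor = n_free  # SE peaks take ids after the free peaks
    chrom_i, cursor = 0, 10_000
    for unit in units:
        kind = unit[0]
        if kind == "promoter":
            span = 4200
        elif kind == "se":
            m = int(se_sizes[unit[1]])
            widths = rng.integers(800, 1500, size=m)
            gaps = rng.integers(800, 2500, size=m - 1) if m > 1 else np.array([], dtype=int)
            span = int(widths.sum() + gaps.sum() + 4000)
        else:
            g = groups[unit[1]]
            widths = rng.integers(600, 1600, size=len(g))
            gaps = rng.integers(500, 9000, size=len(g) - 1) if len(g) > 1 else np.array([], dtype=int)
            span = int(widths.sum() + gaps.sum()) + int(rng.integers(12_800, 16_000))
        while cursor + span > genome[chrom_names[chrom_i]] - 10_000:
            chrom_i += 1
            cursor = 10_000
            if chrom_i >= len(chrom_names):
                raise ValueError("genome too small for the requested feature counts")
        chrom = chrom_names[chrom_i]
        if kind == "promoter":
            t = unit[1]
            tss_pos[t] = cursor + 2100
            tss_chrom[t] = chrom
        elif kind == "se":
            s = unit[1]
            pos = cursor + 2000
            for w, gap in zip(widths, np.append(gaps, 0)):
                pid = se_peak_cursor
                peak_iv[pid] = (pos, pos + int(w))
                peak_chrom[pid] = chrom
                se_of_peak[pid] = s
                se_members[s].append(pid)
                se_peak_cursor += 1
                pos += int(w) + int(gap)
        else:
            pos = cursor
            for pid, w, gap in zip(groups[unit[1]], widths, np.append(gaps, 0)):
                peak_iv[pid] = (pos, pos + int(w))
                peak_chrom[pid] = chrom
                pos += int(w) + int(gap)
        cursor += span

    # promoter-colocated peaks sit in the 2-kb upstream promoter window
    prom_peak_ids = free_idx[promoter_flag]
    hosts = rng.choice(host_pool, size=len(prom_peak_ids), replace=False)
    for pid, t in zip(prom_peak_ids, hosts):
        width = int(rng.integers(600, 1100))
        if tss_strand[t] == "+":
            start = int(tss_pos[t]) - 1800
        else:
            start = int(tss_pos[t]) + 1800 - width
        peak_iv[pid] = (start, start + width)
        peak_chrom[pid] = tss_chrom[t]

    # ---- SE member truth ---------------------------------------------------
    peak_dir = np.empty(cfg.n_peaks, dtype=object)
    peak_lfc = np.zeros(cfg.n_peaks)
    peak_dir[:n_free] = free_dir
    peak_lfc[:n_free] = free_lfc
    for s in range(n_se):
        members = se_members[s]
        cls = se_classes[s]
        if cls == "widespread_loss":
            chosen = members
        elif cls == "localized_change":
            chosen = list(rng.choice(members, size=int(rng.integers(1, 3)), replace=False))
        else:
            chosen = []
        for pid in members:
            if pid in chosen:
                peak_dir[pid] = "correlated"
                peak_lfc[pid] = cfg.peak_lfc_floor + rng.gamma(1.5, 1.0)
            else:
                peak_dir[pid] = "unchanged"
                peak_lfc[pid] = 0.0

    # ---- TF binding ---------------------------------------------------------
    corr_all = peak_dir == "correlated"
    mag_all = np.abs(peak_lfc)
    tf_p = np.where(
        peak_dir == "anticorrelated", cfg.tf_anticorrelated_rate,
        np.where(peak_dir == "unchanged", cfg.tf_unchanged_rate, cfg.tf_other_correlated_rate),
    )
    if corr_all.sum() > 0 and not cfg.null:
        thr = np.quantile(mag_all[corr_all], 0.9)
        tf_p[corr_all & (mag_all >= thr)] = cfg.tf_top_decile_rate
    tf_bound = rng.random(cfg.n_peaks) < tf_p
    # localized SE changes are driven by TF binding at the changing peaks
    for s in range(n_se):
        if se_classes[s] == "localized_change":
            for pid in se_members[s]:
                if peak_dir[pid] == "correlated":
                    tf_bound[pid] = True
    tf_regions = []
    for pid in np.flatnonzero(tf_bound):
        s, e = peak_iv[pid]
        w = int(rng.integers(200, 401))
        off = int(rng.integers(0, max(1, (e - s) - w)))
        tf_regions.append(
            GenomicRegion(peak_chrom[pid], int(s) + off, int(s) + off + w, ".", f"tf_{pid}")
        )

    # ---- promoter mark presence and track rectangles ------------------------
    rep_factors = {
        (st, r): float(rng.uniform(0.85, 1.15))
        for st in STATES for r in range(1, cfg.n_replicates + 1)
    }
    presence = {}
    for t in range(n):
        planted = _draw_presence(int(clusters[t]), rng)
        if directions[t] == "correlated":
            presence[t] = {"high": np.asarray(ACTIVE_PATTERN), "low": planted}
        elif directions[t] == "anticorrelated":
            presence[t] = {"high": planted, "low": np.asarray(ACTIVE_PATTERN)}
        else:
            presence[t] = {"high": planted, "low": planted}

    # per-(state, replicate) log2 levels for peaks
    se_boost = 0.0 if cfg.null else cfg.se_base_log2 - cfg.peak_base_log2
    peak_state_mu = {
        "high": cfg.peak_base_log2 + np.where(se_of_peak >= 0, se_boost, 0.0)
        + rng.normal(0.0, cfg.peak_base_sd, size=cfg.n_peaks) + peak_lfc / 2.0,
    }
    peak_state_mu["low"] = peak_state_mu["high"] - peak_lfc

    tracks: list[CoverageTrack] = []
    for mark_i, mark in enumerate(MARKS):
        for st in STATES:
            for r in range(1, cfg.n_replicates + 1):
                factor = rep_factors[(st, r)]
                rect_by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_names}
                mu = np.where(
                    np.array([presence[t][st][mark_i] for t in range(n)]) == 1,
                    cfg.mark_mu_present, cfg.mark_mu_absent,
                )
                levels = 2.0 ** rng.normal(mu, cfg.mark_sigma)
                for t in range(n):
                    rect_by_chrom[tss_chrom[t]].append(
                        (int(tss_pos[t]) - 1000, int(tss_pos[t]) + 1000, float(levels[t] * factor))
                    )
                if mark == "H3K27ac":
                    noise = rng.normal(0.0, cfg.peak_rep_sd, size=cfg.n_peaks)
                    vals = 2.0 ** (peak_state_mu[st] + noise)
                    for pid in range(cfg.n_peaks):
                        s, e = peak_iv[pid]
                        rect_by_chrom[peak_chrom[pid]].append(
                            (int(s), int(e), float(vals[pid] * factor))
                        )
                chroms = {}
                for c in chrom_names:
                    starts, ends, values = _flatten_rectangles(
                        rect_by_chrom[c], genome[c], cfg.background_value * factor
                    )
                    chroms[c] = (starts, ends, values)
                tracks.append(CoverageTrack(mark, st, r, chroms))

    # ---- expression counts ---------------------------------------------------
    base = np.exp(rng.normal(np.log(cfg.expr_base_mean), 0.8, size=n))
    nb_n = 1.0 / cfg.expr_dispersion
    cols = {}
    for st in STATES:
        shift = expr_lfc / 2.0 if st == "high" else -expr_lfc / 2.0
        mean = base * 2.0**shift
        for r in range(1, cfg.n_replicates + 1):
            m = mean * rep_factors[(st, r)]
            cols[f"{st}_rep{r}"] = rng.negative_binomial(nb_n, nb_n / (nb_n + m))
    transcript_ids = [f"tx_{i:05d}" for i in range(n)]
    expression = pd.DataFrame(cols, index=pd.Index(transcript_ids, name="transcript_id"))

    # ---- methylation ---------------------------------------------------------
    meth_rows = {"chrom": [], "pos": [], "meth_reads": [], "total_reads": []}

    def add_cpgs(chrom: str, start: int, end: int, a: float, b: float, count: int) -> None:
        pos = np.sort(rng.integers(start, end, size=count))
        betas = rng.beta(a, b, size=count)
        total = rng.integers(10, 51, size=count)
        meth = rng.binomial(total, betas)
        meth_rows["chrom"].extend([chrom] * count)
        meth_rows["pos"].extend(pos.tolist())
        meth_rows["meth_reads"].extend(meth.tolist())
        meth_rows["total_reads"].extend(total.tolist())

    for pid in range(cfg.n_peaks):
        s, e = peak_iv[pid]
        a, b = (2.0, 8.0) if tf_bound[pid] else (8.0, 2.0)
        if cfg.null:
            a, b = 5.0, 5.0
        add_cpgs(peak_chrom[pid], int(s), int(e), a, b, int(rng.integers(4, 9)))
    for t in range(n):
        add_cpgs(tss_chrom[t], int(tss_pos[t]) - 1000, int(tss_pos[t]) + 1000, 1.5, 8.5, 6)
    methylation = pd.DataFrame(meth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)

    # ---- cell-type panel -----------------------------------------------------
    celltypes = [f"celltype_{k:02d}" for k in range(cfg.n_celltypes - 1)] + ["matched"]
    open_p_other = np.where(
        corr_all, 0.05 + 0.55 * (1.0 - _percentile_rank(mag_all, corr_all)), 0.50
    )
    if cfg.null:
        open_p_other = np.full(cfg.n_peaks, 0.5)
    open_matrix = np.zeros((cfg.n_peaks, cfg.n_celltypes), dtype=bool)
    open_matrix[:, -1] = rng.random(cfg.n_peaks) < 0.88  # matched cell type
    for k in range(cfg.n_celltypes - 1):
        open_matrix[:, k] = rng.random(cfg.n_peaks) < open_p_other
    exclusive_forced = np.zeros(cfg.n_peaks, dtype=bool)
    if not cfg.null and corr_all.sum() > 0:
        thr = np.quantile(mag_all[corr_all], 0.9)
        strongest = corr_all & (mag_all >= thr) & tf_bound
        exclusive_forced = strongest & (rng.random(cfg.n_peaks) < cfg.exclusivity_rate)
        open_matrix[exclusive_forced, :-1] = False
        open_matrix[exclusive_forced, -1] = True
    panel_sets = {}
    for k, name in enumerate(celltypes):
        regs = []
        for pid in np.flatnonzero(open_matrix[:, k]):
            s, e = peak_iv[pid]
            regs.append(GenomicRegion(peak_chrom[pid], int(s), int(e), ".", f"{name}_{pid}"))
        # a few cell-type-private open regions placed in unused space
        for j in range(60):
            c = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = int(rng.integers(0, genome[c] - 1000))
            regs.append(GenomicRegion(c, start, start + int(rng.integers(300, 900)), ".", f"{name}_bg{j}"))
        panel_sets[name] = RegionSet(name, regs, genome)
    panel = CellTypePanel(panel_sets, matched="matched")

    # ---- response table and gene sets ---------------------------------------
    responds = (directions == "anticorrelated") & np.isin(clusters, (2, 3, 4)) & (not cfg.null)
    response_lfc = np.where(responds, cfg.response_effect, 0.0) + rng.normal(
        0.0, cfg.response_sd, size=n
    )
    response = pd.DataFrame(
        {"transcript_id": transcript_ids, "response_log2fc": response_lfc}
    )

    gene_sets: dict[str, list[str]] = {}
    tx_arr = np.asarray(transcript_ids, dtype=object)
    if not cfg.null:
        target = (directions == "correlated") & (clusters == 1)
        members = list(tx_arr[target & (rng.random(n) < 0.60)])
        members += list(tx_arr[~target & (rng.random(n) < 0.05)])
        gene_sets["planted_C1_correlated"] = sorted(members)
    for j in range(10):
        gene_sets[f"random_set_{j:02d}"] = sorted(
            rng.choice(tx_arr, size=100, replace=False)
        )

    # ---- assemble region sets and truth --------------------------------------
    peak_ids = [f"peak_{i:05d}" for i in range(cfg.n_peaks)]
    all_peaks = RegionSet(
        "h3k27ac_peaks",
        [
            GenomicRegion(peak_chrom[i], int(peak_iv[i, 0]), int(peak_iv[i, 1]), ".", peak_ids[i])
            for i in range(cfg.n_peaks)
        ],
        genome,
    )
    peaks_high = all_peaks.subset(peak_dir != "anticorrelated", "h3k27ac_high")
    peaks_low = all_peaks.subset(peak_dir != "correlated", "h3k27ac_low")
    tf_sites = RegionSet("tf_sites", tf_regions, genome)
    tss_list = [
        TSSAnnotation(transcript_ids[t], transcript_ids[t], tss_chrom[t], int(tss_pos[t]), tss_strand[t])
        for t in range(n)
    ]

    truth_tx = pd.DataFrame(
        {
            "direction": directions,
            "cluster": clusters,
            "expr_log2fc": expr_lfc,
            "chrom": tss_chrom,
            "tss": tss_pos,
            "strand": tss_strand,
            "responds": responds,
        },
        index=pd.Index(transcript_ids, name="transcript_id"),
    )
    truth_pk = pd.DataFrame(
        {
            "direction": peak_dir,
            "log2fc": peak_lfc,
            "tf_bound": tf_bound,
            "se_id": se_of_peak,
            "promoter_colocated": np.concatenate(
                [promoter_flag, np.zeros(n_se_peaks, dtype=bool)]
            ),
            "exclusive_to_matched": (open_matrix.sum(axis=1) == 1) & open_matrix[:, -1],
            "n_celltypes_open": open_matrix.sum(axis=1),
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )
    truth_se = pd.DataFrame(
        {
            "se_id": np.arange(n_se),
            "members": [",".join(peak_ids[p] for p in m) for m in se_members],
            "dynamics": se_classes,
        }
    )
    truth = TruthLedger(seed, asdict(cfg), truth_tx, truth_pk, truth_se)

    return SyntheticDataset(
        cfg, seed, genome, tss_list, expression, tracks, all_peaks, peaks_high,
        peaks_low, tf_sites, panel, methylation, response, gene_sets, truth,
    )


def _percentile_rank(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Percentile rank (0..1) of masked values, 0 elsewhere."""
    out = np.zeros(len(values))
    if mask.sum() > 1:
        ranks = values[mask].argsort().argsort()
        out[mask] = ranks / (mask.sum() - 1)
    return out


def generate_null(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Dataset with no planted effects (type-I-error suites)."""
    cfg = config or SyntheticConfig()
    cfg = SyntheticConfig(**{**asdict(cfg), "null": True})
    return generate(cfg, seed)
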