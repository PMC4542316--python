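"""Cell-type specificity of peaks against a multi-cell-type open-chromatin
panel.

Each peak is scored by the number of panel cell types in which it overlaps
an open-chromatin region (>= 1 bp).  A low share (n open / K cell types)
marks a tissue-specific element; a peak open only in the designated
"matched" cell type is exclusive to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet, overlaps_any
from .signal import ks_compare
from .enrichment import fisher_table

__all__ = [
    "CellTypePanel",
    "score_specificity",
    "specificity_by_bin",
    "exclusivity_test",
    "qq_compare",
]


@dataclass
class CellTypePanel:
    """K named open-chromatin region sets, one flagged as the matched cell type."""

    sets: dict[str, RegionSet]
    matched: str | None = None

    def __post_init__(self) -> None:
        if len(self.sets) < 2:
            raise ValueError("panel needs at least two cell types")
        if self.matched is not None and self.matched not in self.sets:
            raise ValueError(f"matched cell type {self.matched!r} not in panel")

    @property
    def k(self) -> int:
        return len(self.sets)

    @classmethod
    def from_directory(
        cls, directory: str | Path, genome: Mapping[str, int], manifest: str = "manifest.tsv"
    ) -> "CellTypePanel":
        """Load per-cell-type BED files via a manifest TSV (name, path, matched)."""
        from .regions import read_bed

        directory = Path(directory)
        man = pd.read_csv(directory / manifest, sep="\t")
        sets = {}
        matched = None
        for _, row in man.iterrows():
            sets[row["name"]] = read_bed(directory / row["path"], row["name"], genome)
            if bool(row.get("matched", False)):
                matched = row["name"]
        return cls(sets, matched)


def score_specificity(peaks: RegionSet, panel: CellTypePanel) -> pd.DataFrame:
    """Per-peak openness counts across the panel.

    Columns: ``n_open`` (0..K), ``share`` (n/K), ``exclusive_to_matched``
    (open in exactly one cell type, and that one is the matched one).
    """
    if panel.k == 0:
        raise ValueError("empty panel")
    open_in = {
        name: overlaps_any(peaks, ct_set) for name, ct_set in panel.sets.items()
    }
    mat = np.column_stack(list(open_in.values()))
    n_open = mat.sum(axis=1)
    exclusive = np.zeros(len(peaks), dtype=bool)
    if panel.matched is not None:
        exclusive = (n_open == 1) & open_in[panel.matched]
    return pd.DataFrame(
        {
            "n_open": n_open,
            "share": n_open / panel.k,
            "exclusive_to_matched": exclusive,
        },
        index=pd.Index(peaks.ids, name="id"),
    )


def specificity_by_bin(
    profile: pd.DataFrame,
    bins,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean openness share per magnitude bin with a seeded bootstrap CI.

    ``bins`` is a :class:`~epirewire.differential.RankedPeakBins` over the
    same peaks scored in ``profile``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in sorted(bins.table["bin"].unique()):
        ids = bins.bin_ids(int(b))
        shares = profile.loc[profile.index.intersection(ids), "share"].to_numpy()
        if len(shares) == 0:
            raise ValueError(f"bin {b} has no scored peaks")
        boots = shares[rng.integers(0, len(shares), size=(n_boot, len(shares)))].mean(axis=1)
        rows.append(
            {
                "bin": int(b),
                "mean_share": float(shares.mean()),
                "ci_lo": float(np.percentile(boots, 2.5)),
                "ci_hi": float(np.percentile(boots, 97.5)),
                "n": len(shares),
            }
        )
    return pd.DataFrame(rows)


def exclusivity_test(
    exclusive_a: Sequence[bool], exclusive_b: Sequence[bool]
) -> dict:
    """Fisher 2x2 test of matched-cell-type exclusivity between two peak subsets."""
    a = np.asarray(exclusive_a, dtype=bool)
    b = np.asarray(exclusive_b, dtype=bool)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both subsets must be non-empty")
    table = (int(a.sum()), int((~a).sum()), int(b.sum()), int((~b).sum()))
    orr, p = fisher_table(*table)
    return {
        "a_exclusive": table[0], "a_other": table[1],
        "b_exclusive": table[2], "b_other": table[3],
        "odds_ratio": orr, "p": p,
    }


def qq_compare(scores_a: Sequence[float], scores_b: Sequence[float]) -> pd.DataFrame:
    """Paired quantiles (1..99th percentiles, linear/type-7 interpolation).

    Also reports the two-sample KS comparison in frame attrs
    (``ks_D``, ``ks_p``).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("each sample needs n >= 10 for a quantile comparison")
    pct = np.arange(1, 100)
    qa = np.percentile(a, pct, method="linear")
    qb = np.percentile(b, pct, method="linear")
    out = pd.DataFrame({"percentile": pct, "q_a": qa, "q_b": qb})
    d, p = ks_compare(a, b)
    out.attrs["ks_D"] = d
    out.attrs["ks_p"] = p
    return out
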