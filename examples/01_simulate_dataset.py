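"""Generate a desk-scale synthetic two-state epigenome study.

The generator plants known truth at every level: transcript regulation
directions, promoter chromatin prototype classes, differential H3K27ac
peaks, TF binding, super-enhancer agglomerates, methylation and a
cell-type open-chromatin panel.  Everything is reproducible from the seed.
"""

from epirewire.synthetic import SyntheticConfig, generate

cfg = SyntheticConfig(
    n_chroms=2, chrom_length=4_500_000, n_transcripts=300,
    n_peaks=600, n_superenhancers=6, n_celltypes=6,
)
ds = generate(cfg, seed=7)

print("genome:", ", ".join(f"{c}={ln:,} bp" for c, ln in ds.genome.items()))
print("transcripts by direction:",
      ds.truth.transcripts["direction"].value_counts().to_dict())
print("peaks by direction:      ",
      ds.truth.peaks["direction"].value_counts().to_dict())
print("TF binding sites:", len(ds.tf_sites))
print("super-enhancer agglomerates:", len(ds.truth.superenhancers),
      "| dynamics:", ds.truth.superenhancers["dynamics"].value_counts().to_dict())
print("coverage tracks:", len(ds.tracks), "(5 marks x 2 states x 2 replicates)")

# ds.write("scratch/synthetic_study")  # emits BED/bedGraph/TSV + truth.json
# Directions are planted relative to the oncogene-high state: a "correlated"
# transcript or peak is higher in the high state and loses signal on knockdown.
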