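# sexscan

**Does a gonochoristic species have sex-specific genomic regions?**

`sexscan` is a Python library for deciding whether a genome carries
sex-linked sequence — a Y/W chromosome, or hemizygous X/Z-like regions —
from three independent evidence channels, and for the equally important
negative call: concluding that strongly sex-biased gene expression does
*not* reflect a sex chromosome. It is aimed at researchers working on
emerging model organisms (tardigrades, other micro-invertebrates) where
karyotypes are unknown, sequencing is short-read, and the only inputs
are sex-separated RNA-Seq and low-coverage genome sequencing.

## The three evidence channels

**1. Window enrichment of sex-biased transcripts.** Genes that are
significant DEGs (BH FDR < 0.05) with a pseudocount fold change
log2((TPM_M + 0.1)/(TPM_F + 0.1)) beyond 10× form per-sex biased gene
sets. Windows of 200 kbp (100 kbp steps) slide across the assembly;
each window's biased-gene count is tested against the genome-wide rate
with a one-sided Fisher exact test (hypergeometric tail), BH-corrected
across windows, and called enriched at *Q* < 0.01. Enriched windows
merge into candidate regions.

**2. Sex-compared genome coverage.** Sequencing depth in 10 kbp bins,
normalized per sample by the median over all bins, is averaged per sex.
A bin near 1 in both sexes is autosomal; near 0.5 in males and 1 in
females it is hemizygous in males (X-like); near 0 in one sex it is
sex-specific (Y/W-like). Bands are explicit and configurable.

**3. The k-mer genome scan (P_VSC_UK).** For each contig, with
canonical 15-mers counted over the assembly and over each sex's pooled
reads:

```
SC      = contig k-mers occurring exactly once in the assembly
VSC     = SC present in the carrier sex's trusted read k-mers (count >= 2)
VSC_UK  = VSC absent from the opposite sex's trusted read k-mers
P_VSC_UK = 100 * |VSC_UK| / |VSC|
```

P_VSC_UK approaches 100 for a contig present in one sex only and 0 for
shared sequence. The scan runs female-to-male (XY direction, flags Y
candidates) and male-to-female (ZW direction, flags W candidates), with
flagging at P_VSC_UK > 80 for contigs ≥ 1 kb. A joint diagnostic
detects the anomaly where many contigs sit near 50% in *both*
directions — the signature of individual variability rather than sex
linkage.

A verdict combines the channels: `XY_candidate` / `ZW_candidate` on
concordant k-mer and coverage evidence, `no_sex_specific_regions` when
the genomic channels are clean regardless of expression bias, and
`inconclusive` on conflict or missing genomic data.

The package also ships a first-class synthetic-study generator
(`sexscan.simulate`) that builds assemblies, annotations,
negative-binomial RNA-Seq counts, Poisson coverage, and per-sex k-mer
tables under declared XY / ZW / no-sex-chromosome architectures with
machine-readable ground truth, so every stage is validated by parameter
recovery.

## Worked example

```python
import sexscan as sx

# a genuine XY genome: 4 autosomes + X + Y, 4 male / 3 female samples
xy = sx.run_all(sx.SimConfig(seed=6, architecture="XY"))
print(xy.verdict.architecture_call)
print(xy.verdict.evidence["ygs"]["flagged_XY_screened"])

# the instructive case: clustered male-biased expression, no sex chromosome
none = sx.run_all(sx.SimConfig(
    seed=6, architecture="NONE", n_autosomes=10,
    frac_biased_male=0.10, frac_biased_female=0.0,
    biased_opposite_scale=0.001,
    bias_cluster_scaffolds=("scaffold0001", "scaffold0002"),
))
print(none.verdict.architecture_call)
```

prints

```
XY_candidate
['scaffold0006']
no_sex_specific_regions
```

In the first study the simulated Y (`scaffold0006`) is flagged at
P_VSC_UK = 100 in the XY direction only, X bins classify hemizygous in
males, and the verdict is `XY_candidate`. In the second, the expression
channel finds genuinely enriched male-biased windows on the two cluster
scaffolds — but their coverage is ~1.0 in both sexes and no contig is
k-mer-flagged, so the verdict is `no_sex_specific_regions`: expression
bias alone never implies a sex chromosome. The scripts in `examples/`
walk through each channel separately with printed output.

`sx.run_all(cfg, out_dir=...)` additionally writes a deterministic
report bundle: FASTA assembly, BED gene/region intervals, TSV tables
for every stage, and JSON truth/verdict records.

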