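# Methods

This note documents the models, defaults, and numerical choices behind
`sexscan`, and what the synthetic validation does and does not
demonstrate about real data.

## Detection model

The package treats "does this species have sex-specific genomic
regions?" as three separable questions with separable data:

1. *Is sex-biased expression spatially clustered?* — answered by the
   window-enrichment scan on RNA-Seq.
2. *Does any genomic region have sex-dependent copy number?* —
   answered by the coverage scan on sex-separated genome sequencing.
3. *Does any contig contain sequence absent from one sex?* — answered
   by the k-mer scan on pooled per-sex reads.

Only (2) and (3) can establish a sex chromosome. (1) is deliberately
subordinate in the verdict: sex-limited transcription of shared
sequence (e.g. sperm genes) produces exactly the enrichment signal of
(1) with null signals in (2) and (3), and the pipeline's verdict logic
encodes that asymmetry — `no_sex_specific_regions` requires clean
genomic channels and ignores expression, while an `XY_candidate`
requires k-mer flags and/or hemizygous/specific coverage in the male
direction. If both the coverage and k-mer stages are skipped the
verdict is always `inconclusive`; expression can never promote itself
to a chromosome call.

### Expression stage

TPM is the standard length-normalized quantity (columns sum to 1e6).
The fold change used for the 10× filter is
`log2((mean_M TPM + 0.1) / (mean_F TPM + 0.1))` with arithmetic per-sex
means; the pseudocount keeps sex-limited genes finite and is the only
fold-change definition used anywhere.

The built-in differential-expression test is a Welch t per gene on
`log2(normalized count + 1)`, where counts are divided by
median-of-ratios size factors (geometric-mean reference over
everywhere-nonzero genes, rescaled to geometric mean 1). Size factors
rather than totals matter here: when ~10% of genes carry a 16× effect
in one sex, total-count (or TPM) scaling shifts every null gene and
inflates the empirical FDR to ~0.17 in our calibration scenario;
median-of-ratios normalization restores FDR ≈ 0.03 at sensitivity
≈ 0.96. This mirrors the normalization of the standard NB-model DE
tools, whose full shrinkage machinery is intentionally out of scope —
the DE interface is pluggable, and an externally produced table
(`gene_id, log2fc_mf, pvalue[, fdr]`) can be ingested instead
(`expression.read_de_table`). Everything downstream consumes only
(log2FC, FDR).

Degenerate genes (zero variance in both sexes) get p = 1 when the
means agree and p = 0 when they differ exactly.

### Window enrichment

Windows are emitted at every multiple of the step below the scaffold
length and truncated at the scaffold end, so a 150 kb scaffold at
200 kb/100 kb settings yields two windows (0–150 kb and 100–150 kb)
and the total window count is Σ ceil(length/step). A gene belongs to
every window it overlaps by ≥ 1 bp; multi-window genes count in each.

The per-window test is the one-sided (enrichment) Fisher exact test,
computed as the hypergeometric tail P(X ≥ k) with the de-duplicated
genome-wide gene universe as the population; margins therefore sum to
the universe size for every window. BH correction runs across all
windows of one sex's analysis (the sexes are corrected separately);
windows with zero genes get p = 1 and stay in the BH family, which is
deterministic and slightly conservative. Enriched windows merge into
maximal regions by interval union (bookended intervals merge).

### Coverage scan

Raw depth per 10 kbp bin per sample is divided by that sample's median
over all bins (zero-depth bins included in the median; a sample with
zero median raises). Classification bands on per-sex mean normalized
depth:

| label | male mean | female mean |
|---|---|---|
| autosomal | 0.8–1.2 | 0.8–1.2 |
| hemizygous_M | 0.35–0.65 | 0.8–1.2 |
| specific_M | in half or diploid band | ≤ 0.1 |

(female labels mirrored; anything else is `ambiguous`; checked in the
order specific > hemizygous > autosomal). The ±30%-wide bands absorb
Poisson noise at the 15–20× depths the pipeline targets; at 10 kbp
bins and 20× the relative SE per bin is ~0.2%, so classification noise
is negligible and the bands mostly guard against mapping and
repeat-content artifacts in real data.

### k-mer scan

k-mers are packed 2 bits/base into uint64 (k ≤ 31), stored canonically
as min(kmer, revcomp); k must be odd so no k-mer is its own reverse
complement and canonicalization is tie-free. Windows containing
non-ACGT characters are skipped entirely. Counting and the set algebra
(single-copy → validated → unmatched) run on sorted unique code
arrays.

Defaults: k = 15; trusted read k-mers require count ≥ 2 (removes
singleton sequencing-error k-mers at ~20× without erasing hemizygous
signal, whose expected count is ~10); flag threshold P_VSC_UK > 80;
contig length ≥ 1,000 bp; and contigs with fewer than 20 validated
k-mers are reported but never flagged, because a percentage on a tiny
denominator is meaningless. The bidirectional anomaly flag fires when
more than 10% of contigs have both directional percentages in
[40, 60] — sequence apparently specific to both sexes at once, which
sex linkage cannot produce and individual heterozygosity can.

### Verdict

Contigs flagged in both directions are screened out before the verdict
(same artifact class as the anomaly). Coverage counts as XY evidence
when any bin is `specific_M` or ≥ 1% of bins are `hemizygous_M` (the
1% floor keeps isolated misclassified bins from driving the call; a
real X at plausible genome fractions clears it easily). Concordant
evidence gives `XY_candidate`/`ZW_candidate`, conflicting directions
give `inconclusive`, and clean genomic channels give
`no_sex_specific_regions`.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume,
under a study design of 4 male / 3 female RNA-Seq replicates and ~20×
genome sequencing:

* scaffolds are i.i.d.-uniform random nucleotide sequences (default
  4 autosomes of 200 kb; XY/ZW add an X/Z and a Y/W of 200 kb with
  copy numbers 1/2 and 1/0 in the appropriate sexes);
* genes are non-overlapping intervals, 30 per scaffold, lengths
  uniform in 300–3,000 bp (so TPM length-normalization is exercised),
  placed with multinomially distributed gaps;
* expression: per-gene lognormal baseline (median 100 counts,
  σ = 1.2), NB counts with dispersion 0.05; biased genes multiply the
  favored sex's mean by `bias_fold` (default 16) and the other sex's
  by `biased_opposite_scale` (default 1.0, preserving an exact
  mean-ratio contract; 0.001 emulates sex-limited genes, which real
  male-biased sperm genes are — at transcriptome scale only a few
  permille of them leak above TPM 10 in females). Biased genes land on
  declared
  cluster scaffolds with probability 0.9, else uniformly, and are
  never drawn from single-sex scaffolds (whose genes are sex-limited
  by construction);
* coverage: per-bin depth ~ Poisson(mean_depth · copies/2 · width)/width;
* read k-mers: every canonical k-mer of the scaffolds a sex carries,
  count ~ Poisson(mean_depth · copies/2) truncated at 1, plus a
  1%-of-mass admixture of uniformly random novel singleton "error"
  k-mers.

Each stage draws from its own child generator of the config seed
(`default_rng([seed, stage])`), so outputs are byte-reproducible and
independent of call order.

**What the generator does not emulate** — and hence what passing
parameter-recovery tests do not certify about real data: read-level
error and mapping ambiguity (coverage is drawn, not aligned), repeats
and low-complexity sequence (assemblies are uniform-random, so nearly
all k-mers are single-copy and cross-scaffold collisions are rare),
individual heterozygosity (read k-mer tables are genome-derived; the
both-direction ~50% anomaly is exercised in tests by thinning tables,
not by a population model), GC/coverage bias, and transcript-level
quantification uncertainty. On real data the same thresholds will see
noisier margins; the bands and the min-VSC floor exist for exactly
that reason.

## Problem sizes used for validation

Parameter recovery and calibration run at deliberately small scale
chosen for tight analytic expectations: XY recovery uses the default
6-scaffold × 200 kb genome over 20 replicates; the clustered-bias
scenario uses 10 autosomes with 10% male-biased genes (cluster windows
then carry ~13/30 biased genes against a genome-wide 30/300 rate,
putting the hypergeometric tail near 1e-8 and making ≥ 90%
concentration a robust expectation); DE calibration uses 2,000 genes
over 20 replicates. The cross-sex fraction is evaluated at
transcriptome scale (2,000 genes) because with tiny gene universes a
single stray opposite-sex read exceeds TPM 10 — a discreteness
artifact, not leakage.

## Known limitations

* The built-in DE test is a two-sample Welch t, not an NB GLM; at 4v3
  replicates it is adequately calibrated on the generator's data but
  underpowered for subtle effects — ingest a DESeq2/edgeR table for
  real studies.
* The k-mer machinery is capacity-limited to k ≤ 31 by the 2-bit
  uint64 packing (k = 15 default).
* Coverage ingestion expects per-bin depth tables; BAM reduction is
  upstream of this package.
* The verdict is a rule-based combination, not a probabilistic model;
  its thresholds (flag screening, the 1% hemizygous floor) are
  documented above and exposed as parameters.
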