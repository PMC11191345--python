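"""Quantify expression, call differential expression, and select biased genes.

Counts become TPM (length-normalized, 1e6 per sample), the built-in
Welch test on size-factor-normalized counts yields per-gene FDR, and
genes that are significant (FDR < 0.05) with a pseudocount TPM fold
change above 10x form the male- and female-biased sets. The cross-sex
fraction asks how many of those genes still show appreciable (> TPM 10)
expression in the other sex — near zero for genuinely sex-limited
genes.
"""

import sexscan as sx
from sexscan import expression

cfg = sx.SimConfig(
    seed=2, architecture="XY", biased_opposite_scale=0.001,
    frac_biased_male=0.1, frac_biased_female=0.03,
    n_autosomes=2, scaffold_length_bp=2_000_000,
    sex_scaffold_length_bp=2_000_000, n_genes_per_scaffold=500,
)
_, annotation, truth = sx.simulate.simulate_genome(cfg)
em = sx.simulate.simulate_expression(annotation, truth, cfg)

table = expression.de_test(em)
sets = expression.select_biased(table)
frac = expression.cross_sex_fraction(sets, em.tpm, em.sex)

print(f"genes: {len(table)}  significant DEGs: {int(table['significant'].sum())}")
print(f">10x biased:  male {len(sets.male_biased)}  female {len(sets.female_biased)}")
print(f"truth biased: male {len(truth.biased_gene_ids['M'])} (+Y-resident genes)  "
      f"female {len(truth.biased_gene_ids['F'])}")
print(f"cross-sex fraction (male-biased genes with female TPM > 10): {frac['M']:.3f}")
# A small cross-sex fraction means the male-biased genes are close to
# sex-exclusive in expression, as expected for sperm-related genes.
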