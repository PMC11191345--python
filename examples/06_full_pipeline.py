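"""Run every stage end to end and combine the evidence into a verdict.

Two contrasting studies: a genuine XY genome, and the instructive case
of a genome with strongly male-biased, spatially clustered expression
but no sex-specific sequence at all — where the coverage and k-mer
channels must overrule the expression signal.
"""

import sexscan as sx

xy = sx.run_all(sx.SimConfig(seed=6, architecture="XY"))
print("XY study       ->", xy.verdict.architecture_call)
print("  YGS flags (screened):", xy.verdict.evidence["ygs"]["flagged_XY_screened"])
print("  hemizygous_M bin fraction:",
      round(xy.verdict.evidence["coverage"]["frac_hemizygous_M"], 3))

none = sx.run_all(
    sx.SimConfig(
        seed=6, architecture="NONE", n_autosomes=10,
        frac_biased_male=0.10, frac_biased_female=0.0,
        biased_opposite_scale=0.001,
        bias_cluster_scaffolds=("scaffold0001", "scaffold0002"),
    )
)
print("biased-NONE    ->", none.verdict.architecture_call)
print("  enriched male windows:",
      none.verdict.evidence["enriched_expression"]["M"]["n_bins"])
print("  YGS flags:", none.verdict.evidence["ygs"]["flagged_XY"])
print("  region coverage (M, F):",
      [round(v, 3) for v in none.region_coverage[["mean_M", "mean_F"]].mean()])
# Expression bias alone never implies a sex chromosome: with normal
# coverage in both sexes and no k-mer flags the verdict stays
# no_sex_specific_regions despite the enriched male windows.
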