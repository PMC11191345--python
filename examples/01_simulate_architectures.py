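"""Generate synthetic studies under XY, ZW, and no-sex-chromosome architectures.

Each run produces an assembly, a gene annotation, and a ground-truth
record naming the sex-specific scaffold (the Y or W, present in one sex
only), the hemizygous scaffold (the X or Z, single copy in the
heterogametic sex), and the genes assigned a sex-biased expression
effect.
"""

import sexscan as sx

for arch in ("XY", "ZW", "NONE"):
    cfg = sx.SimConfig(seed=1, architecture=arch)
    assembly, annotation, truth = sx.simulate.simulate_genome(cfg)
    print(f"--- architecture {arch} ---")
    print(f"scaffolds: {len(assembly.sequences)}  genes: {len(annotation)}")
    print(f"sex-specific: {sorted(truth.sex_specific_scaffolds) or '-'}")
    print(f"hemizygous:   {sorted(truth.hemizygous_scaffolds) or '-'}")
    print(f"biased genes: M={len(truth.biased_gene_ids['M'])} "
          f"F={len(truth.biased_gene_ids['F'])}")

# Under NONE there is nothing sex-linked to find: both truth sets are
# empty and every scaffold is diploid in both sexes.
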