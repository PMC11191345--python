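"""Classify genome bins from sex-compared sequencing coverage.

Depth in 10 kbp bins is normalized by each sample's median, then the
per-bin male and female means are compared against explicit bands:
~1 in both sexes = autosomal; ~0.5 in males with ~1 in females =
hemizygous in males (an X); ~0 in females = male-specific (a Y).
"""

import sexscan as sx
from sexscan import coverage

cfg = sx.SimConfig(seed=4, architecture="XY")
assembly, annotation, truth = sx.simulate.simulate_genome(cfg)
cm = sx.simulate.simulate_coverage(assembly, truth, cfg)
labels = coverage.classify_bins(cm)

print(labels.groupby("scaffold")["label"]
      .agg(lambda s: s.value_counts().idxmax()).to_string())
print("\nbin label counts:", labels["label"].value_counts().to_dict())
(y,) = truth.sex_specific_scaffolds
(x,) = truth.hemizygous_scaffolds
print(f"truth: Y = {y} (expect specific_M), X = {x} (expect hemizygous_M)")
# The dominant label per scaffold recovers the simulated copy-number
# architecture; autosomes stay autosomal.
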