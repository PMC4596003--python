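"""Estimate telomere content from reads and the tumour/normal ratio.

A read is telomeric when it contains (TTAGGG)x3 or (CCCTAA)x3; counts are
normalized by genome-wide mean coverage, and the tumour/normal ratio of
normalized counts summarizes somatic telomere change.
"""

import numpy as np

from chromocat import count_telomeric_reads, telomere_ratio
from chromocat.simulate import simulate_telomere_reads

rng = np.random.default_rng(3)
tumor_reads, _ = simulate_telomere_reads(10_000, 100, telomere_fraction=0.01, rng=rng)
normal_reads, _ = simulate_telomere_reads(10_000, 100, telomere_fraction=0.02, rng=rng)

tumor = count_telomeric_reads(tumor_reads, mean_coverage=74.0)
normal = count_telomeric_reads(normal_reads, mean_coverage=39.0)
ratio = telomere_ratio(tumor, normal)

print(f"tumour:  {tumor.n_telomeric_reads}/{tumor.n_total_reads} telomeric reads "
      f"at 74x -> normalized {tumor.normalized:.2f}")
print(f"normal:  {normal.n_telomeric_reads}/{normal.n_total_reads} telomeric reads "
      f"at 39x -> normalized {normal.normalized:.2f}")
print(f"tumour/normal telomere ratio: {ratio:.3f}")
# A ratio below 1 indicates somatic telomere shortening in the tumour.
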