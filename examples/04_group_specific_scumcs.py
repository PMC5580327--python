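"""Label scUMCs specific to one of two cell lineages.

Builds two small groups of methylomes around three scUMC loci: one locus
unmethylated only in group A, one only in group B, one in both. The
labelling rule requires every covered sample of the low group at or
below 10% and the other group's mean at or above 30%.
"""
import numpy as np
import pandas as pd

from scumc import GenomicRegion, Methylome, group_specific

LOCI = [1000, 5000, 9000]  # A-specific, B-specific, shared


def build(sample_id, low_at):
    pos = np.arange(0, 10_000, 100)
    ratios = np.full(pos.size, 0.85)
    for p in low_at:
        ratios[pos == p] = 0.03
    return Methylome(sample_id, pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "meth_ratio": ratios, "coverage": 30}
    ))


group_a = [build(f"esc_{i}", [1000, 9000]) for i in range(3)]
group_b = [build(f"blood_{i}", [5000, 9000]) for i in range(4)]
scumcs = [GenomicRegion("chr1", p, p + 2) for p in LOCI]

for call in group_specific(scumcs, group_a, group_b):
    print(f"{call.region.chrom}:{call.region.start}-{call.region.end}  "
          f"mean_A={call.mean_a:.2f} mean_B={call.mean_b:.2f}  {call.label}")
# A_specific / B_specific loci are candidates for lineage-defining
# regulatory sites; shared loci are constitutively protected CpGs.
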