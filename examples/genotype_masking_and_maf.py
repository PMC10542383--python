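"""Record-level genotype masking and rare/common MAF classification.

Round-trips a genotype matrix through VCF, masks genotypes by depth
(< 10x, or > 1.65-fold the sample mean) and heterozygote allelic balance
(alt fraction outside [0.25, 0.8]), and classifies SNP frequencies into
the rare (MAF < 0.01) / common (MAF > 0.05) classes used to compare
call sets made against two different references.
"""

import tempfile
from pathlib import Path

import numpy as np

import refbias as rb

gm = rb.GenotypeMatrix(
    sample_ids=["s1", "s2"],
    chrom=np.array(["chr1"] * 3, dtype=object),
    pos=np.array([99, 199, 299]),
    ref=np.array(["A", "C", "T"], dtype=object),
    alt=np.array(["G", "G", "A"], dtype=object),
    genotypes=np.array([[1, 1, 2], [1, 0, 2]], dtype=np.int8),
    depth=np.array([[30, 9, 31], [28, 33, 80]]),
    ad_ref=np.array([[15, 5, 0], [25, 33, 0]]),
    ad_alt=np.array([[15, 4, 31], [3, 0, 80]]),
)

with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "cohort.vcf"
    rb.write_vcf(gm, path)
    back = rb.read_biallelic_vcf(path)
    print("VCF round-trip lossless:",
          bool((back.genotypes == gm.genotypes).all()))

masked = rb.mask_genotypes(gm, {"s1": 30.0, "s2": 30.0})
print("genotypes before masking:\n", gm.genotypes)
print("after masking (-1 = missing):\n", masked.genotypes)
# s1 site2 lost to DP=9 (< 10x); s2 site1 lost to alt fraction 3/28 < 0.25;
# s2 site3 lost to DP=80 > 1.65 x 30

print("allele frequencies after masking:",
      np.round(masked.alt_allele_frequencies(), 3))
for fa, fb in [(0.005, 0.005), (0.008, 0.20), (0.03, None)]:
    print(f"  freq_cn1={fa} freq_chm13={fb}: "
          f"{rb.classify_maf_pair(fa, fb)}")
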