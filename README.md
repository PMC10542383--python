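# refbias

Reference-bias and archaic-introgression analyses for population
genomics, built for the comparison of call sets and alignments made
against two complete human reference assemblies (an East Asian diploid
T2T reference versus CHM13).

When the same cohort is mapped to two references, the differences are
not noise: reads from non-reference alleles go missing, rare-SNP calls
flip between call sets, archaic-introgression signals appear or vanish
with the reference, and sequence present in only one assembly shows up
as reference-specific read pileups. `refbias` packages the statistics
used to measure these effects:

- **ABBA-BABA introgression scan** — on the quartet ((P1, P2), P3, O),
  site weights ABBA = (1−p1)p2p3(1−p4), BABA = p1(1−p2)p3(1−p4);
  Patterson's D = (ΣABBA−ΣBABA)/(ΣABBA+ΣBABA) and the modified statistic
  f_d = Σ(ABBA−BABA) / Σ(ABBA−BABA)|p2,p3→max(p2,p3) in 10-kb windows
  (1-kb step, ≥ 30 good sites); outlier windows (f_d > 0.35) merge into
  putative introgression regions (pIRs, ≥ 20 kb).
- **Depth analyses** — specific mapping regions (runs of reference-
  specific coverage above half the genome-wide mean, ≥ 100 bp), and
  presence/absence genotyping of an insertion from scaled depth
  (region mean / genome mean: < 0.4 absent, 0.4-0.8 heterozygous,
  > 0.8 homozygous) with per-population allele frequencies.
- **Weir-Cockerham Fst** — per-SNP θ (the vcftools estimator), windowed
  as a ratio of summed variance components (10 kb / 2-kb step),
  empirical outlier p-values p = (1+#{null ≥ x})/(1+N) against an
  intergenic null, and differentiated-region calls (> 50% of SNVs with
  p < 0.05).
- **Heterozygosity bubbles** — SV counts h per 500-kb window between two
  haplotypes ("hete" when h ≥ 2), exported as a GFA 1.0 bubble graph.
- **Mapping-bias correlation** — Pearson r between ΔFst to the two
  reference populations and the per-population difference in unique
  mapping (or clipping) rates.
- **Synthetic data** — every input above generated with planted truth
  (introgression tracts, SMRs, insertion genotypes, SV positions,
  linearly coupled mapping statistics) from a single seed.

Genotype-record utilities (depth/allelic-balance masking, rare/common
MAF classification, VCF/BED/depth/popmap readers and writers) round out
the pipeline.

## Worked example

`examples/introgression_scan.py` simulates a 600-kb quartet panel
(10 African + 20 East Asian + 1 archaic + 5 outgroup genomes) with two
planted full-replacement tracts, scans it and calls pIRs:

```
simulated 3000 bi-allelic SNPs for 36 samples
good (polarizable) sites: 2986
595 windows; genome-wide mean D = 0.185
putative introgression regions (pIRs):
  chr1:145000-217000  length=72000  max_fd=1.00  windows=63
  chr1:392000-477000  length=85000  max_fd=1.00  windows=75
planted tracts: ((150000, 210000), (400000, 470000))
```

Both planted tracts (150-210 kb and 400-470 kb) are recovered, with
boundaries blurred by at most one window size; max f_d ≈ 1 inside the
tracts means the ABBA excess matches complete donor replacement. The
positive genome-wide mean D reflects the planted gene flow.

The other scripts in `examples/` each demonstrate one capability in the
same style: `smr_and_insertion_genotyping.py` (depth tracks → SMRs and
insertion allele frequencies), `fst_outlier_scan.py` (per-SNP and
windowed Fst, empirical p-values, differentiated regions),
`heterozygosity_bubbles.py` (SV windows → GFA), and
`mapping_bias_correlation.py` / `genotype_masking_and_maf.py`.

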