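# Methods

`refbias` implements, as a reusable and tested library, the analysis
steps used to quantify reference bias between two complete human
assemblies (an East Asian diploid reference, "CN1", and the European
"CHM13") and to scan modern genomes for archaic introgression. All
statistics operate on standard inputs (VCF, population map, per-base
depth, SV tables, mapping-statistic tables); a synthetic-data module
generates every input with known planted truth, which is how the test
suite and the acceptance script exercise the pipeline.

Internal coordinates are 0-based half-open throughout; VCF and
samtools-depth positions are converted on read and back on write, and
BED output is emitted natively.

## ABBA-BABA scan and f_d

Under the four-taxon topology ((P1, P2), P3, O), with per-taxon derived
allele frequencies p1..p4 at a bi-allelic site, the site pattern weights
are

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)

Patterson's D over a window is (ΣABBA - ΣBABA) / (ΣABBA + ΣBABA); its
expectation is zero under incomplete lineage sorting alone. The
introgressed-fraction estimator f_d divides the window's ABBA - BABA
excess by the excess expected under complete replacement of the
recipient by the higher-frequency donor: each site's denominator term is
ABBA - BABA re-evaluated with both p2 and p3 replaced by
p_D = max(p2, p3). (When p1 = p_D the replaced ABBA and BABA terms
cancel and the site contributes zero to the denominator; when p2 = p3
either choice of p_D gives the same value, so no tie-break is needed.)

Polarization: the derived allele is the one not carried by the outgroup
majority. A site is *good* when it is bi-allelic, every taxon has at
least one called allele, and the outgroup minor-allele frequency is at
most 0.1 (default, configurable) — the polarization of a strongly
polymorphic outgroup is not meaningful. Frequencies use non-missing
alleles only.

Windows default to 10 kb with a 1-kb step, anchored at position 0, and
windows with fewer than 30 good sites are discarded; the last partial
window is kept if it clears that filter. f_d is reported only for
windows with D > 0 and is clamped to [0, 1]; windows with D ≤ 0 get
f_d = 0, since the estimator has no meaning there. Outlier windows
(f_d strictly above the 0.35 empirical cutoff, D > 0) merge into
putative introgression regions (pIRs) when they overlap or abut
(gap tolerance 0 by default, configurable); merged regions shorter than
20 kb are dropped.

Window sums are accumulated with a sequential per-site loop over the
window slice rather than a pairwise vector reduction. At these problem
sizes the cost is negligible and the sums are bit-identical to a
straightforward reference loop, which makes exact oracle comparisons
possible.

## Depth analyses

**Specific mapping regions (SMRs).** Given a per-base depth track of
reads mapping to only one of the two references, candidate segments are
maximal runs of bases with specific depth strictly greater than half the
genome-wide mean of the *total* alignment, merged across gaps of at most
`merge_gap` bases (default 0); a segment is retained when its mean depth
still exceeds the half-coverage line and it is at least 100 bp long.
With `merge_gap = 0` the per-base-runs and region-mean readings of the
rule coincide. At Poisson(λ = 30) noise a single base dips below λ/2
about once per ~270 bp, so biologically contiguous regions fragment at
gap 0; a small `merge_gap` (a few bases) bridges those dips. Whether the
half-coverage threshold should use the total or the specific alignment's
mean is ambiguous in the field; the total alignment is the default here,
and the mean is a parameter.

**Insertion genotyping.** A sample's *scaled depth* over an insertion is
the region mean depth divided by the sample's genome-wide mean depth.
Calls: scaled depth in [0.4, 0.8] → heterozygous (closed boundaries),
above 0.8 → homozygous insertion, below 0.4 → absent. Population allele
frequency is (n_het + 2 n_hom) / (2 n_samples); populations with no
genotyped sample report missing.

## Genotype-record filters

Cohort-style masking: a genotype becomes missing when its depth is below
10× or above 1.65× the sample's mean depth; a heterozygote additionally
becomes missing when its alternate-allele fraction
DP_ALT / (DP_REF + DP_ALT) is strictly above 0.8 or strictly below 0.25.
Boundary values are retained because the rules are strict inequalities.
Masking never un-masks: the non-missing count is non-increasing.
Half-calls (e.g. `0/.`) are treated as missing on VCF read. Minor-allele
frequencies are computed from non-missing alleles (AC/AN after masking);
classes are rare (MAF < 0.01), common (MAF > 0.05), intermediate
otherwise, with paired labels (Both-rare, A-rare/B-common, …) for SNPs
called against two references.

## Fst and empirical outliers

Per-site Fst is the two-population Weir & Cockerham (1984) θ computed
from sample sizes, allele frequencies and observed heterozygosity — the
estimator vcftools reports per SNP. The variance components a, b, c are
kept per site; windowed Fst (default 10 kb / 2-kb step) is Σa / Σ(a+b+c),
a ratio of averages, not an average of ratios. Negative per-site values
are retained, so windowed values may be slightly negative. Sites
monomorphic across both populations are skipped.

The genome-wide population-pair matrix (`pairwise_fst_matrix`) uses the
same estimator aggregated over all sites. This is a deliberate,
documented approximation of a multilocus estimator such as adegenet's,
which differs slightly in its weighting. The 1/1000 variant
downsampling with a MAF > 0.01 filter used before building such a matrix
is provided as a seed-deterministic helper.

Empirical outlier p-values use the add-one rank rule against a stated
null set (in the intended use, intergenic SNPs):
p = (1 + #{null ≥ observed}) / (1 + N), so p ∈ (0, 1] and is never zero.
The exact rank convention in the literature this follows is not uniquely
pinned down; the add-one rule is declared rather than inferred. The
plotted significance cutoff is the null 95th percentile
(`empirical_cutoff`). A region is called differentiated when strictly
more than half of its SNVs have p < 0.05; a region with no SNVs fails
with a flag.

## Heterozygosity windows and bubbles

The heterozygosity rate h of a 500-kb non-overlapping window is the
number of SVs (≥ 50 bp by convention, configurable) whose *start* lies
in the window, so Σh equals the SV count and a boundary-spanning SV
counts once (an "overlap" mode is provided as the alternative reading).
Windows with h ≥ 2 are "hete", otherwise "homo". The GFA 1.0 export
collapses maximal homo runs into single segments and renders each hete
window as a two-arm bubble linked to its flanking segments; segments
carry `LN` (length) and `HC` (SV count) tags instead of sequence, which
is what a renderer like Bandage needs to shade bubbles by h. Emitting
actual haplotype sequences is out of scope.

The p-distance of a gapped sequence pair deletes every column containing
a gap — divergence = mismatched bases / (aligned bases − alignment
gaps) — and columns containing an ambiguous base (N) are likewise
excluded, so only {A,C,G,T}×{A,C,G,T} columns count.

## Mapping-bias correlation

For each population m, x = Fst(m, CHS) − Fst(m, CEU) locates m between
the two reference populations, and y is the population mean of
UniqMap_CHM13 − UniqMap_CN1 (percent of reads uniquely mapped to each
reference). Pearson's r over populations is reported; a negative r means
populations closer to CHS map better on the East Asian reference. The
same machinery serves UniqClip with the difference computed
CN1 − CHM13, which flips the expected sign.

## Synthetic data: what it emulates, and what it does not

All generators draw from a single `numpy.random.Generator` seeded by
`SimulationConfig.seed`; identical configs give byte-identical outputs.

**Quartet genotypes.** Per site, an ancestral derived-allele frequency
q ~ Beta(0.2, 0.2) (a realistically U-shaped frequency spectrum,
configurable) drifts independently into each taxon via Beta resampling
with concentration c (default 20 for P1/P2 — sister populations, mild
drift). The donor P3 uses concentration 0.1: a lineage as deeply
diverged as an archaic hominin is effectively fixed at every site, which
is also the regime in which the f_d denominator is a meaningful
replacement bound. The outgroup is fixed ancestral at 95% of sites and
rarely polymorphic otherwise, exercising the polarization filter.
Genotypes are binomial draws per sample. Introgression is a
tract-copying process: inside a planted tract each P2 haplotype is, with
probability γ, drawn from the donor frequency instead of its own. The
background allele, donor allele and copy indicator are drawn
unconditionally, so runs differing only in γ share all other randomness
and in-tract f_d is monotone in γ by coupling, not merely in
expectation. Defaults follow the study panel the scan is designed for:
10 P1, 20 P2, 1 archaic P3, 5 outgroup genomes, and 5 SNPs/kb so 10-kb
windows clear the 30-good-site filter at desk scale.

This is deliberately not a coalescent simulation: there is no
recombination map, no linkage structure within tracts beyond the copying
itself, no mutation model, and no sequencing error. Passing recovery
tests therefore demonstrates the *estimator and caller logic* — that
f_d finds planted replacement and pIR merging reconstructs tract extents
— not performance on real genomes, where ILS, recombination and
low-coverage genotyping add noise sources this generator does not model.

**Depth tracks.** Per-base depth ~ Poisson(λ·e), λ = 30 by default
(`noise="none"` yields the exact expectation instead, for zero-noise
recovery checks). The total track has e = 1; the specific track has
background e = 0.1 (some cross-mapping leakage) and e = 1 inside planted
SMRs — comfortably above the half-coverage calling line, as true
reference-specific sequence would be. Insertion samples get region
tracks with e ∈ {0, 0.5, 1} by planted genotype, either given explicitly
or drawn from per-population allele frequencies under Hardy-Weinberg.
Planted depth regions must not overlap. Real depth tracks carry GC and
mappability waves that are not modeled.

**Mapping statistics** are generated as an exact linear function of the
Fst-difference coordinate plus population-level Gaussian noise, so the
downstream Pearson r is recoverable by construction (|r| = 1 at zero
noise). The helper Fst matrix places populations on a latent 1-D axis,
which is sufficient for the correlation geometry but not a model of real
population structure.

## Calibration choices in the acceptance checks

The ABBA-BABA null check compares |mean window D| to three standard
errors of the window D distribution. That comparison is only valid when
the windows are independent, so the null calibration runs with
non-overlapping windows (step = window) over a 5.2-Mb chromosome
(≥ 500 windows); 1-kb-step windows share 90% of their sites and would
need an effective-sample-size correction instead. Signal recovery uses
five 50-kb tracts on a 1-Mb chromosome at γ = 1 with the default 0.35
cutoff and 20-kb minimum; recall and precision use a 50%-overlap
criterion (of the tract for recall, of the pIR for precision). The SMR
acceptance check reports base-level recall/precision against planted
regions at `merge_gap = 0`, so single-base Poisson dips cost a little
recall (~2-6%) honestly rather than being bridged for the report.

## Numerical and degenerate-input conventions

- D is NaN when a window's ABBA + BABA sum is zero; f_d is NaN when D is
  NaN, 0 when D ≤ 0, clamped to [0, 1] otherwise.
- Frequencies outside [0, 1] raise immediately in the site-pattern
  functions.
- `detect_smr` requires a positive genome-wide mean; the strict `>`
  at exactly half coverage excludes the boundary.
- `scaled_region_depth` counts bases outside the covered range as zero
  and rejects empty regions.
- Weir-Cockerham sites with a zero denominator (a+b+c = 0) report NaN;
  single-individual populations are supported as the degenerate case.
- `empirical_p` on an empty null, `p_distance` with no gap-free columns,
  unsorted windows in `call_pirs`, non-contiguous windows in
  `build_bubble_gfa`, and duplicate samples in a population map all
  raise with specific messages.

## Known limitations

- No block-jackknife Z-scores for genome-wide D, no f-branch statistics,
  no ancient-DNA damage handling: upstream read processing is assumed.
- The library analyses one chromosome per depth track and per pIR call;
  multi-chromosome orchestration is the caller's loop.
- BAM/CRAM are not read; depth tracks and mapping statistics arrive as
  text tables produced by standard tools (samtools depth or bedGraph).
- The bubble GFA encodes window topology and h, not haplotype sequence.
- Problem sizes in the tests and acceptance script (0.4-5.2 Mb
  chromosomes, 100-kb depth tracks, 500-sample cohorts) are the
  package's chosen desk-scale study conditions; the algorithms are
  linear in sites/bases and run unchanged on full-genome inputs.
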