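"""Readers, writers and record-level filters for the standard formats.

All coordinates are 0-based half-open internally.  VCF and samtools-depth
input is 1-based and converted on read; BED output is emitted 0-based
half-open directly, and VCF output converts back to 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .depth import DepthTrack

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "read_biallelic_vcf",
    "write_vcf",
    "mask_genotypes",
    "classify_maf",
    "classify_maf_pair",
    "read_popmap",
    "read_depth",
    "read_bedgraph",
    "write_bed",
    "read_mapping_stats",
    "region_to_bed_coords",
]

MAPPING_STAT_COLUMNS = (
    "sample",
    "population",
    "uniqmap_cn1",
    "uniqmap_chm13",
    "uniqclip_cn1",
    "uniqclip_chm13",
)


@dataclass
class GenotypeMatrix:
    """Bi-allelic SNP genotypes for a set of samples.

    ``genotypes`` holds the alternate-allele count per sample per site
    (0, 1, 2) with ``MISSING`` (-1) for uncalled genotypes.  ``pos`` is
    0-based.  ``depth``/``ad_ref``/``ad_alt`` are the optional per-genotype
    total and allelic depths used by :func:`mask_genotypes`.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_samples, n_sites = len(self.sample_ids), len(self.pos)
        if self.genotypes.shape != (n_samples, n_sites):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != "
                f"({n_samples} samples, {n_sites} sites)"
            )
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be 0, 1, 2 or MISSING")
        for name in ("depth", "ad_ref", "ad_alt"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n_samples, n_sites):
                raise ValueError(f"{name} shape mismatch")
        for chrom in pd.unique(self.chrom):
            p = self.pos[self.chrom == chrom]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        take = lambda a: None if a is None else a[:, index]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[:, index],
            depth=take(self.depth),
            ad_ref=take(self.ad_ref),
            ad_alt=take(self.ad_alt),
        )

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        take = lambda a: None if a is None else a[idx, :]
        return GenotypeMatrix(
            sample_ids=list(samples),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            genotypes=self.genotypes[idx, :],
            depth=take(self.depth),
            ad_ref=take(self.ad_ref),
            ad_alt=take(self.ad_alt),
        )

    def alt_allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing genotypes.

        NaN where every genotype is missing (AC/AN after masking).
        """
        called = self.genotypes != MISSING
        an = 2 * called.sum(axis=0).astype(float)
        ac = np.where(called, self.genotypes, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / an, np.nan)


@dataclass(frozen=True)
class PopulationMap:
    """sample -> (population, super-population) assignment.

    Populations partition the samples: every sample maps to exactly one
    population.
    """

    population: Mapping[str, str]
    super_population: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError("empty population map")

    @property
    def samples(self) -> list[str]:
        return list(self.population)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.population.values()))

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.population.items() if p == population]

    def super_population_of(self, sample: str) -> str | None:
        return self.super_population.get(sample)


def read_biallelic_vcf(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read bi-allelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records, indels and non-SNPs are skipped.  Missing and
    half-called genotypes become ``MISSING``.  ``region`` uses the
    1-based-inclusive ``chrom:start-end`` convention of VCF tooling.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise OSError(f"no such VCF: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    adr: list[np.ndarray] = []
    ada: list[np.ndarray] = []
    has_dp = has_ad = True
    it = vcf(region) if region else vcf
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in it:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        chroms.append(v.CHROM)
        positions.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gts.append(gt_code[v.gt_types])
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if dp is None:
            has_dp = False
        else:
            dps.append(dp[:, 0])
        if ad is None:
            has_ad = False
        else:
            adr.append(ad[:, 0])
            ada.append(ad[:, 1])
    vcf.close()
    if not positions:
        warnings.warn(f"no bi-allelic SNPs in {path}", stacklevel=2)
        empty = np.empty((len(samples), 0))
        return GenotypeMatrix(
            sample_ids=samples,
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            alt=np.array([], dtype=object),
            genotypes=empty.astype(np.int8),
        )
    stack = lambda cols: np.column_stack(cols)
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=stack(gts),
        depth=stack(dps) if has_dp and dps else None,
        ad_ref=stack(adr) if has_ad and adr else None,
        ad_alt=stack(ada) if has_ad and ada else None,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as minimal VCFv4.2 (GT, and DP/AD if present)."""
    with_depth = gm.depth is not None and gm.ad_ref is not None and gm.ad_alt is not None
    fmt = "GT:DP:AD" if with_depth else "GT"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_depth:
        lines += [
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        ]
    for chrom in pd.unique(gm.chrom):
        length = int(gm.pos[gm.chrom == chrom].max()) + 1 if gm.n_sites else 1
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    out = []
    for j in range(gm.n_sites):
        cells = []
        for i in range(gm.n_samples):
            gt = _GT_STRINGS[int(gm.genotypes[i, j])]
            if with_depth:
                cells.append(
                    f"{gt}:{int(gm.depth[i, j])}:"
                    f"{int(gm.ad_ref[i, j])},{int(gm.ad_alt[i, j])}"
                )
            else:
                cells.append(gt)
        out.append(
            f"{gm.chrom[j]}\t{int(gm.pos[j]) + 1}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
            f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines + out) + "\n")


def mask_genotypes(
    gm: GenotypeMatrix,
    per_sample_mean_depth: Mapping[str, float] | Sequence[float],
    min_depth: float = 10.0,
    max_depth_fold: float = 1.65,
    het_alt_fraction: tuple[float, float] = (0.25, 0.8),
) -> GenotypeMatrix:
    """Apply depth and allelic-balance genotype masks.

    A genotype becomes missing when its depth is < ``min_depth`` or
    > ``max_depth_fold`` x the sample's mean depth; a heterozygote
    additionally becomes missing when DP_ALT/(DP_REF+DP_ALT) falls strictly
    outside ``het_alt_fraction`` (boundaries retained: the rules are
    strict "<" / ">").  Never un-masks anything.
    """
    if gm.depth is None or gm.ad_ref is None or gm.ad_alt is None:
        raise ValueError("mask_genotypes requires DP and AD annotations")
    if isinstance(per_sample_mean_depth, Mapping):
        missing_samples = [s for s in gm.sample_ids if s not in per_sample_mean_depth]
        if missing_samples:
            raise ValueError(f"no mean depth for sample(s): {missing_samples}")
        means = np.array([per_sample_mean_depth[s] for s in gm.sample_ids], float)
    else:
        means = np.asarray(per_sample_mean_depth, dtype=float)
        if means.shape != (gm.n_samples,):
            raise ValueError("per_sample_mean_depth length != n_samples")
    dp = gm.depth.astype(float)
    bad = (dp < min_depth) | (dp > max_depth_fold * means[:, None])
    lo, hi = het_alt_fraction
    ad_total = gm.ad_ref.astype(float) + gm.ad_alt.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ad_total > 0, gm.ad_alt / ad_total, np.nan)
    het = gm.genotypes == 1
    bad |= het & ((frac > hi) | (frac < lo))
    new_gt = np.where(bad, MISSING, gm.genotypes).astype(np.int8)
    new_gt = np.where(gm.genotypes == MISSING, MISSING, new_gt).astype(np.int8)
    return replace(gm, genotypes=new_gt)


def _maf(freq: float) -> float:
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"allele frequency {freq} outside [0, 1]")
    return min(freq, 1.0 - freq)


def classify_maf(freq: float, rare: float = 0.01, common: float = 0.05) -> str:
    """Classify one allele frequency as rare (MAF < 0.01), common (MAF > 0.05)
    or intermediate.  Input may be an allele frequency; it is folded to the
    minor allele."""
    maf = _maf(freq)
    if maf < rare:
        return "rare"
    if maf > common:
        return "common"
    return "intermediate"


def classify_maf_pair(
    freq_a: float | None,
    freq_b: float | None,
    rare: float = 0.01,
    common: float = 0.05,
) -> str:
    """Joint rare/common class of a SNP called in two call sets.

    ``None``/NaN means the SNP is absent from that call set.  Labels:
    Both-rare, A-rare/B-common, B-rare/A-common, A-unique, B-unique, other.
    """
    def absent(f):
        return f is None or (isinstance(f, float) and np.isnan(f))

    if absent(freq_a) and absent(freq_b):
        raise ValueError("SNP absent from both call sets")
    if absent(freq_b):
        _maf(freq_a)
        return "A-unique"
    if absent(freq_a):
        _maf(freq_b)
        return "B-unique"
    ca = classify_maf(freq_a, rare, common)
    cb = classify_maf(freq_b, rare, common)
    if ca == "rare" and cb == "rare":
        return "Both-rare"
    if ca == "rare" and cb == "common":
        return "A-rare/B-common"
    if cb == "rare" and ca == "common":
        return "B-rare/A-common"
    return "other"


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a 3-column TSV: sample, population, super-population."""
    pops: dict[str, str] = {}
    supers: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            sample, pop, sup = parts
            if sample in pops:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            pops[sample] = pop
            supers[sample] = sup
    return PopulationMap(population=pops, super_population=supers)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.population.items():
            fh.write(f"{s}\t{p}\t{popmap.super_population.get(s, 'NA')}\n")


def read_depth(path: str | Path, wg_mean: float | None = None) -> DepthTrack:
    """Read a samtools-depth style TSV (chrom, 1-based pos, depth).

    Positions absent from the file have depth 0.  The file must cover a
    single chromosome.
    """
    chrom = None
    pos: list[int] = []
    val: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            c, p, d = parts
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError(f"{path}:{lineno}: multiple chromosomes in depth file")
            try:
                pos.append(int(p))
                val.append(int(d))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
    if chrom is None:
        raise ValueError(f"{path}: empty depth file")
    if min(pos) < 1:
        raise ValueError(f"{path}: depth positions are 1-based; found position < 1")
    depth = np.zeros(max(pos), dtype=np.int64)
    depth[np.asarray(pos) - 1] = val
    return DepthTrack(chrom=chrom, depth=depth, start=0, wg_mean=wg_mean)


def read_bedgraph(path: str | Path, wg_mean: float | None = None) -> DepthTrack:
    """Alternate depth reader: bedGraph (chrom, 0-based start, end, value)."""
    chrom = None
    spans: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            c, s, e, v = parts
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError(f"{path}:{lineno}: multiple chromosomes in bedGraph")
            try:
                spans.append((int(s), int(e), int(float(v))))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
    if chrom is None:
        raise ValueError(f"{path}: empty bedGraph")
    depth = np.zeros(max(e for _, e, _ in spans), dtype=np.int64)
    for s, e, v in spans:
        depth[s:e] = v
    return DepthTrack(chrom=chrom, depth=depth, start=0, wg_mean=wg_mean)


def region_to_bed_coords(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open (BED) coordinates."""
    return start_1based - 1, end_inclusive


def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write intervals as BED3+score.

    Accepts objects with chrom/start/end (and optionally a score attribute
    among score, fd, max_fd, mean_depth, h) or plain (chrom, start, end[,
    score]) tuples.  Coordinates are already 0-based half-open internally.
    """
    with open(path, "w") as fh:
        for r in regions:
            if isinstance(r, (tuple, list)):
                chrom, start, end = r[0], r[1], r[2]
                score = r[3] if len(r) > 3 else "."
            else:
                chrom, start, end = r.chrom, r.start, r.end
                score = "."
                for attr in ("score", "max_fd", "fd", "mean_depth", "h"):
                    if hasattr(r, attr):
                        score = getattr(r, attr)
                        break
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{score}\n")


def read_mapping_stats(path: str | Path) -> pd.DataFrame:
    """Read a per-sample mapping-statistics TSV.

    Columns: sample, population, uniqmap_cn1, uniqmap_chm13, uniqclip_cn1,
    uniqclip_chm13 (UniqMap = percent of reads uniquely mapped to that
    reference; UniqClip = percent of uniquely mapped reads with clipped
    alignments).  Percentages must lie in [0, 100].
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAPPING_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mapping-stat columns {missing}")
    pct = df[list(MAPPING_STAT_COLUMNS[2:])]
    if ((pct < 0) | (pct > 100)).any().any():
        raise ValueError(f"{path}: percentages outside [0, 100]")
    return df
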