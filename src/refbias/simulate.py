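"""Synthetic inputs with known truth for every pipeline stage.

The generators emulate the study conditions the pipeline is meant for:

* a four-taxon quartet ((P1, P2), P3, O) — by default ten Bantu Kenya
  genomes (P1), twenty Han genomes (P2), one archaic genome (P3) and five
  chimpanzee genomes (O) — with introgression planted as tract-copying:
  inside a planted tract each P2 haplotype is, with probability ``gamma``,
  drawn from the donor (P3) allele-frequency distribution instead of its
  own, producing the excess ABBA sharing the scan detects;
* Poisson read-depth tracks with planted reference-specific regions and
  a planted insertion genotyped from scaled depth;
* structural-variant positions along a chromosome;
* per-sample mapping-statistic tables linearly coupled to a population
  Fst matrix, so the mapping-bias correlation is recoverable by design.

All randomness in a generator flows from ``cfg.seed`` through a single
``numpy.random.Generator``; identical configs give byte-identical outputs.
The copy indicator, background allele and donor allele are drawn
unconditionally, so runs differing only in ``gamma`` share all other
randomness (useful for monotonicity checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth import DepthTrack
from .formats import GenotypeMatrix, PopulationMap
from .introgression import TaxonAssignment
from .svwindows import SVRecord

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDepth",
    "DEFAULT_TAXA",
    "simulate_quartet_genotypes",
    "simulate_depth_track",
    "simulate_sv_set",
    "simulate_mapping_stats",
    "simulate_fst_matrix",
]

DEFAULT_TAXA = TaxonAssignment(
    p1="BantuKenya", p2="Han", p3="Neanderthal", outgroup="Chimpanzee"
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all generators.

    Sample sizes default to the introgression-scan panel (10 P1 / 20 P2 /
    1 archaic P3 / 5 outgroup genomes).  ``site_density`` of 5 SNPs per kb
    keeps 10-kb windows above the 30-good-site filter.  ``gamma`` is the
    introgressed-replacement fraction inside the planted ``tracts``.
    ``depth_lambda`` is the mean sequencing coverage of the depth tracks;
    ``noise`` is "poisson" or "none" (exact expected depth).
    """

    seed: int = 0
    # quartet genotypes
    n_p1: int = 10
    n_p2: int = 20
    n_p3: int = 1
    n_outgroup: int = 5
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    site_density: float = 0.005
    gamma: float = 0.0
    tracts: tuple[tuple[int, int], ...] = ()
    ancestral_beta: tuple[float, float] = (0.2, 0.2)
    drift_concentration: float = 20.0
    drift_concentration_p3: float = 0.1
    outgroup_fixed_fraction: float = 0.95
    # depth tracks
    depth_lambda: float = 30.0
    noise: str = "poisson"
    smr_intervals: tuple[tuple[int, int], ...] = ()
    smr_background: float = 0.1
    smr_enrichment: float = 1.0
    insertion_region: tuple[int, int] | None = None
    insertion_genotypes: Mapping[str, int] | None = None
    insertion_allele_freqs: Mapping[str, tuple[int, float]] | None = None
    # SV set
    n_svs: int = 200
    sv_len_range: tuple[int, int] = (50, 5000)
    sv_mode: str = "uniform"  # or "clustered"
    sv_n_clusters: int = 5
    sv_cluster_sd: float = 50_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        for s, e in self.tracts:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"tract ({s}, {e}) outside chromosome")
        regions = list(self.smr_intervals)
        if self.insertion_region is not None:
            regions.append(self.insertion_region)
        for s, e in regions:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"planted region ({s}, {e}) outside chromosome")
        for (s1, e1), (s2, e2) in zip(sorted(regions), sorted(regions)[1:]):
            if s2 < e1:
                raise ValueError("planted depth regions overlap")


@dataclass
class SimulationTruth:
    """Planted features against which recovery is measured."""

    tracts: tuple[tuple[int, int], ...] = ()
    gamma: float = 0.0
    site_pos: np.ndarray | None = None
    true_freqs: pd.DataFrame | None = None  # per-site p1..p4 the draws used
    smr_intervals: tuple[tuple[int, int], ...] = ()
    insertion_region: tuple[int, int] | None = None
    insertion_genotypes: dict[str, int] = field(default_factory=dict)
    insertion_allele_freqs: dict[str, float] = field(default_factory=dict)
    insertion_populations: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedDepth:
    total: DepthTrack
    specific: DepthTrack
    insertion: dict[str, DepthTrack]


def _clip_unit(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 1e-9, 1.0 - 1e-9)


def simulate_quartet_genotypes(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """Genotypes for the four-taxon scan with planted introgression.

    Per site an ancestral derived-allele frequency is drawn from
    Beta(*cfg.ancestral_beta*) and drifts independently into each taxon
    (Beta resampling around the ancestral value; the archaic P3 drifts
    with a lower concentration, i.e. further).  The outgroup is fixed
    ancestral at ``outgroup_fixed_fraction`` of sites and rarely
    polymorphic otherwise.  Genotypes are binomial draws per sample;
    inside planted tracts each P2 haplotype copies the donor frequency
    with probability ``gamma``.
    """
    n_sites = int(round(cfg.chrom_length * cfg.site_density))
    n_total = cfg.n_p1 + cfg.n_p2 + cfg.n_p3 + cfg.n_outgroup
    if n_sites == 0:
        raise ValueError("configuration yields zero sites")
    if min(cfg.n_p1, cfg.n_p2, cfg.n_p3, cfg.n_outgroup) == 0:
        raise ValueError("every taxon needs at least one sample")
    rng = np.random.default_rng(cfg.seed)
    pos = np.sort(rng.choice(cfg.chrom_length, size=n_sites, replace=False))

    a, b = cfg.ancestral_beta
    q = _clip_unit(rng.beta(a, b, n_sites))
    c, c3 = cfg.drift_concentration, cfg.drift_concentration_p3
    p1 = _clip_unit(rng.beta(c * q, c * (1.0 - q)))
    p2 = _clip_unit(rng.beta(c * q, c * (1.0 - q)))
    p3 = _clip_unit(rng.beta(c3 * q, c3 * (1.0 - q)))
    fixed = rng.random(n_sites) < cfg.outgroup_fixed_fraction
    p4_poly = rng.beta(1.0, 19.0, n_sites)
    p4 = np.where(fixed, 0.0, p4_poly)

    in_tract = np.zeros(n_sites, dtype=bool)
    for s, e in cfg.tracts:
        in_tract |= (pos >= s) & (pos < e)

    def draw(n_samples: int, freq: np.ndarray) -> np.ndarray:
        haps = rng.random((n_samples, 2, n_sites)) < freq
        return haps.sum(axis=1).astype(np.int8)

    g1 = draw(cfg.n_p1, p1)
    # P2: background allele, donor allele and copy indicator drawn
    # unconditionally -> runs differing only in gamma are coupled
    bg = rng.random((cfg.n_p2, 2, n_sites)) < p2
    donor = rng.random((cfg.n_p2, 2, n_sites)) < p3
    copy = (rng.random((cfg.n_p2, 2, n_sites)) < cfg.gamma) & in_tract
    g2 = np.where(copy, donor, bg).sum(axis=1).astype(np.int8)
    g3 = draw(cfg.n_p3, p3)
    g4 = draw(cfg.n_outgroup, p4)

    taxa_samples = {
        DEFAULT_TAXA.p1: [f"{DEFAULT_TAXA.p1}_{i}" for i in range(cfg.n_p1)],
        DEFAULT_TAXA.p2: [f"{DEFAULT_TAXA.p2}_{i}" for i in range(cfg.n_p2)],
        DEFAULT_TAXA.p3: [f"{DEFAULT_TAXA.p3}_{i}" for i in range(cfg.n_p3)],
        DEFAULT_TAXA.outgroup: [
            f"{DEFAULT_TAXA.outgroup}_{i}" for i in range(cfg.n_outgroup)
        ],
    }
    supers = {
        DEFAULT_TAXA.p1: "AFR",
        DEFAULT_TAXA.p2: "EAS",
        DEFAULT_TAXA.p3: "archaic",
        DEFAULT_TAXA.outgroup: "outgroup",
    }
    sample_ids = [s for members in taxa_samples.values() for s in members]
    popmap = PopulationMap(
        population={s: pop for pop, members in taxa_samples.items() for s in members},
        super_population={
            s: supers[pop] for pop, members in taxa_samples.items() for s in members
        },
    )
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.full(n_sites, cfg.chrom, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        genotypes=np.vstack([g1, g2, g3, g4]),
    )
    truth = SimulationTruth(
        tracts=cfg.tracts,
        gamma=cfg.gamma,
        site_pos=pos,
        true_freqs=pd.DataFrame(
            {"pos": pos, "p1": p1, "p2": p2, "p3": p3, "p4": p4, "in_tract": in_tract}
        ),
    )
    return gm, popmap, truth


def _depth_draw(rng, lam: float, e: np.ndarray | float, n: int, noise: str) -> np.ndarray:
    expected = np.broadcast_to(np.asarray(lam * e, dtype=float), (n,))
    if noise == "none":
        return np.rint(expected).astype(np.int64)
    if noise == "poisson":
        return rng.poisson(expected).astype(np.int64)
    raise ValueError(f"unknown noise model {noise!r}")


def simulate_depth_track(cfg: SimulationConfig) -> tuple[SimulatedDepth, SimulationTruth]:
    """Depth tracks with planted SMRs and insertion genotypes.

    Per-base depth ~ Poisson(lambda * e).  The *total* track has e = 1
    everywhere.  The *specific* (reference-specific reads) track has a low
    background (``smr_background``, default 0.1) and e =
    ``smr_enrichment`` (default 1.0, comfortably above the half-coverage
    calling threshold) inside planted SMRs.  Each insertion sample gets a
    region track with e in {0, 0.5, 1} by its planted genotype; the
    sample's genome-wide mean is lambda.
    """
    if cfg.depth_lambda <= 0:
        raise ValueError("depth_lambda must be positive")
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length
    lam = cfg.depth_lambda
    total = DepthTrack(
        chrom=cfg.chrom,
        depth=_depth_draw(rng, lam, 1.0, L, cfg.noise),
        wg_mean=lam,
    )
    e_spec = np.full(L, cfg.smr_background)
    for s, e in cfg.smr_intervals:
        e_spec[s:e] = cfg.smr_enrichment
    specific = DepthTrack(
        chrom=cfg.chrom,
        depth=_depth_draw(rng, lam, e_spec, L, cfg.noise),
        wg_mean=lam,
    )

    genotypes: dict[str, int] = {}
    pops: dict[str, str] = {}
    freqs: dict[str, float] = {}
    if cfg.insertion_genotypes is not None:
        genotypes.update({s: int(g) for s, g in cfg.insertion_genotypes.items()})
    elif cfg.insertion_allele_freqs is not None:
        for pop, (n, f) in cfg.insertion_allele_freqs.items():
            draws = rng.binomial(2, f, size=n)
            for i, g in enumerate(draws):
                name = f"{pop}_{i}"
                genotypes[name] = int(g)
                pops[name] = pop
            freqs[pop] = float(f)

    insertion_tracks: dict[str, DepthTrack] = {}
    if genotypes:
        if cfg.insertion_region is None:
            raise ValueError("insertion genotypes given without insertion_region")
        s, e = cfg.insertion_region
        n = e - s
        e_of = {0: 0.0, 1: 0.5, 2: 1.0}
        for sample, g in genotypes.items():
            insertion_tracks[sample] = DepthTrack(
                chrom=cfg.chrom,
                depth=_depth_draw(rng, lam, e_of[g], n, cfg.noise),
                start=s,
                wg_mean=lam,
            )
    truth = SimulationTruth(
        smr_intervals=cfg.smr_intervals,
        insertion_region=cfg.insertion_region,
        insertion_genotypes=genotypes,
        insertion_allele_freqs=freqs,
        insertion_populations=pops,
    )
    return SimulatedDepth(total=total, specific=specific, insertion=insertion_tracks), truth


def simulate_sv_set(cfg: SimulationConfig) -> list[SVRecord]:
    """Structural-variant records placed uniformly or in clusters."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.sv_len_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid sv_len_range")
    lengths = rng.integers(lo, hi + 1, size=cfg.n_svs)
    max_start = cfg.chrom_length - int(hi)
    if max_start <= 0:
        raise ValueError("chromosome too short for configured SV lengths")
    if cfg.sv_mode == "uniform":
        starts = rng.integers(0, max_start, size=cfg.n_svs)
    elif cfg.sv_mode == "clustered":
        centers = rng.integers(0, max_start, size=cfg.sv_n_clusters)
        which = rng.integers(0, cfg.sv_n_clusters, size=cfg.n_svs)
        starts = np.clip(
            np.rint(rng.normal(centers[which], cfg.sv_cluster_sd)).astype(np.int64),
            0,
            max_start - 1,
        )
    else:
        raise ValueError(f"unknown sv_mode {cfg.sv_mode!r}")
    types = rng.choice(["INS", "DEL"], size=cfg.n_svs)
    order = np.argsort(starts, kind="stable")
    return [
        SVRecord(
            chrom=cfg.chrom,
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            svtype=str(types[i]),
        )
        for i in order
    ]


def simulate_fst_matrix(
    populations: Sequence[str], seed: int = 0, scale: float = 0.2
) -> pd.DataFrame:
    """Random symmetric zero-diagonal Fst matrix from latent 1-D positions."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, scale, size=len(populations))
    mat = np.abs(z[:, None] - z[None, :])
    return pd.DataFrame(mat, index=list(populations), columns=list(populations))


def simulate_mapping_stats(
    fst_matrix: pd.DataFrame,
    slope: float,
    noise_sd: float,
    cfg: SimulationConfig,
    ref_pop_a: str = "CHS",
    ref_pop_b: str = "CEU",
    n_samples_per_pop: int = 5,
    uniqmap_base: float = 90.0,
    uniqclip_base: float = 5.0,
) -> pd.DataFrame:
    """Mapping-statistic table linearly coupled to genetic distance.

    For population m with x = Fst(m, ref_pop_a) - Fst(m, ref_pop_b):
    UniqMap_CHM13 - UniqMap_CN1 = slope * x + N(0, noise_sd), and
    UniqClip_CN1 - UniqClip_CHM13 = -slope * x + N(0, noise_sd) — a
    negative slope reproduces the field observation that populations
    genetically closer to the reference's own population map better (and
    clip less) on that reference.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not np.allclose(fst_matrix.values, fst_matrix.values.T):
        raise ValueError("fst_matrix must be symmetric")
    if not np.allclose(np.diag(fst_matrix.values), 0.0):
        raise ValueError("fst_matrix must have a zero diagonal")
    for p in (ref_pop_a, ref_pop_b):
        if p not in fst_matrix.index:
            raise ValueError(f"reference population {p!r} missing from fst_matrix")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for pop in fst_matrix.index:
        x = fst_matrix.loc[pop, ref_pop_a] - fst_matrix.loc[pop, ref_pop_b]
        d_map = slope * x + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        d_clip = -slope * x + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        for i in range(n_samples_per_pop):
            rows.append(
                {
                    "sample": f"{pop}_{i}",
                    "population": pop,
                    "uniqmap_cn1": uniqmap_base,
                    "uniqmap_chm13": uniqmap_base + d_map,
                    "uniqclip_cn1": uniqclip_base + d_clip,
                    "uniqclip_chm13": uniqclip_base,
                }
            )
    df = pd.DataFrame(rows)
    for col in df.columns[2:]:
        df[col] = df[col].clip(0.0, 100.0)
    return df
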