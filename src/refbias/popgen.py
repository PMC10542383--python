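"""Per-SNP and windowed Weir-Cockerham Fst, empirical outlier p-values
against an intergenic null, differentiated-region calling, and the
mapping-bias-vs-genetic-distance correlation.

The per-site estimator is the two-population Weir & Cockerham (1984)
theta computed from sample sizes, allele frequencies and observed
heterozygosity — the quantity vcftools reports per SNP.  Its variance
components a (among populations), b (among individuals within
populations) and c (within individuals) are kept per site so windowed
values can be formed as the ratio of summed components (ratio of
averages), the standard way to aggregate Fst over a region.  Negative
per-site estimates are retained, not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "DifferentiatedRegionCall",
    "weir_cockerham_fst",
    "windowed_fst",
    "empirical_p",
    "empirical_cutoff",
    "call_differentiated_regions",
    "mapping_bias_correlation",
    "pairwise_fst_matrix",
    "sample_variants_for_fst",
]


@dataclass(frozen=True)
class DifferentiatedRegionCall:
    chrom: str
    start: int
    end: int
    n_snvs: int
    frac_significant: float
    passed: bool
    no_snvs: bool = False


def _pop_site_stats(gm: GenotypeMatrix, samples: Sequence[str]):
    """Per-site called-sample count, alt frequency and het frequency."""
    idx = [gm.sample_ids.index(s) for s in samples]
    g = gm.genotypes[idx, :]
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / (2.0 * n)
        h = np.where(called & (g == 1), 1, 0).sum(axis=0) / n
    return n, p, h


def weir_cockerham_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
) -> pd.DataFrame:
    """Per-site Weir & Cockerham theta between two populations.

    Sites monomorphic across both populations, or with fewer than one
    called individual in either, are skipped.  Returns a DataFrame with
    chrom, pos, the variance components a, b, c and fst = a/(a+b+c).
    """
    sa, sb = popmap.samples_in(pop_a), popmap.samples_in(pop_b)
    if not sa or not sb:
        raise ValueError(f"empty population among ({pop_a!r}, {pop_b!r})")
    n1, p1, h1 = _pop_site_stats(gm, sa)
    n2, p2, h2 = _pop_site_stats(gm, sb)

    keep = (n1 >= 1) & (n2 >= 1)
    with np.errstate(invalid="ignore"):
        poly = ~((p1 == 0) & (p2 == 0)) & ~((p1 == 1) & (p2 == 1))
    keep &= poly

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    # nc == 0 happens only when both samples are single individuals with
    # everything missing; already excluded by `keep`
    df = pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.pos, "a": a, "b": b, "c": c, "fst": fst}
    )
    return df[keep].reset_index(drop=True)


def windowed_fst(
    site_fst: pd.DataFrame,
    window: int = 10_000,
    step: int = 2_000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Windowed Fst as the ratio of summed variance components.

    Windows (default 10 kb, step 2 kb) are anchored at position 0;
    windows with no variants are omitted.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    rows = []
    for chrom, grp in site_fst.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        a = grp["a"].to_numpy()
        bc = grp["b"].to_numpy() + grp["c"].to_numpy()
        ca, cbc = np.concatenate([[0.0], a.cumsum()]), np.concatenate([[0.0], (a + bc).cumsum()])
        length = chrom_length if chrom_length is not None else int(pos.max()) + 1
        start = 0
        while start < length:
            end = min(start + window, length)
            lo, hi = np.searchsorted(pos, [start, end])
            if hi > lo:
                num = ca[hi] - ca[lo]
                den = cbc[hi] - cbc[lo]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "n_variants": int(hi - lo),
                        "fst": num / den if den != 0 else np.nan,
                    }
                )
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_variants", "fst"])


def empirical_p(observed, null_values) -> np.ndarray | float:
    """Empirical p-value of observed statistic(s) against a null set.

    p = (1 + #{null >= observed}) / (1 + N) — the add-one rank rule, so
    p lies in (0, 1] and never reaches 0.
    """
    null = np.sort(np.asarray(null_values, dtype=float))
    n = null.size
    if n == 0:
        raise ValueError("empty null distribution")
    obs = np.asarray(observed, dtype=float)
    ge = n - np.searchsorted(null, obs, side="left")
    p = (1.0 + ge) / (1.0 + n)
    return float(p) if np.isscalar(observed) or obs.ndim == 0 else p


def empirical_cutoff(null_values, alpha: float = 0.05) -> float:
    """The null-distribution (1 - alpha) quantile — the statistic value at
    which the empirical p-value crosses alpha (the dashed cutoff line on
    an Fst scan plot)."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float(np.quantile(null, 1.0 - alpha))


def call_differentiated_regions(
    regions: Sequence[tuple[str, int, int]],
    snv_chrom: Sequence[str],
    snv_pos: Sequence[int],
    snv_p: Sequence[float],
    alpha: float = 0.05,
) -> list[DifferentiatedRegionCall]:
    """Call a region differentiated when strictly more than half of its
    SNVs have an empirical p below ``alpha``.

    Regions are (chrom, start, end) half-open; a region containing no
    SNVs fails with the ``no_snvs`` flag set.
    """
    chrom_arr = np.asarray(snv_chrom, dtype=object)
    pos_arr = np.asarray(snv_pos, dtype=np.int64)
    p_arr = np.asarray(snv_p, dtype=float)
    out = []
    for chrom, start, end in regions:
        sel = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end)
        n = int(sel.sum())
        if n == 0:
            out.append(
                DifferentiatedRegionCall(chrom, start, end, 0, 0.0, False, no_snvs=True)
            )
            continue
        frac = float((p_arr[sel] < alpha).mean())
        out.append(
            DifferentiatedRegionCall(chrom, start, end, n, frac, frac > 0.5)
        )
    return out


def mapping_bias_correlation(
    mapping_stats: pd.DataFrame,
    fst_matrix: pd.DataFrame,
    ref_pop_a: str = "CHS",
    ref_pop_b: str = "CEU",
    metric: str = "uniqmap",
) -> tuple[pd.DataFrame, float, float]:
    """Correlate per-population mapping bias with genetic distance.

    x = Fst(m, ref_pop_a) - Fst(m, ref_pop_b) per population m;
    y = mean over the population's samples of UniqMap_CHM13 - UniqMap_CN1
    (``metric="uniqmap"``) or UniqClip_CN1 - UniqClip_CHM13
    (``metric="uniqclip"`` — the clipping difference is computed
    unique-to-CN1 minus unique-to-CHM13).  Returns the per-population
    points, Pearson's r and its p-value.
    """
    if metric == "uniqmap":
        diff = mapping_stats["uniqmap_chm13"] - mapping_stats["uniqmap_cn1"]
    elif metric == "uniqclip":
        diff = mapping_stats["uniqclip_cn1"] - mapping_stats["uniqclip_chm13"]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    per_pop = diff.groupby(mapping_stats["population"]).mean()
    missing = [m for m in per_pop.index if m not in fst_matrix.index]
    if missing:
        raise ValueError(f"population(s) missing from fst_matrix: {missing}")
    x = np.array(
        [fst_matrix.loc[m, ref_pop_a] - fst_matrix.loc[m, ref_pop_b] for m in per_pop.index]
    )
    y = per_pop.to_numpy()
    r, p = stats.pearsonr(x, y)
    points = pd.DataFrame(
        {"population": per_pop.index, "fst_diff": x, "bias": y}
    ).reset_index(drop=True)
    return points, float(r), float(p)


def pairwise_fst_matrix(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genome-wide pairwise Fst matrix (ratio-of-averages over all sites)."""
    pops = list(populations) if populations is not None else popmap.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            df = weir_cockerham_fst(gm, popmap, pa, pb)
            den = (df["a"] + df["b"] + df["c"]).sum()
            val = float(df["a"].sum() / den) if den != 0 else np.nan
            mat.loc[pa, pb] = mat.loc[pb, pa] = val
    return mat


def sample_variants_for_fst(
    gm: GenotypeMatrix,
    fraction: float = 0.001,
    min_maf: float = 0.01,
    seed: int = 0,
) -> GenotypeMatrix:
    """Seed-deterministic pre-filter for the population Fst matrix:
    randomly sample ``fraction`` of the variants, then keep those with
    minor-allele frequency above ``min_maf`` across all samples."""
    rng = np.random.default_rng(seed)
    chosen = np.flatnonzero(rng.random(gm.n_sites) < fraction)
    sub = gm.subset_sites(chosen)
    freq = sub.alt_allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    return sub.subset_sites(np.flatnonzero(maf > min_maf))
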