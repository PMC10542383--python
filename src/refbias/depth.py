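"""Depth-track analyses: specific-mapping-region detection and
presence/absence genotyping of an insertion from scaled read depth.

A *specific mapping region* (SMR) is an interval where reads map to one
reference but not the other at more than half the genome-wide coverage —
the depth signature of sequence present in one assembly and absent from
the other.  An insertion is genotyped per sample from its *scaled depth*
(region mean depth divided by the sample's genome-wide mean): reads from
carriers of the insertion pile up on it, so a homozygous carrier sits
near 1, a heterozygote near 0.5 and a non-carrier near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DepthTrack",
    "SMRegion",
    "InsertionGenotype",
    "detect_smr",
    "scaled_region_depth",
    "call_insertion_genotype",
    "population_insertion_frequency",
]


@dataclass
class DepthTrack:
    """Per-base depth over a contiguous 0-based range of one chromosome.

    ``depth[i]`` is the coverage at position ``start + i``; ``wg_mean`` is
    the genome-wide mean depth of the alignment the track was derived from.
    """

    chrom: str
    depth: np.ndarray
    start: int = 0
    wg_mean: float | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")
        if self.wg_mean is not None and self.wg_mean <= 0:
            raise ValueError("wg_mean must be positive")

    @property
    def end(self) -> int:
        return self.start + len(self.depth)


@dataclass(frozen=True)
class SMRegion:
    chrom: str
    start: int
    end: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsertionGenotype:
    sample: str
    scaled_depth: float
    call: str  # "absent" | "heterozygous" | "homozygous"


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean vector."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_smr(
    specific: DepthTrack,
    min_len: int = 100,
    merge_gap: int = 0,
    wg_mean: float | None = None,
) -> list[SMRegion]:
    """Call specific mapping regions from a reference-specific depth track.

    Candidate segments are maximal runs of bases with specific depth
    strictly above half the whole-genome coverage, merged across gaps of at
    most ``merge_gap`` bases; a merged segment is retained when its mean
    specific depth still exceeds half coverage and its length is at least
    ``min_len`` (regions < 100 bp are discarded by default).

    ``wg_mean`` is the mean depth of the *total* alignment (not the
    specific-read track); falls back to ``specific.wg_mean``.
    """
    mean = wg_mean if wg_mean is not None else specific.wg_mean
    if mean is None or mean <= 0:
        raise ValueError("whole-genome mean depth must be set and positive")
    thr = mean / 2.0
    runs = _runs_above(specific.depth > thr)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s < min_len:
            continue
        region_mean = float(specific.depth[s:e].mean())
        if region_mean > thr:
            out.append(
                SMRegion(
                    chrom=specific.chrom,
                    start=specific.start + s,
                    end=specific.start + e,
                    mean_depth=region_mean,
                )
            )
    return out


def scaled_region_depth(track: DepthTrack, start: int, end: int) -> float:
    """Mean depth over the 0-based half-open [start, end), divided by the
    sample's genome-wide mean depth.  Bases outside the track's covered
    range count as depth 0."""
    if end <= start:
        raise ValueError(f"empty region [{start}, {end})")
    if track.wg_mean is None or track.wg_mean <= 0:
        raise ValueError("track.wg_mean must be set and positive")
    lo = max(start, track.start)
    hi = min(end, track.end)
    total = float(track.depth[lo - track.start : hi - track.start].sum()) if hi > lo else 0.0
    return total / (end - start) / track.wg_mean


def call_insertion_genotype(
    scaled: float, het_lo: float = 0.4, het_hi: float = 0.8
) -> str:
    """Genotype an insertion from scaled depth.

    Scaled depth in [het_lo, het_hi] -> heterozygous; above het_hi ->
    homozygous insertion allele; below het_lo -> absent.  The boundary
    values count as heterozygous ("between 0.4 and 0.8" read as closed).
    """
    if scaled < 0:
        raise ValueError("scaled depth must be non-negative")
    if scaled > het_hi:
        return "homozygous"
    if scaled >= het_lo:
        return "heterozygous"
    return "absent"


_ALLELE_COUNT = {"absent": 0, "heterozygous": 1, "homozygous": 2}


def population_insertion_frequency(
    calls: Iterable[InsertionGenotype] | Mapping[str, str],
    popmap,
) -> dict[str, float | None]:
    """Insertion allele frequency per population.

    frequency = (n_het + 2 * n_hom) / (2 * n_samples) over the samples of
    each population present in ``calls``; populations with no genotyped
    sample get ``None``.
    """
    if isinstance(calls, Mapping):
        call_of = dict(calls)
    else:
        call_of = {c.sample: c.call for c in calls}
    unknown = [s for s in call_of if s not in popmap.population]
    if unknown:
        raise ValueError(f"sample(s) not in population map: {unknown}")
    freqs: dict[str, float | None] = {}
    for pop in popmap.populations:
        members = [s for s in popmap.samples_in(pop) if s in call_of]
        if not members:
            freqs[pop] = None
            continue
        ac = sum(_ALLELE_COUNT[call_of[s]] for s in members)
        freqs[pop] = ac / (2 * len(members))
    return freqs
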