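"""Haplotype-heterozygosity windows from SV counts, bubble GFA export,
and the gap-deleted p-distance.

The heterozygosity rate *h* of a 500-kb window is the number of
structural variants between the two haplotypes whose start falls in the
window.  Windows with h >= 2 are "hete" and drawn as bubbles (two
parallel segments) in the emitted GFA 1.0 graph; maximal runs of "homo"
windows collapse to single segments, so the graph renders as a chain of
single paths interrupted by one bubble per heterozygous window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SVRecord",
    "WindowCount",
    "filter_svs",
    "count_svs_per_window",
    "classify_windows",
    "build_bubble_gfa",
    "p_distance",
]


@dataclass(frozen=True)
class SVRecord:
    """A structural variant as a half-open interval with a type label."""

    chrom: str
    start: int
    end: int
    svtype: str = "INS"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"SV start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowCount:
    chrom: str
    start: int
    end: int
    h: int
    cls: str | None = None  # "hete" | "homo"


def filter_svs(svs: Sequence[SVRecord], min_len: int = 50) -> list[SVRecord]:
    """Keep SVs of at least ``min_len`` bp (default: the >= 50 bp SV size
    convention)."""
    return [sv for sv in svs if sv.length >= min_len]


def count_svs_per_window(
    svs: Sequence[SVRecord],
    chrom_length: int,
    window_size: int = 500_000,
    mode: str = "start",
) -> list[WindowCount]:
    """SV count h per non-overlapping window.

    ``mode="start"`` (default) assigns each SV to the window containing
    its start coordinate, so the window h values sum to the SV count; an
    SV spanning a boundary counts once.  ``mode="overlap"`` increments
    every window the SV overlaps.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    n_windows = max(1, math.ceil(chrom_length / window_size))
    counts = [0] * n_windows
    for sv in svs:
        if sv.start >= chrom_length or sv.end > chrom_length:
            raise ValueError(f"SV ({sv.start}, {sv.end}) beyond chromosome end")
        if mode == "start":
            counts[sv.start // window_size] += 1
        elif mode == "overlap":
            for w in range(sv.start // window_size, (sv.end - 1) // window_size + 1):
                counts[w] += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return [
        WindowCount(
            chrom=svs[0].chrom if svs else "chrom",
            start=w * window_size,
            end=min((w + 1) * window_size, chrom_length),
            h=counts[w],
        )
        for w in range(n_windows)
    ]


def classify_windows(
    counts: Sequence[WindowCount], threshold: int = 2
) -> list[WindowCount]:
    """Assign each window "hete" (h >= threshold, default 2) or "homo"."""
    return [
        WindowCount(w.chrom, w.start, w.end, w.h, "hete" if w.h >= threshold else "homo")
        for w in counts
    ]


def build_bubble_gfa(windows: Sequence[WindowCount]) -> str:
    """Emit the heterozygosity landscape as a GFA 1.0 graph.

    Maximal runs of homo windows become one segment; each hete window
    becomes two parallel segments (a bubble) linked to the flanking
    segments.  Segments carry no sequence; length goes into an ``LN`` tag
    and the window SV count into an ``HC`` tag, so a renderer can shade
    bubbles by heterozygosity rate.  Windows must tile the chromosome
    contiguously and be classified.
    """
    if not windows:
        raise ValueError("no windows")
    for prev, cur in zip(windows, windows[1:]):
        if cur.start != prev.end or cur.chrom != prev.chrom:
            raise ValueError("windows must contiguously tile one chromosome")
    if any(w.cls not in ("hete", "homo") for w in windows):
        raise ValueError("windows must be classified before GFA export")

    segments: list[str] = []
    links: list[str] = []
    prev_nodes: list[str] = []

    def add_segment(name: str, length: int, h: int) -> None:
        segments.append(f"S\t{name}\t*\tLN:i:{length}\tHC:i:{h}")

    def link_from_prev(nodes: list[str]) -> None:
        for a in prev_nodes:
            for b in nodes:
                links.append(f"L\t{a}\t+\t{b}\t+\t0M")

    i = 0
    n = len(windows)
    while i < n:
        w = windows[i]
        if w.cls == "homo":
            j = i
            h_sum = 0
            while j < n and windows[j].cls == "homo":
                h_sum += windows[j].h
                j += 1
            name = f"{w.chrom}:{w.start}-{windows[j - 1].end}"
            add_segment(name, windows[j - 1].end - w.start, h_sum)
            link_from_prev([name])
            prev_nodes = [name]
            i = j
        else:
            base = f"{w.chrom}:{w.start}-{w.end}"
            pair = [f"{base}:hap1", f"{base}:hap2"]
            for name in pair:
                add_segment(name, w.end - w.start, w.h)
            link_from_prev(pair)
            prev_nodes = pair
            i += 1
    return "\n".join(["H\tVN:Z:1.0"] + segments + links) + "\n"


_BASES = frozenset("ACGT")


def p_distance(a: str, b: str) -> float:
    """Pairwise divergence with all gap columns deleted.

    divergence = mismatched bases / (aligned bases - alignment gaps):
    columns containing a gap (or an ambiguous base such as N) are
    excluded, and the mismatch fraction is taken over the remaining
    columns.  Raises if the sequences differ in length, share a gap in
    the same column, or leave no gap-free columns.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a, b = a.upper(), b.upper()
    kept = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            raise ValueError("alignment column with a gap in both sequences")
        if x in _BASES and y in _BASES:
            kept += 1
            if x != y:
                mismatches += 1
    if kept == 0:
        raise ValueError("no gap-free columns; p-distance undefined")
    return mismatches / kept
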