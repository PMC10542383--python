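"""ABBA-BABA introgression scan: site patterns, Patterson's D and the
modified f_d statistic in sliding windows, and putative introgression
region (pIR) calling.

The scan works on a four-taxon topology ((P1, P2), P3, O): derived-allele
sharing between P2 and P3 in excess of P1-P3 sharing (ABBA > BABA) is the
signature of gene flow from the donor P3 into P2.  The frequency-based
(population) form of the statistics is used throughout — the study
populations are 10-20 genomes each; single-genome taxa are simply the
degenerate case with frequencies in {0, 0.5, 1}.

f_d divides the window's ABBA-BABA excess by the excess expected under
complete replacement of the recipient by the higher-frequency donor
(p2 and p3 both replaced by max(p2, p3) site by site), giving an estimate
of the introgressed fraction in [0, 1] for windows with D > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "TaxonAssignment",
    "SiteFrequencies",
    "DStatWindow",
    "PIR",
    "site_frequencies",
    "site_abba_baba",
    "site_fd_denominator",
    "window_scan",
    "call_pirs",
    "windows_to_frame",
]


class TaxonAssignment(NamedTuple):
    """Population labels playing P1, P2, P3 and outgroup."""

    p1: str
    p2: str
    p3: str
    outgroup: str


class SiteFrequencies(NamedTuple):
    """Derived-allele frequencies of the four taxa at one bi-allelic site."""

    chrom: str
    pos: int
    p1: float
    p2: float
    p3: float
    p4: float


@dataclass(frozen=True)
class DStatWindow:
    chrom: str
    start: int
    end: int
    n_good_sites: int
    sum_abba: float
    sum_baba: float
    sum_fd_denominator: float
    d: float  # NaN when ABBA+BABA == 0
    fd: float  # 0 when d <= 0; NaN when d undefined


@dataclass(frozen=True)
class PIR:
    """A putative introgression region: merged run of outlier f_d windows."""

    chrom: str
    start: int
    end: int
    max_fd: float
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _taxon_frequencies(gm: GenotypeMatrix, samples: Sequence[str]):
    sub = gm.genotypes[[gm.sample_ids.index(s) for s in samples], :]
    called = sub != MISSING
    an = 2 * called.sum(axis=0).astype(float)
    ac = np.where(called, sub, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(an > 0, ac / an, np.nan)
    return freq, an


def site_frequencies(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    taxa: TaxonAssignment,
    outgroup_max_maf: float = 0.1,
) -> pd.DataFrame:
    """Per-site derived-allele frequencies p1..p4 for the four taxa.

    The derived allele is the one *not* carried by the outgroup majority.
    A site is "good" when every taxon has at least one called allele and
    the outgroup is near-fixed (outgroup minor-allele frequency at most
    ``outgroup_max_maf``); only good sites enter the window statistics.

    Returns a DataFrame with columns chrom, pos (0-based), p1..p4, good.
    """
    groups = [popmap.samples_in(t) for t in taxa]
    for name, members in zip(taxa._fields, groups):
        if not members:
            raise ValueError(f"taxon {name} ({getattr(taxa, name)!r}) has no samples")
    freqs = []
    called_any = []
    for members in groups:
        f, an = _taxon_frequencies(gm, members)
        freqs.append(f)
        called_any.append(an > 0)
    f1, f2, f3, f4 = freqs
    for name, f in zip(taxa._fields, freqs):
        if np.isnan(f).all():
            raise ValueError(f"taxon {name}: all genotypes missing at every site")
    with np.errstate(invalid="ignore"):
        out_maf = np.minimum(f4, 1.0 - f4)
        derived_is_alt = f4 <= 0.5  # outgroup majority carries REF -> ALT is derived
    good = np.logical_and.reduce(called_any) & (out_maf <= outgroup_max_maf)
    flip = ~derived_is_alt
    p = [np.where(flip, 1.0 - f, f) for f in (f1, f2, f3, f4)]
    return pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos,
            "p1": p[0],
            "p2": p[1],
            "p3": p[2],
            "p4": p[3],
            "good": good,
        }
    )


def _check_freqs(*vals) -> None:
    for v in vals:
        arr = np.asarray(v, dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("frequencies must lie in [0, 1]")


def site_abba_baba(p1, p2, p3, p4):
    """Frequency-based ABBA and BABA weights of one site (or arrays).

    abba = (1-p1) * p2 * p3 * (1-p4);  baba = p1 * (1-p2) * p3 * (1-p4).
    """
    _check_freqs(p1, p2, p3, p4)
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba

def site_fd_denominator(p1, p2, p3, p4):
    """Site term of the f_d denominator: ABBA-BABA with the donor frequency
    set to max(p2, p3) in both the P2 and P3 slots (dynamic-donor rule)."""
    _check_freqs(p1, p2, p3, p4)
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    pd_ = np.maximum(p2, p3)
    return (1.0 - p1) * pd_ * pd_ * (1.0 - p4) - p1 * (1.0 - pd_) * pd_ * (1.0 - p4)


def window_scan(
    sites: pd.DataFrame,
    window: int = 10_000,
    step: int = 1_000,
    min_good: int = 30,
    chrom_length: int | None = None,
) -> list[DStatWindow]:
    """Sliding-window D and f_d over polarized site frequencies.

    Windows are anchored at position 0 with the given size and step
    (defaults 10 kb / 1 kb); windows with fewer than ``min_good`` good
    sites are discarded.  The last partial window is retained if it meets
    ``min_good``.  f_d is reported only for windows with D > 0; windows
    with D <= 0 get f_d = 0.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    required = {"chrom", "pos", "p1", "p2", "p3", "p4", "good"}
    if not required.issubset(sites.columns):
        raise ValueError(f"sites frame must have columns {sorted(required)}")
    out: list[DStatWindow] = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        g = grp[grp["good"]].sort_values("pos")
        pos = g["pos"].to_numpy()
        abba, baba = site_abba_baba(
            g["p1"].to_numpy(), g["p2"].to_numpy(), g["p3"].to_numpy(), g["p4"].to_numpy()
        )
        den = site_fd_denominator(
            g["p1"].to_numpy(), g["p2"].to_numpy(), g["p3"].to_numpy(), g["p4"].to_numpy()
        )
        length = chrom_length
        if length is None:
            length = int(grp["pos"].max()) + 1 if len(grp) else 0
        start = 0
        while start < length:
            end = min(start + window, length)
            lo, hi = np.searchsorted(pos, [start, end])
            n = int(hi - lo)
            if n >= min_good:
                # sequential accumulation (site order) so window sums equal a
                # brute-force per-site loop bitwise
                sum_abba = 0.0
                sum_baba = 0.0
                sum_den = 0.0
                for a, b, d_ in zip(
                    abba[lo:hi].tolist(), baba[lo:hi].tolist(), den[lo:hi].tolist()
                ):
                    sum_abba += a
                    sum_baba += b
                    sum_den += d_
                tot = sum_abba + sum_baba
                d = (sum_abba - sum_baba) / tot if tot > 0 else float("nan")
                if np.isnan(d):
                    fd = float("nan")
                elif d > 0 and sum_den > 0:
                    fd = min(max((sum_abba - sum_baba) / sum_den, 0.0), 1.0)
                else:
                    fd = 0.0
                out.append(
                    DStatWindow(
                        chrom=str(chrom),
                        start=start,
                        end=end,
                        n_good_sites=n,
                        sum_abba=sum_abba,
                        sum_baba=sum_baba,
                        sum_fd_denominator=sum_den,
                        d=d,
                        fd=fd,
                    )
                )
            start += step
    return out


def windows_to_frame(windows: Sequence[DStatWindow]) -> pd.DataFrame:
    """Window list -> TSV-ready DataFrame (chrom, start, end, n_sites,
    abba, baba, D, f_d)."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": [w.n_good_sites for w in windows],
            "abba": [w.sum_abba for w in windows],
            "baba": [w.sum_baba for w in windows],
            "D": [w.d for w in windows],
            "f_d": [w.fd for w in windows],
        }
    )


def call_pirs(
    windows: Sequence[DStatWindow],
    cutoff: float = 0.35,
    min_len: int = 20_000,
    max_gap: int = 0,
) -> list[PIR]:
    """Merge outlier f_d windows into putative introgression regions.

    Outlier windows have f_d strictly above ``cutoff`` (default: the
    empirical 0.35 cutoff) and D > 0.  Overlapping or abutting outlier
    windows (gap at most ``max_gap``) merge; merged regions shorter than
    ``min_len`` (default 20 kb) are dropped.
    """
    chroms = {w.chrom for w in windows}
    if len(chroms) > 1:
        raise ValueError("call_pirs expects windows from a single chromosome")
    starts = [w.start for w in windows]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("windows must be sorted by start position")
    out: list[PIR] = []
    cur: list | None = None  # [start, end, max_fd, n]
    for w in windows:
        if not (not np.isnan(w.fd) and w.fd > cutoff and w.d > 0):
            continue
        if cur is not None and w.start <= cur[1] + max_gap:
            cur[1] = max(cur[1], w.end)
            cur[2] = max(cur[2], w.fd)
            cur[3] += 1
        else:
            if cur is not None:
                out.append(cur)
            cur = [w.start, w.end, w.fd, 1]
    if cur is not None:
        out.append(cur)
    chrom = windows[0].chrom if windows else ""
    return [
        PIR(chrom=chrom, start=s, end=e, max_fd=f, n_windows=n)
        for s, e, f, n in out
        if e - s >= min_len
    ]
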