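"""Locus coverage computations.

Two readouts of locus activity used alongside the repertoire tables:

* fixed-width (default 60-bp) binned coverage tracks over a locus span,
  rpm-normalised (reads per million mapped reads in the library), with
  overlap counting: a read increments every bin it touches;
* RSS-centred accessibility meta-profiles: per-bp coverage over a 1,000-bp
  window centred on each recombination signal sequence, averaged across an
  RSS set, with strand-aware flipping so the heptamer side points the same
  way at every site; plus per-RSS counts over a centred 50-bp window for
  group testing.

Reads are half-open genomic intervals (e.g. from a BED file); a cut-site
mode counting only the interval 5' ends is available for transposase-type
data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .locus import Segment

__all__ = [
    "BinnedTrack",
    "MetaProfile",
    "bin_quantify",
    "rss_metaprofile",
    "rss_window_counts",
    "read_bed_intervals",
]


def read_bed_intervals(path: str | Path, chrom: str | None = None) -> np.ndarray:
    """Load (start, end) interval pairs from a BED file, optionally
    restricted to one chromosome."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        usecols=[0, 1, 2], names=["chrom", "start", "end"])
    if chrom is not None:
        frame = frame[frame["chrom"] == chrom]
    return frame[["start", "end"]].to_numpy(dtype=np.int64)


@dataclasses.dataclass
class BinnedTrack:
    span: tuple[int, int]
    bin_size: int
    raw: np.ndarray                # per-bin read counts (overlap counting)
    rpm: np.ndarray
    library_size: int

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.span[0], self.span[1], self.bin_size)

    def to_bedgraph(self, path: str | Path, chrom: str) -> None:
        with open(path, "w") as fh:
            for start, val in zip(self.bin_starts, self.rpm):
                end = min(start + self.bin_size, self.span[1])
                fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")


def bin_quantify(intervals: np.ndarray, span: tuple[int, int],
                 bin_size: int = 60, library_size: int | None = None
                 ) -> BinnedTrack:
    """Binned overlap counts over ``span``, rpm-normalised.

    A read interval increments every bin it overlaps.  ``library_size``
    defaults to the number of input reads (all mapped reads should be passed
    when the track covers only part of the library's genome).
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    lo, hi = span
    if hi <= lo:
        raise ValueError("empty span")
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if library_size is None:
        library_size = len(intervals)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    n_bins = -(-(hi - lo) // bin_size)
    starts = np.clip(intervals[:, 0], lo, hi)
    ends = np.clip(intervals[:, 1], lo, hi)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    b0 = (starts - lo) // bin_size
    b1 = (ends - 1 - lo) // bin_size
    diff = np.zeros(n_bins + 1, dtype=np.int64)
    np.add.at(diff, b0, 1)
    np.add.at(diff, b1 + 1, -1)
    raw = np.cumsum(diff[:-1]).astype(float)
    rpm = raw * 1e6 / library_size
    return BinnedTrack(span=span, bin_size=bin_size, raw=raw, rpm=rpm,
                       library_size=library_size)


@dataclasses.dataclass
class MetaProfile:
    profile: np.ndarray            # mean per-bp coverage, length == window
    window: int
    n_sites: int
    rss_set: str

    @property
    def positions(self) -> np.ndarray:
        """Offsets relative to the RSS centre (position 0)."""
        return np.arange(self.window) - self.window // 2

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"offset": self.positions, "mean_coverage": self.profile}
                     ).to_csv(path, sep="\t", index=False)


def _site_centers(rss_list: Sequence) -> list[tuple[int, str]]:
    sites = []
    for site in rss_list:
        if isinstance(site, Segment):
            sites.append((site.rss_center, site.strand))
        else:
            center, strand = site
            sites.append((int(center), strand))
    return sites


def _per_site_coverage(intervals: np.ndarray, center: int, strand: str,
                       window: int, cut_sites: bool) -> np.ndarray:
    lo = center - window // 2
    hi = lo + window
    cov = np.zeros(window, dtype=float)
    if cut_sites:
        pos = intervals[:, 0]
        sel = pos[(pos >= lo) & (pos < hi)] - lo
        np.add.at(cov, sel, 1)
    else:
        s = np.clip(intervals[:, 0], lo, hi)
        e = np.clip(intervals[:, 1], lo, hi)
        keep = e > s
        diff = np.zeros(window + 1)
        np.add.at(diff, s[keep] - lo, 1)
        np.add.at(diff, e[keep] - lo, -1)
        cov = np.cumsum(diff[:-1])
    if strand == "-":
        cov = cov[::-1]
    return cov


def rss_metaprofile(intervals: np.ndarray, rss_list: Sequence,
                    window: int = 1000, rss_set: str = "",
                    cut_sites: bool = False) -> MetaProfile:
    """Mean per-bp coverage in an RSS-centred window, averaged over sites.

    ``rss_list`` holds :class:`~ighrep.locus.Segment` objects or
    ``(center, strand)`` pairs.  Minus-strand windows are flipped so the
    recombination-facing side is oriented identically at every site.
    """
    if len(rss_list) == 0:
        raise ValueError("empty RSS list")
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    total = np.zeros(window)
    sites = _site_centers(rss_list)
    for center, strand in sites:
        total += _per_site_coverage(intervals, center, strand, window, cut_sites)
    return MetaProfile(profile=total / len(sites), window=window,
                       n_sites=len(sites), rss_set=rss_set)


def rss_window_counts(intervals: np.ndarray, rss_list: Sequence,
                      window: int = 50, cut_sites: bool = False) -> pd.Series:
    """Per-RSS read counts over a centred window (reads counted once per
    site when they overlap the window)."""
    if len(rss_list) == 0:
        raise ValueError("empty RSS list")
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    counts = {}
    for i, site in enumerate(rss_list):
        if isinstance(site, Segment):
            center, name = site.rss_center, site.id
        else:
            center, name = int(site[0]), f"site{i}"
        lo = center - window // 2
        hi = lo + window
        if cut_sites:
            pos = intervals[:, 0]
            counts[name] = int(np.sum((pos >= lo) & (pos < hi)))
        else:
            counts[name] = int(np.sum((intervals[:, 1] > lo) & (intervals[:, 0] < hi)))
    return pd.Series(counts)
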