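"""Igh / Igkappa locus annotation model.

The murine immunoglobulin heavy-chain (*Igh*) locus carries ~195 V_H gene
segments (16 families falling into 3 evolutionary clans), a cluster of D_H
segments, and 4 J_H segments.  During B cell development the locus is
assembled by V(D)J recombination: first a D_H joins a J_H, then a V_H joins
the DJ_H intermediate.  Each segment is flanked by a recombination signal
sequence (RSS) on its recombination-facing side.  The kappa light-chain
locus contributes 162 Vkappa RSSs, used here only as accessibility controls.

This module defines the segment catalogue every other stage consumes:
segment identity, family / clan / chromatin-state / family-domain labels for
V_H genes, genomic intervals, RSS intervals and nucleotide sequences stored
in *recombination orientation* (the orientation in which the segment appears
in a rearranged VDJ molecule), with genomic strand kept as metadata.

The bundled default locus (:func:`default_locus`) is a *reconstructed,
synthetic* stand-in: segment counts, ordering, family structure and group
labels follow the published description of the locus, but the per-gene
clan/state assignments are a plausible reconstruction (the authoritative
per-gene table is not redistributed here) and all nucleotide sequences are
length-realistic pseudo-random placeholders generated deterministically from
the build tag.  A real annotation + FASTA can be supplied via
:func:`load_locus`.

Coordinates are 0-based half-open throughout; conversion from 1-based
formats must happen at import time.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "LocusModel",
    "LocusError",
    "LocusSchemaError",
    "LocusValidationError",
    "EmptyLocusError",
    "default_locus",
    "load_locus",
    "write_locus",
]

_BASES = np.array(list("ACGT"))

# RSS length by segment kind: 7-mer heptamer + spacer + 9-mer nonamer.
# V_H and J_H use 23-bp spacers (39 bp total), D_H and Vkappa 12-bp (28 bp).
RSS_LEN = {"VH": 39, "DH": 28, "JH": 39, "VK": 28}

VH_COUNT = 195
VK_COUNT = 162
VH_LEN = 300
VK_LEN = 300
JH_LEN = 52

# V_H family blocks in 3'->5' locus order (index 1 = most D-proximal gene).
# 16 families; sizes sum to 195.  Reconstructed layout, not authoritative.
_VH_FAMILY_BLOCKS = [
    ("7183", 1, 22),
    ("Q52", 23, 37),
    ("S107", 38, 41),
    ("X24", 42, 44),
    ("SM7", 45, 48),
    ("VGAM3.8", 49, 53),
    ("36-60", 54, 60),
    ("VH10", 61, 63),
    ("VH11", 64, 65),
    ("VH12", 66, 66),
    ("VH15", 67, 68),
    ("VH16", 69, 69),
    ("J606", 70, 74),
    ("VH14", 75, 86),
    ("J558", 87, 183),
    ("3609", 184, 195),
]

_CLAN_OF_FAMILY = {
    "J558": 1, "VGAM3.8": 1, "X24": 1, "SM7": 1, "VH12": 1, "VH15": 1, "VH16": 1,
    "Q52": 2, "3609": 2, "36-60": 2, "VH10": 2, "VH11": 2,
    "7183": 3, "S107": 3, "J606": 3, "VH14": 3,
}

# Local chromatin state classes previously assigned to V_H genes: the
# enhancer state covers clan 1 plus the distal 3609 family, the architectural
# state the remaining clan 2/3 families, and the background state the most
# D-proximal families.  Reconstruction at family resolution.
_STATE_OF_FAMILY = {
    "J558": "enhancer", "3609": "enhancer", "VGAM3.8": "enhancer",
    "VH12": "enhancer", "VH15": "enhancer", "VH16": "enhancer",
    "Q52": "architectural", "36-60": "architectural", "VH10": "architectural",
    "VH11": "architectural", "S107": "architectural", "J606": "architectural",
    "VH14": "architectural",
    "7183": "background", "X24": "background", "SM7": "background",
}

# D_H segments in 5'->3' genomic order with germline lengths.
_DH_SEGMENTS = [
    ("DFL16.1", 23), ("DFL16.2", 22), ("DSP2.2", 17), ("DSP2.3", 17),
    ("DSP2.4", 16), ("DSP2.5", 17), ("DSP2.6", 16), ("DSP2.7", 17),
    ("DSP2.9", 18), ("DSP2x5", 16), ("DSP2x3", 16), ("DST4", 18),
    ("DQ52", 16),
]

_TSV_COLUMNS = [
    "id", "kind", "family", "clan", "state", "domain",
    "chrom", "start", "end", "strand", "rss_start", "rss_end",
]


class LocusError(ValueError):
    """Base class for locus annotation problems."""


class LocusSchemaError(LocusError):
    """A required column or field is missing or unparseable."""


class LocusValidationError(LocusError):
    """The annotation violates a locus invariant (duplicate ids, bad RSS...)."""


class EmptyLocusError(LocusError):
    """The annotation contains no segments."""


@dataclasses.dataclass(frozen=True)
class Segment:
    """A single V/D/J/Vkappa gene segment.

    ``sequence`` is stored in recombination orientation; ``strand`` records
    the genomic strand.  ``rss_interval`` abuts the segment on the
    recombination-facing side.
    """

    id: str
    kind: str                      # VH | DH | JH | VK
    family: str | None
    clan: int | None               # V_H only
    chromatin_state: str | None    # V_H only: enhancer | architectural | background
    domain: str | None             # V_H only: family-domain label
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    rss_start: int
    rss_end: int

    def __post_init__(self):
        if self.kind not in ("VH", "DH", "JH", "VK"):
            raise LocusValidationError(f"unknown segment kind {self.kind!r}")
        if len(self.sequence) != self.end - self.start:
            raise LocusValidationError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise LocusValidationError(f"{self.id}: non-ACGTN characters in sequence")
        if self.kind == "VH" and (self.family is None or self.clan is None
                                  or self.chromatin_state is None or self.domain is None):
            raise LocusValidationError(f"{self.id}: V_H segments need family/clan/state/domain")
        if not (self.rss_end == self.start or self.rss_start == self.end):
            raise LocusValidationError(f"{self.id}: RSS not adjacent to segment")

    @property
    def rss_center(self) -> int:
        return (self.rss_start + self.rss_end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


class LocusModel:
    """Ordered, validated catalogue of gene segments.

    V_H segments are held in 3'->5' locus order: position 1 is the most
    D-proximal gene, position 195 the most distal.
    """

    def __init__(self, segments: Iterable[Segment], build_tag: str = "custom"):
        self.segments = list(segments)
        self.build_tag = build_tag
        if not self.segments:
            raise EmptyLocusError("locus model has no segments")
        self._by_id = {}
        for seg in self.segments:
            if seg.id in self._by_id:
                raise LocusValidationError(f"duplicate segment id {seg.id!r}")
            self._by_id[seg.id] = seg
        self.vh = [s for s in self.segments if s.kind == "VH"]
        self.dh = [s for s in self.segments if s.kind == "DH"]
        self.jh = [s for s in self.segments if s.kind == "JH"]
        self.vk = [s for s in self.segments if s.kind == "VK"]
        if not self.jh:
            raise LocusValidationError("locus model must contain at least one J_H segment")
        starts = [s.start for s in self.vh]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise LocusValidationError("V_H segments are not strictly ordered by coordinate")

    # -- queries ---------------------------------------------------------

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._by_id

    def __getitem__(self, seg_id: str) -> Segment:
        try:
            return self._by_id[seg_id]
        except KeyError:
            raise KeyError(f"unknown segment id {seg_id!r}") from None

    def vh_ids(self) -> list[str]:
        return [s.id for s in self.vh]

    def dh_ids(self) -> list[str]:
        return [s.id for s in self.dh]

    def jh_ids(self) -> list[str]:
        return [s.id for s in self.jh]

    def vh_index(self, gene_id: str) -> int:
        """1-based 3'->5' position of a V_H gene (1 = most D-proximal)."""
        for i, s in enumerate(self.vh, start=1):
            if s.id == gene_id:
                return i
        raise KeyError(f"{gene_id!r} is not a V_H gene")

    def group_of(self, gene_id: str, axis: str) -> str:
        """Group label of a gene along one of the grouping axes.

        ``axis`` is one of ``family``, ``clan``, ``state``, ``domain``.
        Clan, state and domain are defined for V_H segments only.
        """
        seg = self[gene_id]
        if axis == "family":
            if seg.family is None:
                raise TypeError(f"{gene_id}: no family for kind {seg.kind}")
            return seg.family
        if seg.kind != "VH":
            raise TypeError(f"axis {axis!r} is only defined for V_H segments")
        if axis == "clan":
            return f"clan {seg.clan}"
        if axis == "state":
            return seg.chromatin_state
        if axis == "domain":
            return seg.domain
        raise ValueError(f"unknown grouping axis {axis!r}")

    def vh_group_sizes(self, axis: str) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.vh:
            g = self.group_of(s.id, axis)
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    @property
    def family_domains(self) -> dict[str, str]:
        """Family -> family-domain label.  J558 splits positionally into
        proximal/central/distal domains; the split lives on the segments."""
        out: dict[str, str] = {}
        for s in self.vh:
            out.setdefault(s.family, s.domain)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments:
            rows.append({
                "id": s.id, "kind": s.kind,
                "family": s.family if s.family is not None else ".",
                "clan": s.clan if s.clan is not None else ".",
                "state": s.chromatin_state if s.chromatin_state is not None else ".",
                "domain": s.domain if s.domain is not None else ".",
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "strand": s.strand, "rss_start": s.rss_start, "rss_end": s.rss_end,
            })
        return pd.DataFrame(rows, columns=_TSV_COLUMNS)

    def to_bed6(self, path: str | Path) -> None:
        """Write segment intervals as BED6 (name = id, score = 0)."""
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.id}\t0\t{s.strand}\n")


# -- deterministic synthetic sequences -----------------------------------

def _synth_seq(build_tag: str, key: str, length: int) -> str:
    seed = zlib.crc32(f"{build_tag}:{key}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, length)])


def synthetic_flank(build_tag: str, seg_id: str, length: int = 150) -> str:
    """Deterministic pseudo-genomic context upstream of a segment, used by the
    simulator to model sonication fragments extending past the segment."""
    return _synth_seq(build_tag, f"{seg_id}:flank", length)


# -- default (bundled, synthetic) locus ----------------------------------

def _vh_domain(family: str, idx: int) -> str:
    if family in ("7183", "Q52"):
        return "7183/Q52"
    if family == "J606":
        return "J606"
    if family == "J558":
        if idx <= 118:
            return "proximal J558"
        if idx <= 151:
            return "central J558"
        return "distal J558"
    return "middle"


def default_locus(build_tag: str = "ighrep-synthetic-r1") -> LocusModel:
    """Build the bundled default locus model.

    195 V_H genes (16 families, 3 clans, 3 chromatin states, 6 family
    domains), 13 D_H, 4 J_H and 162 Vkappa RSS entries.  All sequences are
    synthetic placeholders derived deterministically from ``build_tag``.
    """
    segments: list[Segment] = []

    # J_H cluster, then D_H cluster, then V_H genes at increasing distance.
    jh_base = 1_000_000
    for j in range(4):
        start = jh_base + j * 400
        segments.append(Segment(
            id=f"JH{j + 1}", kind="JH", family=None, clan=None,
            chromatin_state=None, domain=None, chrom="chr12",
            start=start, end=start + JH_LEN, strand="+",
            sequence=_synth_seq(build_tag, f"JH{j + 1}:seq", JH_LEN),
            rss_start=start - RSS_LEN["JH"], rss_end=start,
        ))

    dh_base = 1_010_000
    for k, (did, dlen) in enumerate(_DH_SEGMENTS):
        start = dh_base + k * 600
        segments.append(Segment(
            id=did, kind="DH", family=did.rstrip("0123456789.x").replace("DSP2", "DSP"),
            clan=None, chromatin_state=None, domain=None, chrom="chr12",
            start=start, end=start + dlen, strand="+",
            sequence=_synth_seq(build_tag, f"{did}:seq", dlen),
            rss_start=start - RSS_LEN["DH"], rss_end=start,
        ))

    fam_of_idx = {}
    fam_rank = {}
    for fam, lo, hi in _VH_FAMILY_BLOCKS:
        for r, idx in enumerate(range(lo, hi + 1), start=1):
            fam_of_idx[idx] = fam
            fam_rank[idx] = r

    vh_base = 1_100_000
    for idx in range(1, VH_COUNT + 1):
        fam = fam_of_idx[idx]
        gid = "VH-81X" if idx == 2 else f"{fam}.{fam_rank[idx]}.{idx}"
        start = vh_base + (idx - 1) * 8_000
        # V_H genes sit on the minus strand: the recombination-facing (3')
        # end corresponds to the lower genomic coordinate.
        segments.append(Segment(
            id=gid, kind="VH", family=fam, clan=_CLAN_OF_FAMILY[fam],
            chromatin_state=_STATE_OF_FAMILY[fam], domain=_vh_domain(fam, idx),
            chrom="chr12", start=start, end=start + VH_LEN, strand="-",
            sequence=_synth_seq(build_tag, f"{gid}:seq", VH_LEN),
            rss_start=start - RSS_LEN["VH"], rss_end=start,
        ))

    vk_base = 2_000_000
    for i in range(VK_COUNT):
        gid = f"Vk{i // 12 + 1}.{i % 12 + 1}"
        start = vk_base + i * 8_000
        segments.append(Segment(
            id=gid, kind="VK", family=f"Vk{i // 12 + 1}", clan=None,
            chromatin_state=None, domain=None, chrom="chr6",
            start=start, end=start + VK_LEN, strand="+",
            sequence=_synth_seq(build_tag, f"{gid}:seq", VK_LEN),
            rss_start=start + VK_LEN, rss_end=start + VK_LEN + RSS_LEN["VK"],
        ))

    return LocusModel(segments, build_tag=build_tag)


# -- TSV / FASTA I/O -----------------------------------------------------

def write_locus(model: LocusModel, tsv_path: str | Path,
                fasta_path: str | Path | None = None) -> None:
    """Write the annotation TSV (and optionally the companion FASTA)."""
    frame = model.to_frame()
    with open(tsv_path, "w") as fh:
        fh.write(f"#build_tag={model.build_tag}\n")
        frame.to_csv(fh, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for s in model.segments:
                fh.write(f">{s.id}\n{s.sequence}\n")


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line.upper())
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def load_locus(tsv_path: str | Path, fasta_path: str | Path | None = None,
               synthesize_missing: bool = True) -> LocusModel:
    """Load and validate a locus annotation.

    The TSV must carry the columns written by :func:`write_locus`.  Sequences
    come from ``fasta_path`` when given; otherwise, if ``synthesize_missing``,
    deterministic placeholder sequences are generated from the build tag.
    """
    tsv_path = Path(tsv_path)
    build_tag = "custom"
    with open(tsv_path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "build_tag=" in first:
            build_tag = first.strip().split("build_tag=", 1)[1]
    try:
        frame = pd.read_csv(tsv_path, sep="\t", skiprows=skip, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyLocusError(f"{tsv_path}: empty annotation file") from None
    missing = [c for c in _TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise LocusSchemaError(f"{tsv_path}: missing required columns {missing}")
    if frame.empty:
        raise EmptyLocusError(f"{tsv_path}: annotation has zero segments")

    seqs = _read_fasta(fasta_path) if fasta_path is not None else {}
    segments = []
    seen = set()
    for row in frame.itertuples(index=False):
        if row.id in seen:
            raise LocusValidationError(f"duplicate segment id {row.id!r}")
        seen.add(row.id)
        start, end = int(row.start), int(row.end)
        if row.id in seqs:
            seq = seqs[row.id]
        elif synthesize_missing:
            seq = _synth_seq(build_tag, f"{row.id}:seq", end - start)
        else:
            raise LocusValidationError(f"{row.id}: sequence missing and synthesis disabled")
        segments.append(Segment(
            id=row.id, kind=row.kind,
            family=None if row.family == "." else row.family,
            clan=None if row.clan == "." else int(row.clan),
            chromatin_state=None if row.state == "." else row.state,
            domain=None if row.domain == "." else row.domain,
            chrom=row.chrom, start=start, end=end, strand=row.strand,
            sequence=seq, rss_start=int(row.rss_start), rss_end=int(row.rss_end),
        ))
    return LocusModel(segments, build_tag=build_tag)
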