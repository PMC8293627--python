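"""Germline segment assignment and event classification.

Each deduplicated molecule (its consensus read 2, or a rendered molecule
sequence) is matched directly against the locus model's segment sequences —
no genome index is needed at this scale:

1. **Orientation.** Both orientations are scored; the one whose end carries
   a J_H suffix match is the correctly orientated one, the other is
   rejected.
2. **J_H**: best semi-global match anchored at the read's J-proximal end —
   the longest germline suffix run (a bounded mismatch rate is tolerated).
3. **V_H**: best match at the opposite end, located with a 20-mer seed
   index over the germline V catalogue; a contiguous seed of
   ``min_v_seed`` bases is required.
4. **D_H**: searched strictly between the V match and the J match (or left
   of J for molecules without V) as the longest contiguous germline-D
   substring, requiring at least ``min_d_match`` bases.

Molecules with V+D+J are classed VDJ; with J but no V, DJ; without a J
match, unassigned.  Ties are broken toward fewer mismatches, then longer
match, then lower segment catalogue index (deterministic, flagged).
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .locus import LocusModel
from .simulate import revcomp

__all__ = [
    "AssignParams",
    "SegmentAssignment",
    "CountTable",
    "SegmentIndex",
    "assign_segments",
    "assign_all",
    "quantify",
    "dj_vdj_ratio",
]


@dataclasses.dataclass
class AssignParams:
    min_v_seed: int = 20
    min_d_match: int = 5
    min_j_seed: int = 15
    max_mismatch_rate: float = 0.1
    v_kmer: int = 20
    v_stride: int = 7
    d_seed: int = 5


@dataclasses.dataclass
class SegmentAssignment:
    molecule_id: str
    event_class: str               # "VDJ" | "DJ" | "unassigned"
    j_id: str | None = None
    j_span: tuple[int, int] | None = None     # on the oriented read
    d_id: str | None = None
    d_span: tuple[int, int] | None = None
    d_germ_span: tuple[int, int] | None = None
    v_id: str | None = None
    v_span: tuple[int, int] | None = None
    v_germ_offset: int | None = None          # read pos - germline pos
    orientation_ok: bool = True
    ambiguous: bool = False
    d_unresolved: bool = False
    oriented_seq: str | None = None


class SegmentIndex:
    """Precomputed match structures for one locus model."""

    def __init__(self, model: LocusModel, params: AssignParams | None = None):
        self.model = model
        self.params = params or AssignParams()
        self.j_list = [(s.id, s.sequence) for s in model.jh]
        self.d_list = [(s.id, s.sequence) for s in model.dh]
        k = self.params.v_kmer
        self.v_kmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
        self.v_list = [(s.id, s.sequence) for s in model.vh]
        for vi, (vid, seq) in enumerate(self.v_list):
            for p in range(len(seq) - k + 1):
                self.v_kmers[seq[p: p + k]].append((vi, p))
        ds = self.params.d_seed
        self.d_seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for di, (did, seq) in enumerate(self.d_list):
            for p in range(len(seq) - ds + 1):
                self.d_seeds[seq[p: p + ds]].append((di, p))


def _j_suffix_run(read: str, germ: str, max_mm_rate: float) -> int:
    """Longest m with read[-m:] ~ germ[-m:] at the allowed mismatch rate."""
    limit = min(len(read), len(germ))
    mm = 0
    best = 0
    for m in range(1, limit + 1):
        if read[-m] != germ[-m]:
            mm += 1
        if mm <= math.floor(max_mm_rate * m):
            best = m
    return best


def _find_v(seq: str, hi: int, index: SegmentIndex) -> tuple[int, int, int, bool] | None:
    """Locate the V segment in seq[:hi].

    Returns (v_index, read_end_of_match, germ_offset, ambiguous) where
    germ_offset maps read position -> germline position (read - offset).
    A 20-mer seed hit satisfies the contiguous ``min_v_seed`` requirement;
    the V/N boundary is the exact-match extension of the rightmost seed.
    """
    p = index.params
    k = p.v_kmer
    if hi < k:
        return None
    hits: dict[tuple[int, int], list[int]] = defaultdict(list)   # (vi, offset) -> seed read positions
    positions = list(range(0, hi - k + 1, p.v_stride))
    if positions[-1] != hi - k:
        positions.append(hi - k)
    for pos in positions:
        for vi, gp in index.v_kmers.get(seq[pos: pos + k], ()):
            hits[(vi, pos - gp)].append(pos)
    if not hits:
        return None
    ranked = sorted(hits.items(), key=lambda kv: (-len(kv[1]), kv[0][0]))
    (vi, off), seed_pos = ranked[0]
    ambiguous = (len(ranked) > 1 and len(ranked[1][1]) == len(seed_pos)
                 and ranked[1][0][0] != vi)
    germ = index.v_list[vi][1]
    # exact rightward extension from the rightmost seed to the V/N boundary
    end = min(hi, len(germ) + off)
    j = max(seed_pos) + k
    while j < end and seq[j] == germ[j - off]:
        j += 1
    return vi, j, off, ambiguous


def _find_d(seq: str, lo: int, hi: int, index: SegmentIndex
            ) -> tuple[int, int, int, int] | None:
    """Longest contiguous germline-D match within seq[lo:hi].

    Returns (d_index, read_start, germ_start, length); ties toward lower
    catalogue index, then leftmost placement.
    """
    p = index.params
    ds = p.d_seed
    if hi - lo < p.min_d_match:
        return None
    best = None   # (-length, d_index, read_start) ordering
    extended_to: dict[tuple[int, int], int] = {}   # (d_index, diagonal) -> run end
    for pos in range(lo, hi - ds + 1):
        for di, gp in index.d_seeds.get(seq[pos: pos + ds], ()):
            diag = (di, pos - gp)
            if pos < extended_to.get(diag, lo):
                continue   # seed inside an already-extended run on this diagonal
            germ = index.d_list[di][1]
            # extend left
            s_r, s_g = pos, gp
            while s_r > lo and s_g > 0 and seq[s_r - 1] == germ[s_g - 1]:
                s_r -= 1
                s_g -= 1
            # extend right
            e_r, e_g = pos + ds, gp + ds
            while e_r < hi and e_g < len(germ) and seq[e_r] == germ[e_g]:
                e_r += 1
                e_g += 1
            extended_to[diag] = e_r
            length = e_r - s_r
            if length < p.min_d_match:
                continue
            cand = (-length, di, s_r)
            if best is None or cand < best:
                best = cand
                best_full = (di, s_r, s_g, length)
    return None if best is None else best_full


def assign_segments(seq: str, index: SegmentIndex,
                    molecule_id: str = "", try_revcomp: bool = True
                    ) -> SegmentAssignment:
    """Assign germline segments to one molecule sequence."""
    p = index.params
    best_orient = None
    for oriented, flipped in ((seq, False), (revcomp(seq), True)) if try_revcomp \
            else ((seq, False),):
        for ji, (jid, jseq) in enumerate(index.j_list):
            run = _j_suffix_run(oriented, jseq, p.max_mismatch_rate)
            cand = (run, -ji, not flipped)
            if best_orient is None or cand > best_orient[0]:
                best_orient = (cand, oriented, flipped, ji, run)
    _, oriented, flipped, ji, run = best_orient
    if run < p.min_j_seed:
        return SegmentAssignment(molecule_id=molecule_id, event_class="unassigned",
                                 orientation_ok=False, oriented_seq=seq)
    jid = index.j_list[ji][0]
    j_start = len(oriented) - run
    asn = SegmentAssignment(
        molecule_id=molecule_id, event_class="DJ", j_id=jid,
        j_span=(j_start, len(oriented)), oriented_seq=oriented,
    )

    v_hit = _find_v(oriented, j_start, index)
    if v_hit is not None:
        vi, v_end, off, ambiguous = v_hit
        asn.v_id = index.v_list[vi][0]
        asn.v_span = (max(off, 0), v_end)
        asn.v_germ_offset = off
        asn.ambiguous = ambiguous
        asn.event_class = "VDJ"

    d_lo = asn.v_span[1] if asn.v_span else 0
    d_hit = _find_d(oriented, d_lo, j_start, index)
    if d_hit is not None:
        di, r_start, g_start, length = d_hit
        asn.d_id = index.d_list[di][0]
        asn.d_span = (r_start, r_start + length)
        asn.d_germ_span = (g_start, g_start + length)
    elif asn.event_class == "VDJ":
        asn.d_unresolved = True
    else:
        # no V and no D: a J-only read still counts as a DJ-stage molecule,
        # but its D is unresolved
        asn.d_unresolved = True
    return asn


def assign_all(seqs: Iterable[tuple[str, str]], index: SegmentIndex,
               try_revcomp: bool = True) -> list[SegmentAssignment]:
    """Assign a batch of (molecule_id, sequence) pairs."""
    return [assign_segments(s, index, molecule_id=mid, try_revcomp=try_revcomp)
            for mid, s in seqs]


# ----------------------------------------------------------------------
# quantification
# ----------------------------------------------------------------------

@dataclasses.dataclass
class CountTable:
    """Per-gene molecule counts for one sample."""

    v_counts: pd.Series            # over all V_H genes (VDJ molecules)
    d_counts: pd.Series            # over all D_H genes (VDJ + DJ molecules)
    n_vdj: int
    n_dj: int
    n_unassigned: int
    sample: str = ""
    genotype: str = ""

    def to_tsv(self, path: str | Path) -> None:
        rows = pd.concat([
            pd.DataFrame({"gene": self.v_counts.index, "kind": "VH",
                          "count": self.v_counts.values}),
            pd.DataFrame({"gene": self.d_counts.index, "kind": "DH",
                          "count": self.d_counts.values}),
        ])
        rows.to_csv(path, sep="\t", index=False)


def quantify(assignments: Sequence[SegmentAssignment], model: LocusModel,
             sample: str = "", genotype: str = "") -> CountTable:
    """Count molecules per gene: V_H among VDJ molecules, D_H among all
    classified molecules.  Order-independent."""
    v_counts = pd.Series(0, index=model.vh_ids(), dtype=int)
    d_counts = pd.Series(0, index=model.dh_ids(), dtype=int)
    n_vdj = n_dj = n_un = 0
    for a in assignments:
        if a.event_class == "VDJ":
            n_vdj += 1
            v_counts[a.v_id] += 1
            if a.d_id is not None:
                d_counts[a.d_id] += 1
        elif a.event_class == "DJ":
            n_dj += 1
            if a.d_id is not None:
                d_counts[a.d_id] += 1
        else:
            n_un += 1
    return CountTable(v_counts=v_counts, d_counts=d_counts, n_vdj=n_vdj,
                      n_dj=n_dj, n_unassigned=n_un, sample=sample,
                      genotype=genotype)


def dj_vdj_ratio(counts_or_assignments) -> float:
    """DJ : VDJ molecule ratio.

    Returns +inf when no VDJ molecules were seen and NaN when neither class
    was seen (both conditions are detectable from the return value).
    """
    if isinstance(counts_or_assignments, CountTable):
        n_dj, n_vdj = counts_or_assignments.n_dj, counts_or_assignments.n_vdj
    else:
        n_dj = sum(1 for a in counts_or_assignments if a.event_class == "DJ")
        n_vdj = sum(1 for a in counts_or_assignments if a.event_class == "VDJ")
    if n_vdj == 0:
        return math.nan if n_dj == 0 else math.inf
    return n_dj / n_vdj
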