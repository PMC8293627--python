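"""Junction decomposition and N-addition statistics.

A recombined molecule's junctions carry the signature of terminal
deoxynucleotidyl transferase (TdT): non-templated N nucleotides inserted
between the trimmed germline segments.  N-additions are absent in fetal
liver B cells and appear first in bone-marrow pro-B cells, so their
incidence distinguishes fetal from adult recombination.

Given a segment assignment, the parser delimits each junction:

* the V remnant is the longest read prefix region matching the germline V
  along the assignment diagonal (exact match, stopping at the first
  mismatch),
* the J remnant is the longest read suffix matching a germline J suffix,
* the D remnant is the highest-scoring (longest, ties toward the leftmost
  placement) contiguous germline-D substring strictly between them,
* ``vd_n`` / ``dj_n`` are whatever bases remain between the remnants.

When a junction base matches the germline continuation of a flanking
segment (microhomology), it is attributed to the templated segment —
V first, then J, then D — which makes the decomposition unique and minimises
the called N length; such junctions carry a microhomology flag, because the
called N length is then a lower bound on the true insertion.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assign import SegmentAssignment
from .locus import LocusModel

__all__ = [
    "JunctionAnnotation",
    "NAdditionSummary",
    "parse_junction",
    "summarize_n_additions",
]

HIST_CAP = 10   # histogram bins 0..9 plus a right overflow bin (>= 10)


@dataclasses.dataclass
class JunctionAnnotation:
    molecule_id: str
    event_class: str
    resolved: bool
    vd_n: str | None = None        # absent for DJ events
    dj_n: str | None = None
    v3: int | None = None          # observed trims
    d5: int | None = None
    d3: int | None = None
    j5: int | None = None
    vd_microhomology: bool = False
    dj_microhomology: bool = False


def _longest_common_substrings(region: str, germ: str, min_len: int
                               ) -> list[tuple[int, int, int]]:
    """All maximal-length common substrings as (region_start, germ_start, length)."""
    n, m = len(region), len(germ)
    if n < min_len or m < min_len:
        return []
    best = 0
    hits: list[tuple[int, int, int]] = []
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ci = region[i - 1]
        for j in range(1, m + 1):
            if ci == germ[j - 1]:
                length = prev[j - 1] + 1
                cur[j] = length
                if length > best:
                    best = length
                    hits = [(i - length, j - length, length)]
                elif length == best and best > 0:
                    hits.append((i - length, j - length, length))
        prev = cur
    if best < min_len:
        return []
    # keep only runs that are maximal (not extendable), i.e. recorded at
    # their full length: runs contained in longer ones share no entry here
    return hits


def parse_junction(assignment: SegmentAssignment, model: LocusModel,
                   min_d_match: int = 5) -> JunctionAnnotation:
    """Decompose the junction(s) of one assigned molecule.

    Requires the assignment to carry the oriented sequence and at least a J
    call; molecules whose D cannot be placed are returned unresolved and are
    excluded from summaries.
    """
    if assignment.event_class == "unassigned":
        raise ValueError("cannot parse junctions of an unassigned molecule")
    s = assignment.oriented_seq
    out = JunctionAnnotation(molecule_id=assignment.molecule_id,
                             event_class=assignment.event_class, resolved=False)

    j_seq = model[assignment.j_id].sequence
    # exact J suffix extension (mismatch handling happens upstream at dedup
    # consensus; assignment may have tolerated mismatches, parsing does not)
    run = 0
    limit = min(len(s), len(j_seq))
    while run < limit and s[-(run + 1)] == j_seq[-(run + 1)]:
        run += 1
    if run == 0:
        return out
    j_start = len(s) - run
    j5_obs = len(j_seq) - run

    if assignment.event_class == "VDJ":
        if assignment.v_germ_offset is None:
            return out
        off = assignment.v_germ_offset
        v_seq = model[assignment.v_id].sequence
        v_lo = max(off, 0)
        end = min(j_start, len(v_seq) + off)
        j = v_lo
        while j < end and s[j] == v_seq[j - off]:
            j += 1
        v_end = j
        v3_obs = len(v_seq) - (v_end - off)
        region_lo = v_end
    else:
        v_end = None
        v3_obs = None
        region_lo = 0

    if assignment.d_id is None:
        return out
    d_seq = model[assignment.d_id].sequence
    region = s[region_lo:j_start]
    hits = _longest_common_substrings(region, d_seq, min_d_match)
    if not hits:
        return out
    hits.sort()
    r_start, g_start, length = hits[0]
    tie = len({(h[0], h[2]) for h in hits}) > 1
    d_start = region_lo + r_start
    d_end = d_start + length
    d5_obs = g_start
    d3_obs = len(d_seq) - (g_start + length)

    dj_n = s[d_end:j_start]
    dj_flag = tie
    if d_end == j_start:
        # the boundary base could belong to either D (extending right) or J
        # (extending left): the decomposition is minimal but not unique
        if d3_obs > 0 and j_start < len(s) and s[j_start] == d_seq[len(d_seq) - d3_obs]:
            dj_flag = True
        if j5_obs > 0 and s[d_end - 1] == j_seq[j5_obs - 1]:
            dj_flag = True

    out.resolved = True
    out.dj_n = dj_n
    out.d5, out.d3, out.j5 = d5_obs, d3_obs, j5_obs
    out.dj_microhomology = dj_flag

    if assignment.event_class == "VDJ":
        vd_n = s[v_end:d_start]
        vd_flag = tie
        if d_start == v_end and v_end > max(assignment.v_germ_offset, 0):
            if d5_obs > 0 and s[v_end - 1] == d_seq[d5_obs - 1]:
                vd_flag = True
            v_germ_pos = v_end - assignment.v_germ_offset
            if v3_obs > 0 and v_germ_pos < len(model[assignment.v_id].sequence) \
                    and d_start < len(s) and s[d_start] == model[assignment.v_id].sequence[v_germ_pos]:
                vd_flag = True
        out.vd_n = vd_n
        out.v3 = v3_obs
        out.vd_microhomology = vd_flag

    return out


@dataclasses.dataclass
class NAdditionSummary:
    """Per-junction-type N-addition incidence and length distribution.

    ``hist`` has bins 0..9 plus a final overflow bin counting lengths of 10
    or more; fractions are over resolved junctions only.
    """

    n_junctions: dict[str, int]
    fraction_ge1: dict[str, float]
    fraction_gt1: dict[str, float]
    hist: dict[str, np.ndarray]
    n_unresolved: int

    def to_json(self, path: str | Path) -> None:
        data = {
            "n_junctions": self.n_junctions,
            "fraction_ge1": self.fraction_ge1,
            "fraction_gt1": self.fraction_gt1,
            "hist": {k: [int(x) for x in v] for k, v in self.hist.items()},
            "n_unresolved": self.n_unresolved,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    def hist_frame(self) -> pd.DataFrame:
        bins = [str(i) for i in range(HIST_CAP)] + [f"{HIST_CAP}+"]
        return pd.DataFrame({"n_additions": bins,
                             **{k: v for k, v in self.hist.items()}})


def summarize_n_additions(annotations: Sequence[JunctionAnnotation]
                          ) -> NAdditionSummary:
    """Aggregate junction annotations into incidence fractions and length
    histograms for the VD and DJ junction types."""
    lengths = {"VD": [], "DJ": []}
    unresolved = 0
    for a in annotations:
        if not a.resolved:
            unresolved += 1
            continue
        if a.event_class == "VDJ" and a.vd_n is not None:
            lengths["VD"].append(len(a.vd_n))
        if a.dj_n is not None:
            lengths["DJ"].append(len(a.dj_n))
    if not lengths["VD"] and not lengths["DJ"]:
        raise ValueError("no resolved junctions to summarise")
    n_j, ge1, gt1, hist = {}, {}, {}, {}
    for jt, vals in lengths.items():
        arr = np.asarray(vals, dtype=int)
        n_j[jt] = len(arr)
        if len(arr) == 0:
            continue
        ge1[jt] = float(np.mean(arr >= 1))
        gt1[jt] = float(np.mean(arr > 1))
        h = np.zeros(HIST_CAP + 1, dtype=int)
        capped = np.minimum(arr, HIST_CAP)
        np.add.at(h, capped, 1)
        hist[jt] = h
    return NAdditionSummary(n_junctions=n_j, fraction_ge1=ge1,
                            fraction_gt1=gt1, hist=hist,
                            n_unresolved=unresolved)
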