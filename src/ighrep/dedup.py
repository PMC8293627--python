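"""Molecular deduplication of VDJ-seq read pairs.

PCR duplicates, sequencing-error variants and genuine biological duplicates
are distinguished by keying each read pair on three fields:

* the 6-nt random barcode (UMI) at the start of read 1,
* the junction window: the first ``k`` bases of read 2 (read 2 is anchored
  at the J_H end, so this window spans the D_H-J_H and, for VDJ molecules,
  the V_H-D_H junction),
* the fragment anchor: the first 20 bases of read 1 after the UMI, a proxy
  for the sonication position (and, for VDJ molecules, the V_H identity)
  that needs no alignment.

Two reads belong to the same molecule when their UMIs are within
``umi_hamming_max``, their junction windows within ``window_hamming_max``
and their anchors within ``anchor_hamming_max`` (an unknown anchor never
blocks a merge).  Clusters are the connected components of this relation;
components are materialised by a count-ordered merge in which the
highest-count key of a component seeds the cluster and absorbs its
lower-count neighbours, which fixes the representative deterministically.

Identical keys are collapsed first, and near-miss candidate pairs are found
by pigeonholing (split the window into three parts and the UMI into two: any
pair within the Hamming tolerances must agree exactly on at least one part
of each), so the clustering never enumerates all read pairs.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "DedupParams",
    "DedupKey",
    "MolecularCluster",
    "DedupStats",
    "extract_key",
    "deduplicate",
    "dedup_fastq",
    "brute_force_clusters",
]

UMI_LEN = 6
ANCHOR_LEN = 20


@dataclasses.dataclass
class DedupParams:
    k: int = 60                    # junction window length (read 2 prefix)
    umi_hamming_max: int = 1
    window_hamming_max: int = 2
    anchor_hamming_max: int = 2
    exact: bool = False            # merge only byte-identical keys


@dataclasses.dataclass(frozen=True)
class DedupKey:
    umi: str
    window: str
    anchor: str | None             # None = unknown, never blocks a merge


@dataclasses.dataclass
class MolecularCluster:
    representative: str            # read-pair id
    members: list[str]
    key: DedupKey
    consensus_read2: str


@dataclasses.dataclass
class DedupStats:
    n_input: int
    n_skipped: int
    n_clusters: int
    duplication_hist: dict[int, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def hamming(a: str, b: str, limit: int) -> int:
    """Hamming distance, short-circuiting once ``limit`` is exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def extract_key(r1: str, r2: str, params: DedupParams) -> DedupKey | None:
    """Key fields of one read pair; None when the reads are too short.

    The UMI is clipped off read 1 before any downstream use; the anchor and
    the junction window are taken after clipping.
    """
    if len(r1) < UMI_LEN or len(r2) < params.k:
        return None
    umi = r1[:UMI_LEN].upper()
    rest = r1[UMI_LEN:]
    anchor = rest[:ANCHOR_LEN].upper() if len(rest) >= ANCHOR_LEN else None
    return DedupKey(umi=umi, window=r2[: params.k].upper(), anchor=anchor)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def _keys_mergeable(a: DedupKey, b: DedupKey, p: DedupParams) -> bool:
    if hamming(a.umi, b.umi, p.umi_hamming_max) > p.umi_hamming_max:
        return False
    if hamming(a.window, b.window, p.window_hamming_max) > p.window_hamming_max:
        return False
    if a.anchor is None or b.anchor is None:
        return True
    return hamming(a.anchor, b.anchor, p.anchor_hamming_max) <= p.anchor_hamming_max


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _candidate_pairs(keys: list[DedupKey], params: DedupParams) -> Iterable[tuple[int, int]]:
    """Near-miss candidate generation by pigeonholing window and UMI parts."""
    n_win_parts = params.window_hamming_max + 1
    part = params.k // n_win_parts
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for idx, key in enumerate(keys):
        for wi in range(n_win_parts):
            lo = wi * part
            hi = params.k if wi == n_win_parts - 1 else lo + part
            wpart = key.window[lo:hi]
            for ui in range(2):
                upart = key.umi[: UMI_LEN // 2] if ui == 0 else key.umi[UMI_LEN // 2:]
                buckets[(wi, wpart, ui, upart)].append(idx)
    seen: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = (members[i], members[j])
                if pair not in seen:
                    seen.add(pair)
                    yield pair


def _consensus(seqs: list[str]) -> str:
    if len(seqs) == 1:
        return seqs[0]
    count = Counter(seqs)
    top, n_top = count.most_common(1)[0]
    if n_top * 2 >= len(seqs) and len(count) <= 2:
        return top
    # per-position majority over members of the modal length
    length = Counter(len(s) for s in seqs).most_common(1)[0][0]
    same = [s for s in seqs if len(s) == length]
    cols = []
    for i in range(length):
        cols.append(Counter(s[i] for s in same).most_common(1)[0][0])
    return "".join(cols)


def deduplicate(read_pairs: Sequence[tuple[str, str, str, str, str]],
                params: DedupParams | None = None
                ) -> tuple[list[MolecularCluster], DedupStats]:
    """Collapse read pairs into molecular clusters.

    ``read_pairs`` holds ``(read_id, r1, q1, r2, q2)`` tuples.  Returns the
    clusters (a partition of all keyable read pairs) and accounting stats;
    reads too short to key are skipped and counted, never merged.
    """
    if params is None:
        params = DedupParams()
    keyed: dict[DedupKey, list[int]] = defaultdict(list)
    skipped = 0
    rows = list(read_pairs)
    for i, (rid, r1, q1, r2, q2) in enumerate(rows):
        key = extract_key(r1, r2, params)
        if key is None:
            skipped += 1
            continue
        keyed[key].append(i)

    keys = list(keyed.keys())
    uf = _UnionFind(len(keys))
    if not params.exact:
        for i, j in _candidate_pairs(keys, params):
            if _keys_mergeable(keys[i], keys[j], params):
                uf.union(i, j)
        # unknown-anchor keys are rare (short read 1); match them against
        # everything sharing a UMI half -- handled above since the anchor
        # check treats None as a wildcard.

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(len(keys)):
        components[uf.find(i)].append(i)

    clusters: list[MolecularCluster] = []
    for comp in components.values():
        # count-ordered: the highest-count key seeds the cluster
        comp.sort(key=lambda i: (-len(keyed[keys[i]]), keys[i].umi, keys[i].window))
        seed_key = keys[comp[0]]
        member_rows = [r for i in comp for r in keyed[keys[i]]]
        # representative: highest mean base quality, ties -> first seen
        def mean_qual(row: int) -> float:
            q = rows[row][2]
            return sum(q.encode()) / len(q) if q else 0.0
        rep_row = max(member_rows, key=lambda r: (mean_qual(r), -r))
        consensus = _consensus([rows[r][3] for r in member_rows])
        clusters.append(MolecularCluster(
            representative=rows[rep_row][0],
            members=[rows[r][0] for r in member_rows],
            key=seed_key,
            consensus_read2=consensus,
        ))

    hist = Counter(len(c.members) for c in clusters)
    stats = DedupStats(
        n_input=len(rows), n_skipped=skipped, n_clusters=len(clusters),
        duplication_hist=dict(sorted(hist.items())),
    )
    assert sum(len(c.members) for c in clusters) + skipped == len(rows)
    return clusters, stats


def brute_force_clusters(read_pairs: Sequence[tuple[str, str, str, str, str]],
                         params: DedupParams | None = None) -> list[set[str]]:
    """All-pairs connected-components oracle (quadratic; small inputs only)."""
    if params is None:
        params = DedupParams()
    rows = list(read_pairs)
    keyed = [(rid, extract_key(r1, r2, params))
             for rid, r1, q1, r2, q2 in rows]
    keyed = [(rid, k) for rid, k in keyed if k is not None]
    n = len(keyed)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if params.exact:
                if keyed[i][1] == keyed[j][1]:
                    uf.union(i, j)
            elif _keys_mergeable(keyed[i][1], keyed[j][1], params):
                uf.union(i, j)
    comps: dict[int, set[str]] = defaultdict(set)
    for i in range(n):
        comps[uf.find(i)].add(keyed[i][0])
    return list(comps.values())


# ----------------------------------------------------------------------
# file interface
# ----------------------------------------------------------------------

def read_fastq_pairs(path1: str | Path, path2: str | Path
                     ) -> list[tuple[str, str, str, str, str]]:
    pairs = []
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for e1, e2 in zip(f1, f2):
            pairs.append((e1.name, e1.sequence, e1.quality or "",
                          e2.sequence, e2.quality or ""))
    return pairs


def dedup_fastq(in1: str | Path, in2: str | Path, out_prefix: str | Path,
                params: DedupParams | None = None) -> DedupStats:
    """File-level interface: FASTQ pair in, representative FASTQ pair +
    clusters TSV + stats JSON out."""
    pairs = read_fastq_pairs(in1, in2)
    by_id = {p[0]: p for p in pairs}
    clusters, stats = deduplicate(pairs, params)
    out_prefix = Path(out_prefix)
    with open(f"{out_prefix}_R1.fastq", "w") as o1, \
            open(f"{out_prefix}_R2.fastq", "w") as o2:
        for c in clusters:
            rid, r1, q1, r2, q2 = by_id[c.representative]
            o1.write(f"@{rid}\n{r1}\n+\n{q1}\n")
            o2.write(f"@{rid}\n{r2}\n+\n{q2}\n")
    with open(f"{out_prefix}_clusters.tsv", "w") as fh:
        fh.write("molecule_id\tn_members\tmembers\tumi\twindow\n")
        for i, c in enumerate(clusters):
            fh.write(f"C{i:07d}\t{len(c.members)}\t{','.join(c.members)}"
                     f"\t{c.key.umi}\t{c.key.window}\n")
    stats.to_json(f"{out_prefix}_stats.json")
    return stats
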