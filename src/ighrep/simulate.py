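"""V(D)J recombination read simulator.

Generates truth-tabled synthetic VDJ-seq libraries.  Each simulated molecule
is either a fully recombined VDJ allele or a partially recombined DJ allele:

    VDJ:  V' + N1 + D' + N2 + J'
    DJ:          D' + N2 + J'

where the primes denote exonuclease-trimmed germline segments and N1/N2 are
non-templated (TdT) insertions.  A genotype preset fixes the statistical
structure the assay reads out:

* V_H / D_H / J_H usage frequency vectors,
* the DJ : VDJ mixture ratio (12:1 in fetal liver, ~2:1 in wild-type bone
  marrow, ~1:1 in IL-7Ralpha-knockout bone marrow),
* the per-junction probability of zero N-additions (wild-type BM junctions
  carry N-additions ~80% of the time, knockout ~60%; fetal liver is tuned so
  that 25% (VD) and 15% (DJ) of junctions carry more than one insertion),
* trimming and insertion-length laws.

Library emission models the VDJ-seq read geometry: molecules acquire a 6-nt
random barcode (UMI), a sonication point upstream of the junction, PCR
duplication, and substitution sequencing errors.  Read 2 is anchored at the
J_H end and covers both junctions; read 1 begins with the UMI followed by
sequence from the fragmentation point.  A truth table links every read back
to its source molecule.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .locus import LocusModel, default_locus, synthetic_flank

__all__ = [
    "GenotypePreset",
    "RecombinationEvent",
    "ReadPair",
    "Library",
    "preset",
    "active_vh_positions",
    "sample_event",
    "sample_events",
    "render_molecule",
    "emit_library",
    "PRESET_NAMES",
]

PRESET_NAMES = ("WT_BM", "IL7RaKO_BM", "FL")

UMI_LEN = 6
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ----------------------------------------------------------------------
# designated actively-recombining V_H gene sets (1-based 3'->5' positions)
# ----------------------------------------------------------------------

def active_vh_positions(name: str) -> list[int]:
    """Positions of the V_H genes a genotype preset recombines at all.

    Sizes match the published binomial-test calls: 128 genes in wild-type
    bone marrow and 84 in the IL-7Ralpha knockout, with all but three of the
    knockout genes inside the wild-type set.  The fetal-liver set (150
    genes) is a free choice consistent with a mildly 3'-biased but broad
    repertoire.
    """
    if name == "WT_BM":
        return list(range(1, 101)) + list(range(101, 183, 3))
    if name == "IL7RaKO_BM":
        return list(range(1, 82)) + [185, 190, 195]
    if name == "FL":
        return list(range(1, 151))
    raise ValueError(f"unknown preset name {name!r}")


def _vh_freq(n_genes: int, top5: Sequence[float], active: Sequence[int]) -> np.ndarray:
    """Frequency vector: fixed mass on positions 1..5, remainder uniform over
    the rest of the active set, zero elsewhere."""
    freq = np.zeros(n_genes)
    for i, p in enumerate(top5):
        freq[i] = p
    rest = [a for a in active if a > 5]
    freq[np.array(rest) - 1] = (1.0 - sum(top5)) / len(rest)
    return freq


# truncated-geometric insertion length law shared by all presets
INSERT_LEN_P = 0.2
INSERT_LEN_MAX = 10


def _p_no_insert_from_gt1(target_gt1: float) -> float:
    """Zero-insertion probability that yields a target fraction of junctions
    with more than one N-addition under the shared length law."""
    norm = 1.0 - (1.0 - INSERT_LEN_P) ** INSERT_LEN_MAX
    p_ge2_given_ins = 1.0 - INSERT_LEN_P / norm
    return 1.0 - target_gt1 / p_ge2_given_ins


@dataclasses.dataclass
class GenotypePreset:
    """Statistical structure of one genotype's repertoire.

    ``vh_freq``/``dh_freq``/``jh_freq`` are probability vectors over the
    locus model's V_H/D_H/J_H segments in catalogue order.  Trim lengths per
    segment end follow a geometric law with success probability ``trim_p``
    clipped at ``trim_max``; insertion lengths follow a geometric law with
    success probability ``insert_len_p`` truncated to 1..``insert_len_max``.
    PCR copy numbers are 1 + Poisson(``pcr_copies_mean`` - 1).
    """

    name: str
    vh_freq: np.ndarray
    dh_freq: np.ndarray
    jh_freq: np.ndarray
    dj_to_vdj_ratio: float
    p_no_insert_vd: float
    p_no_insert_dj: float
    insert_len_p: float = INSERT_LEN_P
    insert_len_max: int = INSERT_LEN_MAX
    trim_p: float = 0.8
    trim_max: int = 8
    pcr_copies_mean: float = 3.0

    def validate(self) -> None:
        for label, vec in (("vh_freq", self.vh_freq), ("dh_freq", self.dh_freq),
                           ("jh_freq", self.jh_freq)):
            vec = np.asarray(vec, dtype=float)
            if vec.ndim != 1 or np.any(vec < 0):
                raise ValueError(f"{label}: must be a nonnegative vector")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{label}: probabilities sum to {vec.sum()}, not 1")
        if self.dj_to_vdj_ratio < 0:
            raise ValueError("dj_to_vdj_ratio must be >= 0")
        for p in (self.p_no_insert_vd, self.p_no_insert_dj):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_no_insert must lie in [0, 1]")
        if not 0 < self.insert_len_p < 1 or not 0 < self.trim_p <= 1:
            raise ValueError("geometric parameters must lie in (0, 1]")

    # -- (de)serialisation ------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("vh_freq", "dh_freq", "jh_freq"):
            data[key] = [float(x) for x in data[key]]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenotypePreset":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("vh_freq", "dh_freq", "jh_freq"):
            data[key] = np.asarray(data[key], dtype=float)
        obj = cls(**data)
        obj.validate()
        return obj


def preset(name: str, model: LocusModel | None = None) -> GenotypePreset:
    """Bundled genotype presets pinned to the published repertoire summaries.

    * ``FL``: DJ:VDJ = 12, V_H-81X at 11% of VDJ molecules, sparse
      N-additions (25% / 15% of VD / DJ junctions with >1 insertion).
    * ``WT_BM``: DJ:VDJ = 2, five most 3' V_H genes at 20% (V_H-81X 7%),
      80% of junctions with at least one N-addition.
    * ``IL7RaKO_BM``: DJ:VDJ = 1, top five at 45% (V_H-81X 14%), 60% of
      junctions with N-additions, central DSP D_H segments silent.
    """
    if model is None:
        model = default_locus()
    g = len(model.vh)
    n_d = len(model.dh)
    n_j = len(model.jh)
    jh = np.full(n_j, 1.0 / n_j)
    dh_uniform = np.full(n_d, 1.0 / n_d)
    active = active_vh_positions(name) if name in PRESET_NAMES else None

    if name == "WT_BM":
        return GenotypePreset(
            name=name,
            vh_freq=_vh_freq(g, [0.04, 0.07, 0.035, 0.03, 0.025], active),
            dh_freq=dh_uniform, jh_freq=jh,
            dj_to_vdj_ratio=2.0, p_no_insert_vd=0.2, p_no_insert_dj=0.2,
        )
    if name == "IL7RaKO_BM":
        dh_ids = model.dh_ids()
        dh = np.zeros(n_d)
        boosted = {"DQ52": 0.18, "DFL16.1": 0.18, "DSP2.9": 0.15}
        silent = {"DSP2x5", "DSP2x3", "DSP2.3", "DSP2.5"}
        others = [d for d in dh_ids if d not in boosted and d not in silent]
        for i, d in enumerate(dh_ids):
            if d in boosted:
                dh[i] = boosted[d]
            elif d not in silent:
                dh[i] = (1.0 - sum(boosted.values())) / len(others)
        return GenotypePreset(
            name=name,
            vh_freq=_vh_freq(g, [0.10, 0.14, 0.09, 0.07, 0.05], active),
            dh_freq=dh, jh_freq=jh,
            dj_to_vdj_ratio=1.0, p_no_insert_vd=0.4, p_no_insert_dj=0.4,
        )
    if name == "FL":
        return GenotypePreset(
            name=name,
            vh_freq=_vh_freq(g, [0.05, 0.11, 0.04, 0.035, 0.03], active),
            dh_freq=dh_uniform, jh_freq=jh,
            dj_to_vdj_ratio=12.0,
            p_no_insert_vd=_p_no_insert_from_gt1(0.25),
            p_no_insert_dj=_p_no_insert_from_gt1(0.15),
        )
    raise ValueError(f"unknown preset name {name!r}; use one of {PRESET_NAMES}")


# ----------------------------------------------------------------------
# events
# ----------------------------------------------------------------------

@dataclasses.dataclass
class RecombinationEvent:
    """One simulated molecule; the simulator's truth record."""

    molecule_id: str
    event_class: str               # "VDJ" | "DJ"
    v_id: str | None
    d_id: str
    j_id: str
    v3: int                        # trims: V 3' end, D 5'/3' ends, J 5' end
    d5: int
    d3: int
    j5: int
    n_vd: str | None               # absent for DJ events
    n_dj: str
    umi: str
    n_pcr_copies: int


def _trunc_geometric_lengths(rng, n: int, p: float, lmax: int) -> np.ndarray:
    """Lengths in 1..lmax, P(L) proportional to (1-p)^(L-1)."""
    w = p * (1.0 - p) ** np.arange(lmax)
    w /= w.sum()
    return rng.choice(np.arange(1, lmax + 1), size=n, p=w)


def sample_events(pset: GenotypePreset, model: LocusModel, n: int,
                  rng: np.random.Generator) -> list[RecombinationEvent]:
    """Sample ``n`` recombination events.

    Event class is DJ with probability r/(1+r) where r is the preset's
    DJ:VDJ ratio; segments are drawn from the preset frequency vectors,
    trims from the trim law (clipped so every remnant keeps >= 1 base for D
    and >= 1 base overall), and N-strings are empty with the per-junction
    zero-insertion probability, else uniformly random bases with truncated
    geometric length.
    """
    pset.validate()
    vh_ids = model.vh_ids()
    dh_ids = model.dh_ids()
    jh_ids = model.jh_ids()
    d_len = {d: model[d].length for d in dh_ids}

    r = pset.dj_to_vdj_ratio
    p_dj = r / (1.0 + r) if math.isfinite(r) else 1.0
    is_dj = rng.random(n) < p_dj

    v_idx = rng.choice(len(vh_ids), size=n, p=pset.vh_freq)
    d_idx = rng.choice(len(dh_ids), size=n, p=pset.dh_freq)
    j_idx = rng.choice(len(jh_ids), size=n, p=pset.jh_freq)

    trims = np.minimum(rng.geometric(pset.trim_p, size=(n, 4)) - 1, pset.trim_max)
    has_vd = rng.random(n) >= pset.p_no_insert_vd
    has_dj = rng.random(n) >= pset.p_no_insert_dj
    vd_lens = _trunc_geometric_lengths(rng, n, pset.insert_len_p, pset.insert_len_max)
    dj_lens = _trunc_geometric_lengths(rng, n, pset.insert_len_p, pset.insert_len_max)
    copies = 1 + rng.poisson(max(pset.pcr_copies_mean - 1.0, 0.0), size=n)
    bases = "ACGT"

    events = []
    for i in range(n):
        dj = bool(is_dj[i])
        d_id = dh_ids[d_idx[i]]
        v3, d5, d3, j5 = (int(x) for x in trims[i])
        d3 = min(d3, d_len[d_id] - d5 - 1)   # keep >= 1 D base
        n_vd = None
        if not dj and has_vd[i]:
            n_vd = "".join(bases[b] for b in rng.integers(0, 4, int(vd_lens[i])))
        elif not dj:
            n_vd = ""
        n_dj = ""
        if has_dj[i]:
            n_dj = "".join(bases[b] for b in rng.integers(0, 4, int(dj_lens[i])))
        umi = "".join(bases[b] for b in rng.integers(0, 4, UMI_LEN))
        events.append(RecombinationEvent(
            molecule_id=f"M{i:07d}",
            event_class="DJ" if dj else "VDJ",
            v_id=None if dj else vh_ids[v_idx[i]],
            d_id=d_id, j_id=jh_ids[j_idx[i]],
            v3=0 if dj else v3, d5=d5, d3=d3, j5=j5,
            n_vd=n_vd, n_dj=n_dj, umi=umi,
            n_pcr_copies=int(copies[i]),
        ))
    return events


def sample_event(pset: GenotypePreset, model: LocusModel,
                 rng: np.random.Generator) -> RecombinationEvent:
    return sample_events(pset, model, 1, rng)[0]


def render_molecule(event: RecombinationEvent, model: LocusModel) -> str:
    """Nucleotide sequence of the recombined molecule, V->J orientation."""
    d_seq = model[event.d_id].sequence
    j_seq = model[event.j_id].sequence
    if event.d5 + event.d3 > len(d_seq):
        raise ValueError(f"{event.molecule_id}: D trims exceed segment length")
    if event.j5 > len(j_seq):
        raise ValueError(f"{event.molecule_id}: J trim exceeds segment length")
    d_part = d_seq[event.d5: len(d_seq) - event.d3]
    j_part = j_seq[event.j5:]
    if event.event_class == "DJ":
        return d_part + event.n_dj + j_part
    v_seq = model[event.v_id].sequence
    if event.v3 > len(v_seq):
        raise ValueError(f"{event.molecule_id}: V trim exceeds segment length")
    v_part = v_seq[: len(v_seq) - event.v3]
    return v_part + (event.n_vd or "") + d_part + event.n_dj + j_part


# ----------------------------------------------------------------------
# library emission
# ----------------------------------------------------------------------

@dataclasses.dataclass
class ReadPair:
    read_id: str
    r1: str
    q1: str
    r2: str
    q2: str


@dataclasses.dataclass
class Library:
    """Emitted read pairs plus the truth table linking reads to molecules."""

    read_pairs: list[ReadPair]
    truth_events: pd.DataFrame     # one row per molecule
    truth_reads: pd.DataFrame      # read_id -> molecule_id

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        for path, which in ((path1, "r1"), (path2, "r2")):
            op = gzip.open if str(path).endswith(".gz") else open
            with op(path, "wt") as fh:
                for rp in self.read_pairs:
                    seq = rp.r1 if which == "r1" else rp.r2
                    qual = rp.q1 if which == "r1" else rp.q2
                    fh.write(f"@{rp.read_id}\n{seq}\n+\n{qual}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth_events.to_csv(path, sep="\t", index=False)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    bases = "ACGT"
    for p in pos:
        old = chars[p]
        new = bases[rng.integers(0, 3)]
        if new == old:          # shift to guarantee a substitution
            new = bases[(bases.index(old) + 1) % 4]
        chars[p] = new
    return "".join(chars)


FLANK_LEN = 150
_MIN_FLANK_KEEP = 20   # fragments keep >= 20 upstream-flank bases for DJ molecules


def emit_library(events: Sequence[RecombinationEvent], model: LocusModel,
                 seq_err: float, rng: np.random.Generator,
                 read_len: int = 250) -> Library:
    """Render molecules and emit UMI-tagged paired-end reads.

    Each molecule is embedded in its anchor segment's upstream pseudo-genomic
    flank (the V_H gene for VDJ, the D_H gene for DJ) and cut at a random
    fragmentation point, emulating sonication.  Read 1 = UMI + fragment
    start; read 2 = reverse complement of the fragment's J-proximal end.
    Every molecule yields ``n_pcr_copies`` identical read pairs before
    sequencing error.
    """
    if not events:
        raise ValueError("emit_library: no events supplied")
    if read_len < 80:
        raise ValueError("read_len too short to span the junction window")
    pairs: list[ReadPair] = []
    reads_rows = []
    flank_cache: dict[str, str] = {}

    for ev in events:
        mol = render_molecule(ev, model)
        anchor = ev.v_id if ev.event_class == "VDJ" else ev.d_id
        if anchor not in flank_cache:
            flank_cache[anchor] = synthetic_flank(model.build_tag, anchor, FLANK_LEN)
        template = flank_cache[anchor] + mol
        if ev.event_class == "VDJ":
            v_keep = len(model[ev.v_id].sequence) - ev.v3
            max_off = FLANK_LEN - _MIN_FLANK_KEEP + v_keep // 2
        else:
            max_off = FLANK_LEN - _MIN_FLANK_KEEP
        offset = int(rng.integers(0, max_off + 1))
        fragment = template[offset:]
        r1_clean = ev.umi + fragment[: read_len - UMI_LEN]
        r2_clean = revcomp(fragment[-read_len:])
        for c in range(ev.n_pcr_copies):
            rid = f"{ev.molecule_id}.{c}"
            r1 = _apply_errors(r1_clean, seq_err, rng)
            r2 = _apply_errors(r2_clean, seq_err, rng)
            pairs.append(ReadPair(rid, r1, "I" * len(r1), r2, "I" * len(r2)))
            reads_rows.append((rid, ev.molecule_id))

    truth_events = pd.DataFrame([dataclasses.asdict(ev) for ev in events])
    truth_reads = pd.DataFrame(reads_rows, columns=["read_id", "molecule_id"])
    if truth_reads["read_id"].duplicated().any():
        raise AssertionError("duplicate read ids in truth table")
    return Library(pairs, truth_events, truth_reads)
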