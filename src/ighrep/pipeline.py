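"""End-to-end convenience wrappers: reads -> molecules -> repertoire.

Chains deduplication, segment assignment and junction parsing over a read
library (in memory or FASTQ files), returning everything downstream
statistics need.  Each stage is importable on its own; this module only
fixes the plumbing between them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

from .assign import (AssignParams, CountTable, SegmentAssignment, SegmentIndex,
                     assign_segments, dj_vdj_ratio, quantify)
from .dedup import DedupParams, DedupStats, MolecularCluster, deduplicate, read_fastq_pairs
from .junctions import JunctionAnnotation, parse_junction
from .locus import LocusModel

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_fastq"]


@dataclasses.dataclass
class PipelineResult:
    clusters: list[MolecularCluster]
    dedup_stats: DedupStats
    assignments: list[SegmentAssignment]
    counts: CountTable
    junctions: list[JunctionAnnotation]

    @property
    def dj_vdj_ratio(self) -> float:
        return dj_vdj_ratio(self.counts)


def run_pipeline(read_pairs: Sequence[tuple[str, str, str, str, str]],
                 model: LocusModel,
                 dedup_params: DedupParams | None = None,
                 assign_params: AssignParams | None = None,
                 parse_junctions: bool = True,
                 sample: str = "", genotype: str = "") -> PipelineResult:
    """Deduplicate, assign and (optionally) junction-parse a read library."""
    clusters, stats = deduplicate(read_pairs, dedup_params)
    index = SegmentIndex(model, assign_params)
    assignments = [
        assign_segments(c.consensus_read2, index, molecule_id=c.representative)
        for c in clusters
    ]
    counts = quantify(assignments, model, sample=sample, genotype=genotype)
    junctions = []
    if parse_junctions:
        min_d = (assign_params or AssignParams()).min_d_match
        junctions = [parse_junction(a, model, min_d_match=min_d)
                     for a in assignments if a.event_class != "unassigned"]
    return PipelineResult(clusters=clusters, dedup_stats=stats,
                          assignments=assignments, counts=counts,
                          junctions=junctions)


def run_pipeline_fastq(fastq1: str | Path, fastq2: str | Path,
                       model: LocusModel, **kwargs) -> PipelineResult:
    return run_pipeline(read_fastq_pairs(fastq1, fastq2), model, **kwargs)
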