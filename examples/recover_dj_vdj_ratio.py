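"""Simulate a fetal-liver VDJ-seq library and recover its DJ:VDJ ratio.

Fetal liver pro-B cells carry mostly partially recombined (DJ) alleles:
the bundled FL preset fixes the DJ:VDJ mixture at 12:1. This script emits
a full read library (UMIs, PCR duplicates, sequencing errors), then runs
deduplication and segment assignment and compares the recovered ratio with
the simulated truth.
"""

import numpy as np

import ighrep as ig

model = ig.default_locus()
rng = np.random.default_rng(0)

preset = ig.preset("FL", model)
events = ig.sample_events(preset, model, 20_000, rng)
library = ig.emit_library(events, model, seq_err=0.001, rng=rng)

result = ig.run_pipeline(
    [(p.read_id, p.r1, p.q1, p.r2, p.q2) for p in library.read_pairs],
    model, parse_junctions=False)

true_dj = sum(e.event_class == "DJ" for e in events)
print(f"molecules simulated : {len(events)} ({true_dj} DJ)")
print(f"read pairs emitted  : {len(library.read_pairs)}")
print(f"molecules recovered : {result.dedup_stats.n_clusters}")
print(f"DJ:VDJ recovered    : {result.dj_vdj_ratio:.2f}  (preset 12, "
      f"sampled truth {true_dj / (len(events) - true_dj):.2f})")
# The recovered ratio should sit within binomial sampling error of 12:
# deduplication has removed the ~3x PCR duplication without conflating
# distinct molecules that share a junction.
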