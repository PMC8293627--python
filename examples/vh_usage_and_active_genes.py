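"""V_H usage skew and actively-recombining gene calls, WT vs knockout.

IL-7R-deficient bone-marrow pro-B cells use a severely 3'-skewed V_H
repertoire. This script simulates VDJ molecules for both genotypes,
quantifies per-gene usage, runs the binomial active test, and aggregates
usage by family domain.
"""

import dataclasses

import numpy as np
import pandas as pd

import ighrep as ig
from ighrep.assign import SegmentIndex, assign_segments, quantify
from ighrep.stats import aggregate_by_group, binomial_active_test, normalize_frequencies

model = ig.default_locus()
index = SegmentIndex(model)

for name in ("WT_BM", "IL7RaKO_BM"):
    rng = np.random.default_rng(1)
    preset = dataclasses.replace(ig.preset(name, model), dj_to_vdj_ratio=0.0)
    events = ig.sample_events(preset, model, 50_000, rng)
    assignments = [assign_segments(ig.render_molecule(e, model), index,
                                   molecule_id=e.molecule_id, try_revcomp=False)
                   for e in events]
    counts = quantify(assignments, model).v_counts
    freq = normalize_frequencies(counts)
    table = binomial_active_test(counts)
    domains = aggregate_by_group(freq, model, "domain")
    print(f"\n{name}:")
    print(f"  top-5 3' V_H genes : {freq.iloc[:5].sum():5.1f}% of VDJ reads")
    print(f"  V_H-81X            : {freq['VH-81X']:5.1f}%")
    print(f"  active V_H genes   : {int(table['active'].sum())} "
          f"(binomial test, BH q < 0.05)")
    print(f"  7183/Q52 domain    : {domains.loc['7183/Q52', 'sum']:5.1f}% "
          f"(distal J558 {domains.loc['distal J558', 'sum']:.1f}%)")
# Expected: WT spreads usage across the locus (128 active genes, top-5
# ~20%); the knockout concentrates ~45% of usage on the five most
# D-proximal genes and calls ~84 genes active.
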