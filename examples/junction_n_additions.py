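"""N-addition fingerprinting of junctions across genotypes.

TdT, which inserts non-templated nucleotides at coding joins, is absent in
fetal liver and active in bone marrow — so the fraction of junctions with
N-additions distinguishes fetal from adult recombination. This script
parses simulated junctions and summarises insertion incidence per genotype.
"""

import dataclasses

import numpy as np

import ighrep as ig
from ighrep.assign import SegmentIndex, assign_segments
from ighrep.junctions import parse_junction, summarize_n_additions

model = ig.default_locus()
index = SegmentIndex(model)

print(f"{'genotype':<12} {'VD >=1':>7} {'VD >1':>7} {'DJ >=1':>7} {'DJ >1':>7}")
for name in ("WT_BM", "IL7RaKO_BM", "FL"):
    rng = np.random.default_rng(2)
    preset = dataclasses.replace(ig.preset(name, model), dj_to_vdj_ratio=0.0)
    events = ig.sample_events(preset, model, 10_000, rng)
    annotations = []
    for e in events:
        a = assign_segments(ig.render_molecule(e, model), index,
                            molecule_id=e.molecule_id, try_revcomp=False)
        annotations.append(parse_junction(a, model))
    s = summarize_n_additions(annotations)
    print(f"{name:<12} "
          f"{100 * s.fraction_ge1['VD']:6.1f}% {100 * s.fraction_gt1['VD']:6.1f}% "
          f"{100 * s.fraction_ge1['DJ']:6.1f}% {100 * s.fraction_gt1['DJ']:6.1f}%")
# Expected: ~80% of WT junctions carry N-additions, ~60% in the knockout
# (so knockout B cells recombine de novo in the marrow), while fetal liver
# shows >1 insertion in only ~25% (VD) / ~15% (DJ) of junctions. Values
# run 1-2 points low: minimal-N parsing attributes microhomologous
# boundary bases to the germline segments.
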