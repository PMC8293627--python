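"""RSS-centred accessibility meta-profiles and binned coverage tracks.

Chromatin accessibility around recombination signal sequences (RSSs) is a
readout of locus activation: V_H RSSs in pro-B cells sit in an accessibility
peak while the kappa light-chain Vkappa RSSs (not yet activated at this
stage) do not. This script builds synthetic accessibility reads that are
enriched at V_H RSSs only, then computes the 1,000-bp meta-profiles, per-RSS
50-bp window counts with a group comparison, and a 60-bp rpm track.
"""

import numpy as np

import ighrep as ig
from ighrep.profiles import bin_quantify, rss_metaprofile, rss_window_counts
from ighrep.stats import compare_groups

model = ig.default_locus()
rng = np.random.default_rng(3)

# background reads across the V_H region + focal reads at V_H RSS centres
vh_lo = model.vh[0].rss_start - 2_000
vh_hi = model.vh[-1].end + 2_000
bg_starts = rng.integers(vh_lo, vh_hi, 30_000)
reads = [np.stack([bg_starts, bg_starts + 80], axis=1)]
for seg in model.vh:
    centers = rng.normal(seg.rss_center, 60, 40).astype(int)
    reads.append(np.stack([centers - 40, centers + 40], axis=1))
vh_reads = np.vstack(reads)

# Vkappa region: background only (locus not yet activated)
vk_lo, vk_hi = model.vk[0].start - 2_000, model.vk[-1].rss_end + 2_000
vk_starts = rng.integers(vk_lo, vk_hi, 30_000)
vk_reads = np.stack([vk_starts, vk_starts + 80], axis=1)

vh_prof = rss_metaprofile(vh_reads, model.vh, window=1000, rss_set="VH")
vk_prof = rss_metaprofile(vk_reads, model.vk, window=1000, rss_set="VK")
print(f"V_H RSS meta-profile ({vh_prof.n_sites} sites): "
      f"centre {vh_prof.profile[500]:.2f}, edge {vh_prof.profile[0]:.2f}")
print(f"Vk  RSS meta-profile ({vk_prof.n_sites} sites): "
      f"centre {vk_prof.profile[500]:.2f}, edge {vk_prof.profile[0]:.2f}")

vh_counts = rss_window_counts(vh_reads, model.vh, window=50)
vk_counts = rss_window_counts(vk_reads, model.vk, window=50)
cmp = compare_groups({"VH": vh_counts.values, "VK": vk_counts.values})
print(f"50-bp window counts: VH mean {vh_counts.mean():.1f}, "
      f"VK mean {vk_counts.mean():.1f}; {cmp.test_used} "
      f"stat {cmp.statistic:.1f}, p = {cmp.p_value:.3g}")

track = bin_quantify(vh_reads, span=(vh_lo, vh_lo + 60_000), bin_size=60,
                     library_size=len(vh_reads))
print(f"60-bp rpm track over 60 kb: {len(track.raw)} bins, "
      f"max {track.rpm.max():.0f} rpm")
# Expected: the V_H profile peaks at the RSS centre while the Vkappa
# profile stays flat, and the 50-bp window counts separate the two RSS
# sets decisively.
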