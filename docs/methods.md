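# Methods

## Scope and model

`ighrep` analyses DNA-based repertoire sequencing of the murine *Igh* locus:
libraries that capture both partially (DJ) and fully (VDJ) recombined
alleles from genomic DNA of pro-B cells. The pipeline proceeds

    reads -> molecular deduplication -> segment assignment -> junction
    decomposition -> repertoire statistics / coverage profiles

and every stage can be exercised against a bundled V(D)J read simulator
that carries a truth table, so recovery of the repertoire parameters is
testable without any external data.

A recombined molecule is modelled as

    VDJ:  V' + N1 + D' + N2 + J'          DJ:  D' + N2 + J'

where `X'` is a germline segment with independently drawn exonuclease trims
at each coding end and `N1`/`N2` are non-templated (TdT) insertions.
P-nucleotides are not modelled. The sequenced fragment embeds the molecule
in its upstream genomic context (the V gene for VDJ molecules, the D gene
for DJ molecules) cut at a random sonication point; read 2 is anchored at
the J end and spans both junctions, read 1 starts with a 6-nt random
barcode (UMI) followed by the fragment start. Sequencing error is a uniform
per-base substitution channel; PCR duplication gives each molecule
`1 + Poisson(mean - 1)` read pairs.

## Locus model

The bundled catalogue has 195 V_H genes (16 families, clans 1/2/3 of sizes
113/39/43, chromatin states enhancer/architectural/background of sizes
118/48/29, six family domains), 13 D_H, 4 J_H and 162 Vkappa RSS entries.
V_H genes are indexed 1..195 from the most D-proximal (gene 2 is V_H-81X)
to the most distal. Coordinates are 0-based half-open; sequences are stored
in recombination orientation with genomic strand as metadata; each RSS
interval abuts its segment on the recombination-facing side (39 bp for
23-spacer RSSs at V_H/J_H, 28 bp for 12-spacer RSSs at D_H/Vkappa).

The per-gene clan/state labels are a *reconstruction at family resolution*,
not an authoritative annotation, and all nucleotide sequences are
length-realistic pseudo-random placeholders generated deterministically
from the build tag (V_H/Vkappa 300 bp, J_H 52 bp, D_H 16-23 bp). A real
annotation TSV plus companion FASTA can be supplied instead. Placeholder
sequences make segment discrimination easier than real data, where family
members are homologous: assignment accuracy measured here is an upper
bound on real-data accuracy.

## Genotype presets

The simulator's defaults pin the study conditions of the three genotypes:

| parameter | WT_BM | IL7RaKO_BM | FL |
|---|---|---|---|
| DJ : VDJ ratio | 2 | 1 | 12 |
| top-5 3' V_H share | 20% (81X 7%) | 45% (81X 14%) | 26.5% (81X 11%) |
| active V_H genes | 128 | 84 (3 outside WT set) | 150 |
| P(no N-insert), VD / DJ | 0.2 / 0.2 | 0.4 / 0.4 | 0.678 / 0.807 |

Non-top active genes share the remaining mass uniformly — the flattest
profile compatible with the published top-gene shares, which also maximises
the power of the binomial active test (see below). The fetal-liver active
set size (150) and its zero-insertion probabilities are free choices: the
latter are derived analytically so that the fraction of junctions with more
than one insertion equals 0.25 (VD) and 0.15 (DJ) under the shared
insertion-length law. The knockout D_H vector silences the four central DSP
segments and boosts DQ52, DFL16.1 and DSP2.9.

Insertion lengths follow a geometric law with success 0.2 truncated to
1..10 (matching the plotted support of up to ten additions; mean about 3.7).
Trims are geometric with P(0) = 0.8, clipped at 8 nt and at one remaining
D base. Light trimming is a deliberate default: the junction parser
attributes boundary bases to templated segments (minimal-N), so each
junction edge under-calls with probability about 1/4 x P(adjacent trim > 0),
and P(trim>0) = 0.2 keeps the expected downward bias of the >=1-insertion
fraction under 3 percentage points (measured ~1.8 at the WT preset). Real
junctions trim more aggressively; analyses of heavily trimmed data should
expect a correspondingly larger minimal-N bias.

## Deduplication

Reads are keyed on (UMI, junction window = first 60 bases of read 2,
fragment anchor = first 20 bases of read 1 after UMI clipping). Two reads
are mergeable when UMIs are within Hamming distance 1, windows within 2 and
anchors within 2 (an unknown anchor never blocks). Clusters are the
connected components of this relation, materialised by a count-ordered
merge in which each component's highest-count key seeds the cluster and
absorbs its lower-count neighbours; candidate near-miss pairs are found by
pigeonholing (3 window parts x 2 UMI halves), so runtime stays near-linear.
The anchor is compared fuzzily like the other fields because a single
sequencing error in an exact anchor class would split ~2% of PCR families
at error rate 1e-3. The representative is the highest mean-quality member;
the consensus read 2 is a per-position majority vote. These thresholds are
standard UMI-network practice, not a reproduction of the original
pipeline's (unstated) tolerances, and are all configurable; an exact-match
mode is available.

Residual error: two distinct molecules merge only when they collide on UMI
neighbourhood, junction window and sonication position simultaneously;
at 50,000 molecules this loses ~0.5% of DJ molecules in the most
homogeneous (FL) library and shifts the recovered DJ:VDJ ratio by < 0.1.

## Segment assignment

Direct matching against the segment catalogue replaces genome alignment.
Both orientations are scored; the orientation carrying the best J suffix
run (>= 15 nt at <= 10% mismatches, anchored at the read end) is kept. The
V gene is located with a 20-mer seed index (stride 7, so any error-free
20-mer window is hit) and voted by seed count; the V/N boundary is the
exact extension of the rightmost seed. The D segment is the longest
contiguous germline-D run (>= 5 nt, seed-and-extend over 5-mers) strictly
between the V and J matches. Ties break toward fewer mismatches, longer
matches, then lower catalogue index, deterministically and flagged.
Molecules with V+D+J are VDJ; J without V is DJ; no J is unassigned. VDJ
molecules whose D cannot be placed (trimming can leave < 5 informative
bases) are flagged and kept in the count table but excluded from junction
summaries. On error-free synthetic data V and J assignment is exact and D
assignment is > 99.9% correct.

## Junction decomposition

Within the oriented read, the V remnant is extended exactly (zero
mismatches) from the assignment diagonal, the J remnant backwards from the
read end, and the D remnant is the longest common substring with the
germline D between them (ties: leftmost, flagged). The gaps are the called
N-insertions. Boundary bases that match a germline continuation are
attributed to the templated segment with precedence V, then J, then D —
minimal-N attribution in the spirit of deterministic junction delimitation.
Consequences, all tested: the called N length never exceeds the true one;
it equals the truth whenever no base adjacent to a boundary matches a
germline continuation; and insert bases that mimic the germline
continuation of a trimmed segment are silently absorbed (undetectable in
principle), producing the bounded incidence bias quantified above.
Microhomology flags mark junctions whose decomposition is not unique
(boundary bases attributable to two segments, or tied D placements).

## Repertoire statistics

Active-recombination calls use a one-sided exact binomial test per gene
against the uniform null p0 = 1/G over all annotated genes of that kind
(the minimal "expected by chance" model; a capture-efficiency-weighted p0
would need external data), with Benjamini-Hochberg correction at q < 0.05.
Frequencies are percent of total quantified molecules of the kind.
Genotype comparisons are log2 ratios of replicate-mean frequencies with
test-sample zeros flagged rather than pseudocounted and both-zero genes
dropped. Group comparisons run Shapiro-Wilk per group at 0.05 (groups of
n < 3 cannot be tested and are treated as normal): all-normal data get a
two-tailed type-III ANOVA with pairwise pooled-variance t tests, otherwise
Kruskal-Wallis with pairwise Wilcoxon rank-sum tests; pairwise p values
are BH-adjusted.

Power note: at N = 50,000 molecules and G = 195, the BH threshold sits
near count 290 while a uniform-floor active gene in the WT profile (0.65%
of reads) expects 325 +- 18 — about 2 sigma of margin. Exact recovery of
all 128 WT active genes therefore fails for a minority of floor genes at
many seeds (observed 125-128), whereas the knockout profile (79 floor
genes at 0.70%, ~3 sigma margin) recovers exactly 84 at most seeds. This
is a property of the stated sample size, not of the test implementation.

## Coverage profiles

Binned tracks tile a stated span with fixed 60-bp bins; a read increments
every bin it overlaps (overlap counting, the probe-quantification
convention; midpoint-style counting can be had by passing cut sites), and
counts are rpm-normalised by an explicit library size defaulting to the
input read count. RSS meta-profiles accumulate per-bp coverage in 1,000-bp
windows centred on each RSS, flipping minus-strand windows so the
recombination-facing side is oriented identically, then average over
sites; 50-bp centred window counts per RSS feed the group tests. Whether
such assays should count full fragments or transposase cut sites is
ambiguous; full intervals are the default and a cut-site mode is provided.

## Numerical and degenerate-input conventions

Probability vectors must sum to 1 within 1e-9. DJ:VDJ ratio of an
assignment set with no VDJ molecules is +inf, with no molecules at all NaN.
Zero-total count tables are errors for normalisation and testing. Empty
annotation files, missing columns and duplicate ids raise typed errors.
All randomness flows through caller-supplied numpy generators; identical
(preset, seed) pairs produce byte-identical FASTQ and truth tables.

## Test problem sizes

Unit tests run at 10^3-10^4 molecules; end-to-end recovery tests use
50,000 molecules per genotype for mixture ratios and usage shares
(3-sigma binomial/multinomial tolerances), 10,000 molecules for junction
statistics (+-3 percentage points, covering the minimal-N bias), and
oracle suites (brute-force clustering, per-base coverage, reference
statistical implementations) on small instances at exact or 1e-8
tolerance. These sizes put sampling error well below the tolerances while
keeping the whole suite to a few minutes.

## Known limitations

Placeholder sequences lack family homology, somatic hypermutation is not
modelled, junction parsing assumes substitution-only errors survive
consensus, no productive/unproductive classification, no P-nucleotides, no
clonotype grouping, and real-data concordance with IMGT delimitation is
not claimed (IMGT's internal parameters are not public).
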