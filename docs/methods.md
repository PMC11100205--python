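# Methods

`telotype` characterizes individual telomere alleles from long sequencing
reads. Human chromosome ends carry, in order: subtelomere, a region of
*telomere variant repeats* (TVRs — canonical TTAGGG units modified by a
substitution such as TCAGGG or by an indel such as TTAAGGG, occurring in
blocks), and the pure canonical telomere. TVR block patterns are inherited
and effectively allele-specific, which is what makes it possible to
assign reads to individual alleles and report an allele-specific telomere
length (ATL) distribution rather than a genome-wide average.

## Pipeline

### 1. Read selection and boundary localization

A read is usable when it ends in telomere sequence on exactly one side
and carries enough non-telomere (subtelomere) sequence on the other to be
anchored to a chromosome arm. Candidate reads must contain at least
`min_copies` (default 10) non-overlapping canonical repeats in one
orientation; reads with strong canonical signal in both orientations
(telomere at both ends) are excluded. Reads are normalized to the
G-strand with the telomere at the 3' end.

The telomere/subtelomere boundary is the start of the terminal run of
sliding windows (default 100 bp) whose repeat-match density stays at or
above `tel_density`. The density threshold defaults to 0.5: pure telomere
tiles a window at ~1.0 while i.i.d. random sequence sits near 0.11
(median over seeds; empirically below 0.31 in every one of 200 null
draws), so the midpoint separates the two regimes with a wide margin. Up
to `tip_tolerance` (200 bp) of low-density sequence at the extreme
telomeric tip is tolerated as adapter/low-quality tail. Reads with fewer
than `min_subtel` (1000 bp) subtelomeric bases are dropped — shorter
flanks cannot be mapped confidently to an arm.

The density boundary is systematically a few tens of bp proximal of the
true junction (a window is called telomeric once roughly half of it is),
so the encoded "telomere region" usually begins with a short stretch of
subtelomere. This is harmless downstream: it encodes as unknown symbols,
is shared by all reads of a cluster, and sits before the TVR boundary.

### 2. Symbol encoding

The telomere region is tiled with exact matches to a curated repeat table
(canonical TTAGGG; substitution variants such as TCAGGG, TGAGGG, TTGGGG;
rarer variants; and error-mode families: canonical repeats modified by
homopolymer indels, e.g. the TAGG/TAGGG/TAGGGG family). Matching is
greedy longest-first — a TTAGGGG septamer must not be shadowed by its
TTAGGG prefix — with ties broken by table order and left-to-right scan; a
shorter repeat partially overlapping an accepted match survives only if
its unclaimed remnant is itself a table entry (the remnant is then found
by that entry's own scan). Each matched repeat becomes one symbol from an
amino-acid-style alphabet; unmatched runs become `?` symbols at one per
6 bp so they stay commensurate with repeat symbols under alignment. Base
coordinates of every symbol are retained for length calculations.

An isolated homopolymer-indel-family symbol flanked by canonical symbols
is relabeled canonical: this is the signature of the dominant long-read
sequencing error (homopolymer indels, to which the GGG-rich repeats are
especially prone), and real variant repeats occur in blocks. The rule is
applied to a fixed point and never touches substitution-type variants or
runs of length ≥ 2.

### 3. Clustering into alleles

Each pair of reads is scored by optimal global alignment of their symbol
strings (match +5, mismatch/gap −4; `?` matches nothing, itself
included). Scores become distances d(a,b) = 1 − S(a,b)/min(S(a,a),
S(b,b)), clipped to [0,1] — the normalization used for progressive-MSA
guide trees. Two numerical choices matter here:

- **Common-prefix comparison.** Strings are truncated to the first
  `max_tvr_symbols` (500) symbols and each pair is compared over its
  common prefix length. Both strings start at the subtelomere junction,
  so pattern differences show up as mismatches inside the shared window,
  while telomere-*length* differences — biology, not allele identity —
  contribute no end-gap penalty. Without this, reads of one allele with
  short and long telomeres drift apart in distance and can split.
- **Banded scoring.** The all-pairs matrix uses a banded global DP
  (|i−j| ≤ 48 after the length difference is absorbed). Reads of the same
  allele differ by scattered errors with net indel shifts far below the
  band, where the banded score equals the unrestricted optimum (verified
  against the full DP in tests); a pair whose optimal path would leave
  the band can only be scored lower, i.e. pushed further apart, which is
  inconsequential for already-dissimilar pairs. Self-scores use the
  closed form (the diagonal is optimal).

Distances are clustered with Ward-linkage agglomerative clustering and
the dendrogram is cut at `cut` (default 0.40). Within-allele distances
under the error model sit well below ~0.2 and between-allele distances
near 1; Ward merge heights for a cloud of mutually equidistant points
equal that distance, so 0.40 leaves generous margin on both sides.
Clusters smaller than `min_reads` (3) are set aside as unassigned — a
consensus over one or two reads is error-dominated.

Each preliminary cluster is then refined in two passes: (1) its members
are re-clustered at the more aggressive `aggressive_cut` (0.25), which
separates alleles whose TVR patterns share a long prefix; (2) members'
telomere-proximal subtelomere sequence (the distal `subtel_compare_bp` =
1000 bp, nucleotide-level alignment under the same +5/−4 scheme) is
clustered at `subtel_cut` (0.25), which separates alleles whose TVRs are
near-identical but whose flanks clearly differ. Clusters whose median
per-read variant-repeat count is below `min_variants` (5) are flagged
*blank*: their TVR carries no usable signature, so all blank reads are
pooled and re-grouped purely by subtelomere distance. None of the three
cut values is dictated by the underlying method description; all are
exposed as flags, and intermediate dendrograms can be inspected via the
plotting output.

### 4. Consensus, TVR boundary, ATL

Per cluster, a consensus symbol string is built by center-star multiple
alignment: the medoid member (largest summed similarity) is the star
center, every member is aligned to it, and the pairwise alignments are
merged on center coordinates, pooling insertions that land in the same
slot. The consensus scoring matrix keeps +5 for variant matches but
scores canonical-canonical matches 0, so alignments are pinned by the
variant blocks rather than the abundant canonical spacer. One numerical
subtlety: with canonical matches at 0, a deletion+insertion pair (−8)
ties two mismatches (−8) whenever only canonical symbols lie between
them, and arbitrary gap placement then corrupts column votes; the gap
score therefore carries an epsilon tie-break (−0.01) that resolves exact
ties toward mismatches and changes nothing else. Columns are decided by
majority vote (ties toward canonical, then table order); gap-majority
columns — member-private insertions, or distal columns most members do
not reach — are dropped; singleton indel-variant pruning is re-applied to
the consensus.

The TVR boundary is placed immediately after the smallest consensus
prefix containing `boundary_q` (95%) of its variant symbols: effectively
the most distal variant repeat, made robust against sporadic
error-induced variants deep in the telomere. A variant-free consensus is
a blank TVR with boundary 0.

Each member's ATL is the distance from the boundary — projected onto the
member through its alignment to the consensus, so member indels do not
bias the length — to the member's telomeric end, clamped at 0. The
cluster reports the full ATL distribution plus a representative value:
75th percentile by default (the summary that proved most stable across
sequencing runs of the same sample), with mean/median/max/any percentile
selectable.

### 5. Subtelomere anchoring

The reference panel holds the most distal 500 kb of each chromosome arm
(q arms as-is, p arms reverse-complemented so every reference ends at its
telomere junction), from one or more assemblies. The built-in mapper
sketches references with (k=15, w=10) minimizers under a fixed 64-bit
mixing hash (deterministic across runs), shortlists references sharing
≥ 95% of the best seed count, and refines near-ties by semi-global edit
distance (edlib), keeping every reference within max(2, 0.5% of query
length) edits of the best — the margin that makes a 99.9%-identical
reference twin an explicit tie rather than an arbitrary pick. Members
with < `min_subtel` subtelomere are skipped. Hits to the same arm from
different assemblies are pooled; arms supported by a majority of voting
members are reported, with `ambiguous=true` whenever more than one arm
survives. External mappers can be substituted through the same
query→scored-hits contract.

## The simulator

`telotype.simulate` generates reads with complete per-read truth. An
allele is subtelomere + decoded TVR pattern + canonical telomere whose
per-read length is drawn from Normal(tl_mean, tl_sd) truncated at 0 —
within-sample telomere-length heterogeneity across cells. Defaults, fixed
once as plausible values for human telomere-capture-style data:
subtelomere flank 2000 bp (uniform random, unique per allele); TVR
patterns of 3–10 variant blocks, 1–20 repeats each, separated by 2–15
canonical repeats, with block symbols drawn at weights that put G-type,
J-type and C-type first, matching their ranking in real TVR composition;
tl_mean uniform in 2000–6000 bp, tl_sd 300 bp. Coverage is diploid: each
allele receives round(coverage/2) reads (or Poisson(coverage/2) under
`depth_model="poisson"`, used for coverage-titration experiments).

Errors: per base, substitution probability `error_rate · 0.4` and indel
probability `error_rate · 0.6`, the latter multiplied by
`homopolymer_bias` (3×) inside homopolymer runs of ≥ 3 bp; insertions
duplicate the local base. This reproduces the dominant long-read failure
mode in telomeres (homopolymer indels in the GGG runs). Reads are emitted
on a random strand, as complete molecules by default (telomere-capture)
or as random normal-length fragments under `wgs_fragmentation`.

The trio generator gives a child one allele per arm per parent and, with
a configurable probability, deletes the most distal variant block of an
inherited pattern — the de novo change mode observed at the
telomere-proximal edge of real inherited TVR regions.

What the simulator does *not* model: read-level quality scores, chimeric
reads, the large systematic telomere-region artifacts seen on some
platforms, subtelomere paralogy between real chromosome arms (simulated
flanks are mutually random unless constructed otherwise), and
cell-population TL dynamics beyond a normal distribution. Passing tests
on this generator therefore demonstrate the pipeline's internal
correctness and error-robustness under the stated error model, not
performance on any particular real dataset.

Generated TVR patterns use substitution-type variants only: an
indel-family singleton in a pattern would be indistinguishable from a
sequencing error and correctly pruned, so encode(decode(p)) = p holds by
construction exactly for the family of patterns the generator emits.

## Test and acceptance problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline on
samples of 2–12 alleles with 10–30 reads per allele at 1% error (the
low-error long-read regime), coverage titrations of a 12-allele sample
from one Poisson-30x run thinned to 5–30x, and 1000-string
matcher/oracle comparisons — sizes chosen so the whole suite completes
in minutes on one CPU while every stage is exercised end to end.
Recovery, purity, consensus identity, boundary and ATL accuracy are
measured against simulator truth; determinism is checked byte-for-byte
on the report.

## Known limitations

- Homozygous alleles (two arms with identical TVR and near-identical
  subtelomere) merge into a single reported cluster; this is inherent to
  the method, not a defect the pipeline attempts to fix.
- The boundary estimate inherits the sliding-window's ~half-window
  proximal bias; reported TVR lengths include a short unknown-symbol
  prefix of subtelomeric sequence.
- Ward cut values are heuristics on a normalized distance; samples with
  unusual error profiles may need the exposed flags adjusted, guided by
  the intermediate dendrogram plots.
- The built-in minimizer mapper is designed for panels of diverged
  synthetic or curated references; for real multi-megabase references an
  external mapper adapter is the intended route.
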