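# Methods

## Problem and model

A hybrid-scaffolding run aligns contig label maps (in-silico digests of the
draft contigs) to an assembled optical map, the *anchor*. The run's output
bundle — key file, contig and anchor CMAPs, XMAPs — fixes the order,
orientation and approximate spacing of the contigs, but every junction is
emitted conservatively: adjacent contigs are separated by a sentinel gap
even when their maps share labels, which duplicates the shared sequence.
`mapfuse` treats that bundle as the single source of evidence and resolves
each junction by one of three rules (shared-label fusion, gap sizing with
local-alignment rescue, containment reinsertion), as summarized in the
README. This note records the modelling assumptions, parameter choices and
numerical conventions behind the implementation.

Assumptions inherited from the evidence model:

* the anchor's label order is correct (misjoins in the hybrid scaffold are
  out of scope; the tool never reorders contigs);
* contig label maps are exact digests of the contig sequence — positional
  uncertainty lives on the anchor side (optical sizing error), so cut
  positions derived from contig CMAPs are sequence-exact;
* one alignment per contig is trustworthy: if a contig aligns to several
  anchors, only the highest-confidence anchor is kept (prevents the same
  sequence appearing in two scaffolds); the discarded alignments are
  logged.

## Coordinate conventions

CMAP/XMAP positions are kept as printed (1-based bp, possibly fractional).
Rounding to sequence indices happens exactly once, at cut time, half-up.
A reverse-aligned contig is reverse-complemented into anchor orientation
before any arithmetic; a label at native position *p* on a contig of
length *L* maps to oriented position *L − p + 1*. This mirror keeps the
labelled base itself fixed, which is what makes zero-noise fixtures
reconstruct the source genome byte-for-byte across all four orientation
combinations — the property the test suite asserts. (A mirror of *L − p*,
off by one base, fails that reconstruction.)

At a shared-label fusion with cut positions *P_k*, *P_n* (oriented), the
left contig contributes bases [1, P_k] and the right contig (P_n, length];
the labelled base is therefore kept exactly once, from the left contig.

## Junction parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `gap_merge_threshold` | 1000 | bp | estimated gaps at or below this trigger the alignment rescue |
| `window` | 30 000 | bp | terminal window of each contig aligned during rescue |
| `min_align_score` | 5000 | score | minimum local-alignment score to fuse |
| `min_gap` | 13 | bp | sentinel emitted when a junction stays unresolved |

The first three are the published operating point of this post-processing
procedure; the 13-N sentinel is the upstream scaffolder's own convention
for an unsized junction, so keeping it preserves the "unresolved" signal
while satisfying AGP's requirement of a positive gap length. Estimated
gaps may be negative (predicted overlap); when the rescue fails they are
clamped to the sentinel and the estimate is retained in the decision
table.

## Local aligner

Scoring is match +1, mismatch −1, gap-open −1 with free gap extension,
approximating the PSL score (matches − mismatches − gap opens) so the 5000
threshold transfers. `N` never matches anything, including another `N` —
conservative next to gap-adjacent sequence.

Two execution paths share the scoring scheme:

* **Exact DP** when the product of window lengths is at most
  `full_dp_max_cells` (4×10⁶). Free extension collapses Gotoh's gap states
  into running maxima, so each DP row is a few vectorized numpy
  operations; traceback recovers spans and match/mismatch/gap counts, and
  the identity `score = matches − mismatches − gap_opens` is asserted in
  tests against an independent Smith-Waterman implementation.
* **Seed-and-extend** for larger windows: exact 11-mer seeds are merged per
  diagonal, extended to maximal gapless segments under an X-drop rule
  (X = 20), and colinear segments are chained with one gap-open penalty per
  join. Restricting large-window alignments to seed-derived gapless
  segments is essential, not an optimization: under free gap extension an
  *unrestricted* optimal path through two unrelated 30 kb windows chains
  thousands of short spurious match runs and can exceed any fixed
  threshold, whereas seed-chained scores on unrelated windows stay in the
  low hundreds. This mirrors how seed-based aligners actually behave and
  preserves the decision boundary: planted exact overlaps ≥ 6 kb score
  above 5000, overlaps ≤ 200 bp cannot.

An adapter for an external `blat` binary (PSL parsing, same return
contract) is provided for users who want fidelity with the original
workflow; the builtin backend is the default and the one under test.

## Containment

Containment is resolved before pairwise adjacency, innermost span first,
so a contained contig is never treated as a linear neighbor. The insert
replaces the host's sequence between the outermost shared labels with the
contained contig's sequence between its own copies of those labels; the
contained contig's flanks outside that interval are dropped (they
duplicate host sequence by construction). Ties in the label-count
comparison keep the host and emit the contained contig as a singleton —
the conservative reading. Degenerate geometries (fewer than two shared
labels, inverted label order, host region already consumed by an earlier
edit) also fall back to the singleton, never to sequence loss.

## Multi-channel arbitration

Two-enzyme runs contribute one CMAP/XMAP per channel. When both channels
yield shared labels for a pair, the channel whose last shared label sits
furthest along the anchor wins (cut closest to the junction); an exact tie
goes to the channel with more shared labels. Gap estimation uses each
contig's highest-confidence alignment.

## Synthetic fixtures

The generator emulates the validation design of the original experiment at
desk scale. Defaults: 5 Mb uniform-random genome, 8 gap junctions
(3–100 kb), 8 overlap junctions, 2 contained contigs, channels DLE-1
(`CTTAAG`) and BspQI (`GCTCTTC`), ~25% of contigs embedded
reverse-complemented. Overlap junctions are planted in three
sub-populations so each resolution path is exercised independently:
labelled (a channel-1 motif is guaranteed inside the overlap, planting one
if none occurred), alignable (motif occurrences scrubbed from the overlap,
size 6–28 kb so the rescue window covers it), and tiny (label-free,
≤ 200 bp). Contained contigs are exact subsequences of large hosts; for
those expected to be re-inserted, the host's alignment drops its interior
pairs in the contained region (emulating a poorly resolved host region),
leaving the outermost two as the shared boundary labels.

Label-position noise is multiplicative on the *intervals* between adjacent
anchor labels (sd 0.3% by default), because optical sizing error grows
with distance; applying independent multiplicative noise to absolute
positions would instead grow with chromosome coordinate and make gap
estimates meaningless. Contig maps are derived by projecting genome label
points into contig coordinates — equivalent to digesting the contig, but
with a single orientation-independent point per site, which is what makes
zero-noise reconstruction exactly testable.

What the simulator does **not** model: real genome sequence composition
(repeats, segmental duplications — the main cause of spurious alignment in
real data), molecule-level map assembly, fragile sites, chimeric joins,
and label false positives/negatives are off by default (rates are
configurable). Passing tests therefore demonstrate the correctness of the
junction arithmetic and bookkeeping under the stated evidence model, not
robustness to real-world map-assembly artefacts.

## Problem sizes

The default test and acceptance runs use 5–10 Mb genomes with 16–50
junctions — roughly a 1/20 to 1/50-scale version of a chromosome-scale
experiment. The quantitative acceptance target (mean scaled absolute
gap-size error over 50 noisy gap junctions) is insensitive to genome scale
because the error is driven by label density and interval noise, both of
which are scale-free here.

## Known limitations

* Junction decisions are strictly pairwise and left-to-right along the
  anchor; a fusion never reconsiders an earlier junction.
* Overlaps larger than the rescue window (30 kb) without shared labels
  cannot be fused; the window is kept at its default regardless of how
  negative the gap estimate is.
* The seed-and-extend path can under-score heavily gapped similarities
  (many small indels closer than a seed length apart); for junction rescue
  on near-identical overlaps this is immaterial.
* AGP output always uses gap type `scaffold`, linkage `yes`, evidence
  `map`; finer evidence vocabularies are not emitted.
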