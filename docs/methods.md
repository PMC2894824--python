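# Methods

This note records the models, parameter choices and numerical decisions
behind `amplicirc`, including the points where the method description
left the design genuinely open.

## Reference panel

A panel holds one 16S rRNA gene per species. When the input FASTA holds
several genes for a species, `select_one_per_species` draws one
reproducibly: species are visited in lexicographic order, candidates
sorted by id, and a single `random.Random(seed)` stream drives the picks,
so the choice depends only on the record set and the seed, never on file
order.

**Kimura two-parameter distances.** For an aligned pair, columns where
either sequence carries a gap or an ambiguous base are dropped (pairwise
deletion — the default of the classic distance programs). Over the
remaining columns with transition proportion P and transversion
proportion Q,

    d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q).

Two degenerate situations are errors, not values: a pair with no
comparable columns, and a saturated pair (either log argument ≤ 0). A
16S pair saturated under K2P is a data problem — emitting infinity would
silently poison the tree — so the error names the offending pair.

**Neighbor joining.** Standard Saitou–Nei agglomeration, exact on
additive matrices. Two under-specified corners are pinned down for
determinism: when several pairs tie on the Q-criterion the pair whose
(smallest-member-id, largest-member-id) is lexicographically least wins
(clusters are named by the smallest leaf id they contain), and negative
branch lengths are clamped to zero without redistributing the deficit —
the resulting tree then over-estimates some path distances slightly
rather than containing physically meaningless negative branches. The
output is an unrooted DendroPy tree with a trifurcation at the final
join.

**Circular leaf order.** The method's plots place species around a
circle "in phylogenetic order", which a tree does not define uniquely.
The fixed rule: depth-first traversal from the leaf with the
lexicographically smallest id, visiting the neighbors of every node in
ascending (subtree leaf count, smallest contained leaf id). The rule
reads only leaf labels and subtree sizes, so it is invariant under
re-serialization (cherry swaps, rotation) of the same topology.

**Palette.** Phyla sorted lexicographically receive colors from a fixed
20-color categorical list, cycling if there are more phyla than colors.

## Assignment

HSPs come from 12-column BLAST tabular files. The pipeline:

1. drops exact duplicate rows (safe re-run concatenation);
2. drops HSPs shorter than `min_hsp_len` (default 50 bp);
3. groups the rest by (query, subject) and sorts each group by
   coordinates so that input row order can never change a result, down
   to floating-point summation order;
4. marks each group consistent or not;
5. among consistent groups of a query, adopts the subject with the
   largest total score (sum of member bit scores), breaking ties toward
   the lexicographically smallest subject id;
6. reports queries with no surviving consistent group as unassigned — a
   value, not an error.

**Consistency rule.** All member HSPs must lie on one strand; sorted by
query start, query starts must strictly increase and the subject
intervals must advance strictly in the strand's direction. Consecutive
intervals may overlap by at most 10 bp on either axis: real BLAST
fragments often share a few terminal bases around a variable region, and
the tolerance absorbs that without admitting genuinely re-ordered
alignments. Mixed-strand groups are inconsistent outright — a genuine
16S read matches a reference in a single orientation.

**Average similarity** is the alignment-length-weighted mean of member
percent identities. An unweighted mean would let short variable-region
fragments count as much as long conserved-region ones; weighting by
aligned length makes the statistic an estimate of whole-read identity.
Assignments below 80% similarity are still reported; the plot layer
decides how to display them.

## Profiles and indices

A cluster key is (reference id, ⌊average similarity⌋). The floor is
deliberate — 98.99% belongs to the 98 cluster — and relative abundances
are computed over assigned reads only, since unassigned reads carry no
key. Jaccard and Lennon are incidence-based on cluster counts
(S_A, S_B, S_AB); theta is abundance-based over the union of keys with
zeros for absent clusters, making it invariant to scaling either
sample's read counts. These are the standard definitions of the three
indices; the comparison is defined for exactly two samples.

## Plot geometry

The arc between circularly adjacent species (including the closing arc
from the last species back to the first) is proportional to their
pairwise K2P matrix distance — matrix distance, not tree path distance,
is the fixed choice. Zero adjacent distances receive a fixed minimum arc
of 0.1° and the remaining angular budget is split proportionally among
the nonzero distances, so arcs always sum to 360°. Radius maps [80, 100]
% similarity linearly onto [r_inner, r_outer] (defaults 110 px and
310 px on an 820 px canvas); similarities below 80% clamp to the inner
ring and set a flag that renders a legend marker rather than dropping
the cluster. Dots are drawn per cluster at similarity
`sim_floor + 0.5` (the center of the 1% band) with four size categories:
< 1%, < 5%, < 10% and ≥ 10% relative abundance; exactly 10% falls in the
largest category. Species labels are italic, radially oriented, colored
by phylum. Output is SVG 1.1 written by a deterministic string-template
emitter with fixed 3-decimal coordinate formatting, so identical inputs
produce byte-identical files — the property the rendering tests rely on,
and the reason a text-based vector dialect was chosen at all.

## Synthetic data

The generator exists to give every pipeline stage a ground truth.

- **References** evolve from one random ancestor under a two-rate
  substitution model (transition:transversion rate ratio
  `transition_bias`, default 2.0) with no indels, so reference sets are
  natively aligned and K2P is the matching distance. The default
  `tree_shape="star"` mutates each reference independently along a
  branch of `ref_divergence / 2` expected substitutions per site, making
  every pair's expected divergence exactly `ref_divergence` (default
  0.15 — comfortably above the ~3% read divergence, like real
  genus-level 16S spread); `tree_shape="coalescent"` draws a random join
  topology rescaled so the *mean* pairwise path hits the target, for
  layouts with real clade structure.
- **Reads** (default 2000 per sample, 250 bp — a typical pyrosequencing
  amplicon read length) are contiguous substrings of their source,
  mutated at `read_divergence` (default 0.03); a truth table records
  source, offset and realized identity.
- **BLAST output** is fabricated, not aligned: because references share
  coordinates, the true window of any read on any reference is known,
  and pairs whose window identity reaches `emit_similarity_floor`
  (default 70%) are emitted as `n_hsp_fragments` colinear HSPs (default
  3, mimicking variable-region splitting) with identities computed from
  the actual sequences and scores from a fixed affine model
  (match +1, mismatch −2, floor 1) — only the ordering of totals matters
  downstream. With probability `false_alignment_rate` a multi-fragment
  pair has its subject intervals shuffled out of order, reproducing the
  structure the consistency check is built to reject.

What this emulates — fragment splitting, near-tie competition between
related references, false-alignment structure, strand conventions — is
the part of the problem the assignment logic actually sees. What it does
not emulate: indels and alignment gaps, chimeras, homopolymer error
models, primer bias, and real BLAST score statistics. Passing tests
therefore demonstrate the correctness of the aggregation, filtering and
comparison logic under the stated noise model, not robustness to every
sequencing artifact.

## Problem sizes

The test suite and acceptance checks run at desk scale by design: panels
of 8 synthetic references (1500 bp), 200–2000 reads per sample, 100
random additive matrices of 4–8 taxa for the NJ oracle, and 1000-case
fuzzing sweeps for K2P symmetry and the consistency check. These sizes
exercise every code path while keeping a full run under a minute or two
on one core; nothing in the implementation is specific to them, and the
panel builder is O(n²) in panel size only through the distance matrix.

## Known limitations

- The comparison layer handles exactly two samples; multi-sample
  statistics, rarefaction and diversity estimation are out of scope.
- No internal aligner: inputs are either BLAST tabular files or, through
  the CLI only, FASTA handed to an externally configured `blastn`.
- Cluster-level (not per-read) dots are rendered, so a plot scales with
  distinct clusters rather than reads; per-read rendering of
  multi-million-read samples is not attempted.
- Saturated reference pairs abort panel construction by design; panels
  mixing extremely divergent domains may need pre-screening.
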