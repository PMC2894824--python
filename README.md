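# amplicirc

Nearest-relative taxonomic profiling of 16S rRNA amplicon reads, with
phylogenetically ordered circular composition plots and between-sample
similarity indices.

## The problem and the method

Amplicon surveys of microbial communities produce large numbers of partial
16S rRNA gene reads. Assigning each read to the most closely related
*genome-sequenced* species anchors the community profile to organisms with
known biology. The catch is that the 16S gene alternates conserved and
variable regions, so a BLAST search of a read against a reference gene is
routinely split into several local alignments (HSPs) — the single
best-scoring HSP is a poor measure of overall affinity.

`amplicirc` implements the total-score approach:

- **Total BLAST score.** For each (read, reference) pair, the bit scores
  of all retained HSPs are summed (e.g. three fragments scoring
  250 + 220 + 300 give a total of 770). The reference with the highest
  total is the read's *nearest relative*.
- **Length filter.** HSPs shorter than 50 bp are discarded as unreliable.
- **Consistency check.** A genuine split alignment is colinear: sorted by
  read coordinate, the matched reference intervals advance strictly in
  the same direction (one strand, no overlaps beyond a 10 bp tolerance).
  Pairs violating this are false alignments between unrelated regions and
  are excluded before totals are compared.
- **Average similarity.** The alignment-length-weighted mean percent
  identity over the winning pair's HSPs; it places the read radially on
  the plot.
- **Clustering and comparison.** Reads sharing a reference and the floor
  of their average similarity (98.8% and 98.1% → the "98 cluster") form
  one cluster. Two samples are compared through their shared cluster keys
  with the Jaccard index `S_AB / (S_A + S_B − S_AB)`, the Lennon index
  `S_AB / (S_AB + min(S_A−S_AB, S_B−S_AB))`, and the abundance-weighted
  Yue–Clayton theta `Σaᵢbᵢ / (Σaᵢ² + Σbᵢ² − Σaᵢbᵢ)`.
- **Circular plot.** Reference species sit on a circle ordered by a
  neighbor-joining tree of Kimura two-parameter distances, adjacent arcs
  proportional to pairwise distance; five rings mark 80–100% similarity;
  each cluster is a dot sized by one of four relative-abundance bins.
  A merged two-sample plot colors clusters gray (common), green (sample A
  only) or orange (sample B only).

The package also ships a fully deterministic synthetic-data generator
(reference panels, mutated reads, fragmented BLAST tabular output with
optional injected false alignments) so every stage can be tested against
a known truth table.

## Worked example

```sh
python examples/01_simulate_and_assign.py
```

prints

```
reads assigned:        500 / 500 (0 unassigned)
correct nearest ref:   100.0%
mean avg similarity:   97.01%  (truth: 97.01%)
```

500 reads simulated at 3% divergence from 8 references (~15% divergent
from each other) all map back to their true source, and the recovered
average similarity matches the realized read identity. Comparing an even
sample against a skewed one (`examples/02_compare_samples.py`):

```
common clusters:  15 (S_A=44, S_B=18)
Jaccard index:    0.3191
Lennon index:     0.8333
Yue-Clayton theta 0.3028
```

Lennon is high because most of the skewed sample's clusters also occur in
the even sample; theta is low because the abundances disagree.
`examples/03_circular_plot.py` renders the single-sample and merged SVG
plots into `scratch/plots/`.

## Command line

The same pipeline is available as a CLI:

```sh
amplicirc simulate -o sim --seed 3
amplicirc build-panel sim/references.aligned.fasta sim/taxonomy.tsv -o panel
amplicirc assign sim/blast.tsv -p panel -o assignments.tsv
amplicirc profile assignments.tsv -o profile.tsv --name gut
amplicirc compare profile_a.tsv profile_b.tsv -o report.tsv \
    -p panel --merged-svg merged.svg
amplicirc plot profile.tsv -p panel -o plot.svg
```

All randomness flows from explicit `--seed` options; reruns are
byte-identical.

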