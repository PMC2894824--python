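"""Assign simulated 16S reads to their nearest genome-sequenced relative.

Builds a synthetic experiment — 8 divergent reference 16S genes and 500
reads drawn from them at 3% divergence — runs the total-score assignment
with the consistency check, and scores the result against the simulation
truth table.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np

from amplicirc import (
    SimulationSpec,
    assign_sample,
    build_reference_panel,
)
from amplicirc.synth import run_simulation

with TemporaryDirectory() as tmp:
    spec = SimulationSpec(n_refs=8, n_reads=500, read_divergence=0.03,
                          seed=42)
    paths = run_simulation(spec, Path(tmp))
    panel = build_reference_panel(paths["reference_fasta"],
                                  paths["taxonomy_tsv"], seed=1)
    assignments, unassigned = assign_sample(paths["blast_tsv"],
                                            panel=panel)

    truth = {r.id: r for r in paths["reads"]}
    correct = sum(a.nearest_ref_id == truth[a.query_id].source_id
                  for a in assignments)
    mean_sim = np.mean([a.avg_similarity for a in assignments])
    mean_true = np.mean([r.identity for r in paths["reads"]])

print(f"reads assigned:        {len(assignments)} / {spec.n_reads} "
      f"({len(unassigned)} unassigned)")
print(f"correct nearest ref:   {correct / len(assignments):.1%}")
print(f"mean avg similarity:   {mean_sim:.2f}%  "
      f"(truth: {mean_true:.2f}%)")
print()
print("Every read should recover its source reference because the")
print("references are ~15% divergent while reads sit only ~3% from")
print("their source; the recovered average similarity is the length-")
print("weighted identity over each read's retained HSPs.")
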