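"""Synthetic data generation for pipeline testing.

Everything the pipeline consumes can be fabricated here with full
determinism from a single seed: a panel of divergent 16S-like reference
sequences, reads sampled from chosen references with controlled
divergence, and a 12-column BLAST tabular file whose HSP structure mimics
the conserved/variable-region alignment splitting of real 16S searches —
including, on demand, order-inconsistent ("false") HSP sets of the kind
the consistency check exists to reject.

Sequences evolve under a two-rate (transition/transversion) substitution
model with no indels, matching the K2P assumptions, so reference sets are
natively aligned and distance recovery is self-consistent. A truth table
accompanies every read set, enabling exact accuracy and similarity-error
measurements for any downstream run.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from amplicirc.refdb import ReferenceRecord

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_PHYLA = ("Actinobacteria", "Bacteroidetes", "Firmicutes",
          "Proteobacteria")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic experiment.

    ``ref_divergence`` and ``read_divergence`` are expected substitutions
    per site; ``transition_bias`` is the per-event rate ratio of
    transitions to each transversion class. ``tree_shape`` selects how the
    references relate: "star" evolves each reference independently from a
    common ancestor so every pair's expected divergence equals
    ``ref_divergence`` exactly; "coalescent" draws a random join topology
    rescaled so the *mean* pairwise path equals ``ref_divergence``.
    """

    n_refs: int = 8
    seq_len: int = 1500
    ref_divergence: float = 0.15
    composition: dict[str, float] | None = None
    n_reads: int = 2000
    read_divergence: float = 0.03
    transition_bias: float = 2.0
    n_hsp_fragments: int = 3
    false_alignment_rate: float = 0.0
    seed: int = 0
    read_len: int = 250
    emit_similarity_floor: float = 70.0
    tree_shape: str = "star"

    def __post_init__(self):
        if self.n_refs < 2:
            raise ValueError("n_refs must be >= 2")
        for name in ("ref_divergence", "read_divergence",
                     "false_alignment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.composition is not None:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"composition sums to {total}, must be 1")
        if self.read_len > self.seq_len:
            raise ValueError("read_len exceeds seq_len")
        if self.tree_shape not in ("star", "coalescent"):
            raise ValueError("tree_shape must be 'star' or 'coalescent'")


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    source_id: str
    start: int  # 0-based offset into the source reference
    seq: str
    identity: float  # realized percent identity vs the source substring


def _mutate(seq: str, t: float, bias: float, rng: random.Random) -> str:
    """Apply substitutions at expected rate ``t`` per site.

    Each site mutates independently with probability ``t``; a mutating
    site takes its transition partner with probability bias/(bias+2) and
    each transversion partner with probability 1/(bias+2).
    """
    if t <= 0.0:
        return seq
    p_ts = bias / (bias + 2.0)
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < t:
            if rng.random() < p_ts:
                out[i] = _TRANSITION[base]
            else:
                out[i] = _TRANSVERSIONS[base][rng.randrange(2)]
    return "".join(out)


def _evolve_star(ancestor: str, spec: SimulationSpec,
                 rng: random.Random) -> list[str]:
    half = spec.ref_divergence / 2.0
    return [_mutate(ancestor, half, spec.transition_bias, rng)
            for _ in range(spec.n_refs)]


def _evolve_coalescent(ancestor: str, spec: SimulationSpec,
                       rng: random.Random) -> list[str]:
    # random join topology; branch lengths in arbitrary units, rescaled
    # so the mean leaf-to-leaf path equals ref_divergence
    nodes: list = [("leaf", i) for i in range(spec.n_refs)]
    while len(nodes) > 1:
        j = rng.randrange(len(nodes))
        left = nodes.pop(j)
        k = rng.randrange(len(nodes))
        right = nodes.pop(k)
        bl, br = rng.uniform(0.5, 1.5), rng.uniform(0.5, 1.5)
        nodes.append(("node", (left, bl), (right, br)))
    root = nodes[0]

    def depths(node) -> dict[int, float]:
        if node[0] == "leaf":
            return {node[1]: 0.0}
        out = {}
        for child, bl in node[1:]:
            for leaf, d in depths(child).items():
                out[leaf] = d + bl
        return out

    def pair_paths(node) -> list[float]:
        if node[0] == "leaf":
            return []
        (left, bl), (right, br) = node[1], node[2]
        paths = pair_paths(left) + pair_paths(right)
        dl, dr = depths(left), depths(right)
        paths.extend(a + bl + b + br
                     for a in dl.values() for b in dr.values())
        return paths

    paths = pair_paths(root)
    scale = spec.ref_divergence / (sum(paths) / len(paths))
    seqs: dict[int, str] = {}

    def evolve(node, seq):
        if node[0] == "leaf":
            seqs[node[1]] = seq
            return
        for child, bl in node[1:]:
            evolve(child, _mutate(seq, bl * scale,
                                  spec.transition_bias, rng))

    evolve(root, ancestor)
    return [seqs[i] for i in range(spec.n_refs)]


def make_reference_records(spec: SimulationSpec) -> list[ReferenceRecord]:
    """In-memory reference panel records (aligned == raw; no indels)."""
    rng = random.Random(spec.seed)
    ancestor = "".join(rng.choice(_BASES) for _ in range(spec.seq_len))
    if spec.tree_shape == "star":
        seqs = _evolve_star(ancestor, spec, rng)
    else:
        seqs = _evolve_coalescent(ancestor, spec, rng)
    return [
        ReferenceRecord(
            id=f"REF{i + 1:03d}",
            species=f"Synthspecies ref{i + 1:03d}",
            phylum=_PHYLA[i % len(_PHYLA)],
            aligned_seq=seq,
        )
        for i, seq in enumerate(seqs)
    ]


def generate_reference_set(spec: SimulationSpec, out_dir: str | Path
                           ) -> tuple[Path, Path, list[ReferenceRecord]]:
    """Write an aligned multi-FASTA and taxonomy TSV for a synthetic panel."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = make_reference_records(spec)
    fasta = out_dir / "references.aligned.fasta"
    with open(fasta, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.aligned_seq}\n")
    tsv = out_dir / "taxonomy.tsv"
    with open(tsv, "w") as fh:
        fh.write("id\tspecies\tphylum\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.species}\t{rec.phylum}\n")
    return fasta, tsv, records


def _allocate_counts(spec: SimulationSpec,
                     ref_ids: list[str]) -> dict[str, int]:
    comp = spec.composition or {rid: 1.0 / len(ref_ids)
                                for rid in ref_ids}
    unknown = set(comp) - set(ref_ids)
    if unknown:
        raise ValueError(
            f"composition names unknown references: {sorted(unknown)}")
    # largest-remainder apportionment for exact totals
    raw = {rid: frac * spec.n_reads for rid, frac in comp.items()}
    counts = {rid: int(v) for rid, v in raw.items()}
    short = spec.n_reads - sum(counts.values())
    for rid, _ in sorted(raw.items(),
                         key=lambda kv: (kv[1] - int(kv[1]), kv[0]),
                         reverse=True)[:short]:
        counts[rid] += 1
    return counts


def generate_reads(spec: SimulationSpec,
                   references: list[ReferenceRecord]
                   ) -> list[SimulatedRead]:
    """Sample mutated contiguous subreads from the references.

    Read counts per reference follow ``spec.composition`` (uniform when
    absent) with largest-remainder rounding; each read is a contiguous
    ``read_len`` substring of its source mutated at ``read_divergence``.
    """
    rng = random.Random(spec.seed + 1)
    by_id = {r.id: r for r in references}
    counts = _allocate_counts(spec, [r.id for r in references])
    reads = []
    idx = 0
    for rid in sorted(counts):
        source = by_id[rid].raw_seq
        for _ in range(counts[rid]):
            idx += 1
            start = rng.randrange(0, len(source) - spec.read_len + 1)
            template = source[start:start + spec.read_len]
            mutated = _mutate(template, spec.read_divergence,
                              spec.transition_bias, rng)
            matches = sum(a == b for a, b in zip(template, mutated))
            reads.append(SimulatedRead(
                id=f"READ{idx:06d}", source_id=rid, start=start,
                seq=mutated,
                identity=100.0 * matches / spec.read_len))
    return reads


def write_reads(reads: list[SimulatedRead], out_dir: str | Path
                ) -> tuple[Path, Path]:
    """Write reads FASTA and truth TSV (source, offset, identity)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "reads.fasta"
    with open(fasta, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.seq}\n")
    truth = out_dir / "truth.tsv"
    with open(truth, "w") as fh:
        fh.write("read_id\tsource_id\tstart\tidentity\n")
        for r in reads:
            fh.write(f"{r.id}\t{r.source_id}\t{r.start}\t"
                     f"{r.identity:.4f}\n")
    return fasta, truth


def _fragment_bounds(length: int, k: int,
                     rng: random.Random) -> list[tuple[int, int]]:
    """Split [1, length] into k contiguous 1-based fragments with jitter."""
    k = max(1, min(k, length // 60))  # keep fragments comfortably > 50 bp
    cuts = [0]
    for i in range(1, k):
        base = round(i * length / k)
        cuts.append(base + rng.randint(-5, 5))
    cuts.append(length)
    return [(cuts[i] + 1, cuts[i + 1]) for i in range(k)]


def simulate_blast_tabular(reads: list[SimulatedRead],
                           references: list[ReferenceRecord],
                           spec: SimulationSpec,
                           out_path: str | Path) -> Path:
    """Fabricate fragmented 12-column BLAST tabular output.

    For every read x reference pair whose ungapped identity over the
    read's source window reaches ``emit_similarity_floor``, the read is
    split into ``n_hsp_fragments`` colinear HSPs. Fragment scores follow a
    fixed affine model (match +1, mismatch -2; only the ordering of totals
    matters downstream). With probability ``false_alignment_rate`` a
    multi-fragment pair has its subject intervals shuffled out of order,
    reproducing the structure of a false alignment.
    """
    rng = random.Random(spec.seed + 2)
    out_path = Path(out_path)
    rows = []
    for read in reads:
        for ref in references:
            window = ref.raw_seq[read.start:read.start + spec.read_len]
            if len(window) < spec.read_len:
                continue
            matches = [a == b for a, b in zip(read.seq, window)]
            identity = 100.0 * sum(matches) / spec.read_len
            if identity < spec.emit_similarity_floor:
                continue
            bounds = _fragment_bounds(spec.read_len,
                                      spec.n_hsp_fragments, rng)
            s_intervals = [(read.start + q1, read.start + q2)
                           for q1, q2 in bounds]
            if (len(bounds) > 1
                    and rng.random() < spec.false_alignment_rate):
                while True:
                    rng.shuffle(s_intervals)
                    if s_intervals != sorted(s_intervals):
                        break
            for (q1, q2), (s1, s2) in zip(bounds, s_intervals):
                frag_len = q2 - q1 + 1
                n_match = sum(matches[q1 - 1:q2])
                n_mm = frag_len - n_match
                pident = 100.0 * n_match / frag_len
                score = max(1.0, n_match - 2.0 * n_mm)
                rows.append(
                    f"{read.id}\t{ref.id}\t{pident:.2f}\t{frag_len}\t"
                    f"{n_mm}\t0\t{q1}\t{q2}\t{s1}\t{s2}\t"
                    f"1e-50\t{score:.1f}")
    with open(out_path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))
    return out_path


def run_simulation(spec: SimulationSpec, out_dir: str | Path) -> dict:
    """End-to-end fixture: panel inputs, reads, truth and BLAST tabular."""
    out_dir = Path(out_dir)
    fasta, tax, records = generate_reference_set(spec, out_dir)
    reads = generate_reads(spec, records)
    reads_fasta, truth = write_reads(reads, out_dir)
    blast = simulate_blast_tabular(reads, records, spec,
                                   out_dir / "blast.tsv")
    return {
        "reference_fasta": fasta,
        "taxonomy_tsv": tax,
        "reads_fasta": reads_fasta,
        "truth_tsv": truth,
        "blast_tsv": blast,
        "records": records,
        "reads": reads,
    }
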