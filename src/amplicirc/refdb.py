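"""Reference panel construction.

A reference panel is the fixed backdrop of the profiler: one 16S rRNA gene
per genome-sequenced species, the matrix of Kimura two-parameter (K2P)
distances between the aligned genes, a neighbor-joining tree over those
distances, a deterministic circular ordering of the leaves for plotting,
and a categorical color per phylum.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

GAP_CHARS = frozenset("-.")
_ACGT = frozenset("ACGT")
_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))

#: fixed categorical palette (tab20-style hex values), assigned to phyla in
#: lexicographic order so colors are reproducible across runs
PHYLUM_COLORS = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
)


class DistanceError(ValueError):
    """Raised when a K2P distance is undefined for a pair of sequences."""


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference 16S gene with its taxonomy.

    ``raw_seq`` is ``aligned_seq`` with gap characters removed; the aligned
    form is used for distances, the raw form is what reads align against.
    """

    id: str
    species: str
    phylum: str
    aligned_seq: str

    @property
    def raw_seq(self) -> str:
        return "".join(c for c in self.aligned_seq if c not in GAP_CHARS)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self):
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


@dataclass
class ReferencePanel:
    records: list[ReferenceRecord]
    distances: DistanceMatrix
    tree: dendropy.Tree
    leaf_order: list[str]
    phylum_palette: dict[str, str]
    seed: int | None = None
    _by_id: dict[str, ReferenceRecord] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_id = {r.id: r for r in self.records}

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def record(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def save(self, directory: str | Path) -> Path:
        """Write the panel to a directory of plain-text files.

        Contents: ungapped FASTA, taxonomy TSV, lower-triangle distance
        matrix TSV, Newick tree, leaf-order list and a JSON manifest.
        Byte-identical for identical panels.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "references.fasta", "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n{rec.raw_seq}\n")
        with open(directory / "aligned.fasta", "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n{rec.aligned_seq}\n")
        with open(directory / "taxonomy.tsv", "w") as fh:
            fh.write("id\tspecies\tphylum\n")
            for rec in self.records:
                fh.write(f"{rec.id}\t{rec.species}\t{rec.phylum}\n")
        with open(directory / "distances.tsv", "w") as fh:
            ids = self.distances.ids
            for i, rid in enumerate(ids):
                row = "\t".join(repr(float(self.distances.d[i, j]))
                                for j in range(i))
                fh.write(rid + ("\t" + row if row else "") + "\n")
        with open(directory / "tree.nwk", "w") as fh:
            fh.write(self.tree.as_string(schema="newick",
                                         suppress_rooting=True))
        with open(directory / "leaf_order.txt", "w") as fh:
            fh.write("\n".join(self.leaf_order) + "\n")
        manifest = {
            "format": "amplicirc-panel-v1",
            "seed": self.seed,
            "n_records": len(self.records),
            "ids": self.ids,
            "leaf_order": self.leaf_order,
            "phylum_palette": self.phylum_palette,
            "files": {
                "references": "references.fasta",
                "aligned": "aligned.fasta",
                "taxonomy": "taxonomy.tsv",
                "distances": "distances.tsv",
                "tree": "tree.nwk",
                "leaf_order": "leaf_order.txt",
            },
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return directory


def select_one_per_species(records: list[ReferenceRecord],
                           seed: int) -> list[ReferenceRecord]:
    """Keep exactly one record per species, chosen reproducibly from seed.

    Species are processed in lexicographic order and candidates sorted by
    id, so the draw depends only on the record set and the seed, not on
    input order.
    """
    if not records:
        raise ValueError("no records to select from")
    by_species: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    rng = random.Random(seed)
    chosen = []
    for species in sorted(by_species):
        group = sorted(by_species[species], key=lambda r: r.id)
        chosen.append(group[rng.randrange(len(group))])
    chosen.sort(key=lambda r: r.id)
    return chosen


def _is_transition(x: str, y: str) -> bool:
    return frozenset((x, y)) in _TRANSITION_PAIRS


def kimura2p_distance(a: str, b: str) -> float:
    """K2P distance between two aligned sequences.

    Columns where either sequence has a gap or an ambiguous base are
    dropped (pairwise deletion). With P and Q the transition and
    transversion proportions over the compared columns,

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    Raises :class:`DistanceError` if no columns are comparable or the pair
    is saturated (a log argument is non-positive): a saturated 16S pair
    indicates bad input rather than a finite distance.
    """
    if len(a) != len(b):
        raise ValueError(
            f"aligned lengths differ: {len(a)} vs {len(b)}")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _ACGT and y in _ACGT:
            n += 1
            if x != y:
                if _is_transition(x, y):
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        raise DistanceError("no comparable (both-ACGT) columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise DistanceError(
            f"saturated pair (P={P:.4f}, Q={Q:.4f}); K2P undefined")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def distance_matrix(records: list[ReferenceRecord]) -> DistanceMatrix:
    """All pairwise K2P distances over the panel's aligned sequences."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    length = len(records[0].aligned_seq)
    for rec in records:
        if len(rec.aligned_seq) != length:
            raise ValueError(
                f"record {rec.id} has aligned length "
                f"{len(rec.aligned_seq)}, expected {length}")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = kimura2p_distance(records[i].aligned_seq,
                                        records[j].aligned_seq)
            except DistanceError as exc:
                raise DistanceError(
                    f"pair ({records[i].id}, {records[j].id}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=tuple(r.id for r in records), d=d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Ties on the Q-criterion are broken toward the pair whose
    (smallest-member-id, largest-member-id) is lexicographically least,
    where a cluster is named by the smallest leaf id it contains. Negative
    branch lengths are clamped to zero without redistributing the deficit.
    Returns an unrooted tree (trifurcation at the seed node).
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # active clusters: key -> newick subtree string; key = smallest leaf id
    sub = {rid: _quote(rid) for rid in dm.ids}
    dist: dict[frozenset, float] = {}
    ids = list(dm.ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[frozenset((ids[i], ids[j]))] = float(dm.d[i, j])
    active = sorted(ids)

    def d(a, b):
        return dist[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * d(a, b) - r[a] - r[b]
                if q < best_q:  # active is sorted: first hit wins ties
                    best_q, best = q, (a, b)
        a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d(a, b) - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = min(a, b)
        new_sub = f"({sub[a]}:{la!r},{sub[b]}:{lb!r})"
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = sorted(set(active) - {a, b} | {new})
        sub[new] = new_sub
        # note: when new == a, dist entries keyed by a were overwritten above

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({sub[a]}:{la!r},{sub[b]}:{lb!r},{sub[c]}:{lc!r});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def leaf_order(tree: dendropy.Tree) -> list[str]:
    """Deterministic circular leaf ordering for plot layout.

    The tree is traversed depth-first from the leaf with the
    lexicographically smallest id; at every node the unvisited neighbors
    are taken in ascending (subtree leaf-count, smallest contained leaf id)
    order. The rule depends only on leaf labels, so the output is invariant
    under re-serialization of the same tree.
    """
    adj: dict[object, list] = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            adj[node].append(child)
            adj.setdefault(child, []).append(node)
    leaves = {node: node.taxon.label for node in adj
              if node.taxon is not None and not node.child_nodes()}
    # a leaf used as seed node has children but a taxon; treat any node
    # with a taxon label as a leaf for ordering purposes
    for node in adj:
        if node.taxon is not None:
            leaves[node] = node.taxon.label
    root = min(leaves, key=lambda n: leaves[n])

    # subtree summaries (leaf count, min label) away from the root
    count: dict[tuple, tuple[int, str]] = {}

    def summary(node, parent):
        key = (id(node), id(parent))
        if key in count:
            return count[key]
        cnt, lo = (1, leaves[node]) if node in leaves else (0, "￿")
        for nb in adj[node]:
            if nb is parent:
                continue
            c, m = summary(nb, node)
            cnt += c
            lo = min(lo, m)
        count[key] = (cnt, lo)
        return count[key]

    order: list[str] = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        if node in leaves:
            order.append(leaves[node])
        nxt = [nb for nb in adj[node] if nb is not parent]
        nxt.sort(key=lambda nb: summary(nb, node), reverse=True)
        stack.extend((nb, node) for nb in nxt)
    return order


def _palette_for(phyla) -> dict[str, str]:
    names = sorted(set(phyla))
    return {p: PHYLUM_COLORS[i % len(PHYLUM_COLORS)]
            for i, p in enumerate(names)}


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["id", "species", "phylum"]
    if list(tax.columns[:3]) != expected:
        raise ValueError(
            f"taxonomy header must be {expected}, got {list(tax.columns)}")
    return tax


def build_reference_panel(aligned_fasta: str | Path,
                          taxonomy_tsv: str | Path,
                          seed: int = 0) -> ReferencePanel:
    """Assemble a panel from an aligned multi-FASTA and a taxonomy TSV.

    Picks one sequence per species (seeded), computes the K2P distance
    matrix, builds the NJ tree, derives the circular leaf order and assigns
    the phylum palette. Pure function of (inputs, seed).
    """
    tax = read_taxonomy(taxonomy_tsv)
    tax_by_id = {}
    for row in tax.itertuples(index=False):
        if row.id in tax_by_id:
            raise ValueError(f"duplicate id in taxonomy: {row.id}")
        tax_by_id[row.id] = (row.species, row.phylum)
    records = []
    seen = set()
    for seq in SeqIO.parse(str(aligned_fasta), "fasta"):
        if seq.id in seen:
            raise ValueError(f"duplicate id in FASTA: {seq.id}")
        seen.add(seq.id)
        if seq.id not in tax_by_id:
            raise ValueError(f"id missing from taxonomy: {seq.id}")
        species, phylum = tax_by_id[seq.id]
        records.append(ReferenceRecord(id=seq.id, species=species,
                                       phylum=phylum,
                                       aligned_seq=str(seq.seq)))
    records = select_one_per_species(records, seed)
    dm = distance_matrix(records)
    tree = neighbor_joining(dm)
    order = leaf_order(tree)
    palette = _palette_for(r.phylum for r in records)
    return ReferencePanel(records=records, distances=dm, tree=tree,
                          leaf_order=order, phylum_palette=palette,
                          seed=seed)


def load_panel(directory: str | Path) -> ReferencePanel:
    """Load a panel previously written by :meth:`ReferencePanel.save`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    tax = read_taxonomy(directory / files["taxonomy"])
    tax_by_id = {r.id: (r.species, r.phylum)
                 for r in tax.itertuples(index=False)}
    records = [
        ReferenceRecord(id=seq.id, species=tax_by_id[seq.id][0],
                        phylum=tax_by_id[seq.id][1],
                        aligned_seq=str(seq.seq))
        for seq in SeqIO.parse(str(directory / files["aligned"]), "fasta")
    ]
    ids = []
    rows = []
    with open(directory / files["distances"]) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    n = len(ids)
    d = np.zeros((n, n))
    for i, row in enumerate(rows):
        for j, val in enumerate(row):
            d[i, j] = d[j, i] = val
    tree = dendropy.Tree.get(path=str(directory / files["tree"]),
                             schema="newick", preserve_underscores=True)
    return ReferencePanel(
        records=records,
        distances=DistanceMatrix(ids=tuple(ids), d=d),
        tree=tree,
        leaf_order=manifest["leaf_order"],
        phylum_palette=manifest["phylum_palette"],
        seed=manifest.get("seed"),
    )
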