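import random

import pytest

from amplicirc.refdb import ReferenceRecord, build_reference_panel
from amplicirc.synth import SimulationSpec, run_simulation


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Small but complete synthetic experiment: 8 refs, 200 reads."""
    spec = SimulationSpec(n_refs=8, n_reads=200, seed=11)
    out = tmp_path_factory.mktemp("sim")
    paths = run_simulation(spec, out)
    paths["spec"] = spec
    return paths


@pytest.fixture(scope="session")
def small_panel(small_sim):
    return build_reference_panel(small_sim["reference_fasta"],
                                 small_sim["taxonomy_tsv"], seed=1)


def random_additive_case(n_leaves: int, rng: random.Random):
    """Random binary tree with positive branch lengths plus its exact
    leaf-to-leaf path-distance matrix and nontrivial splits.

    Serves as the independent oracle for neighbor joining: NJ run on the
    returned matrix must reproduce both the distances and the splits.
    """
    labels = [f"T{i:02d}" for i in range(n_leaves)]
    nodes = [("leaf", lab) for lab in labels]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(("node", (a, rng.uniform(0.1, 1.0)),
                      (b, rng.uniform(0.1, 1.0))))
    root = nodes[0]

    def depths(node):
        if node[0] == "leaf":
            return {node[1]: 0.0}
        out = {}
        for child, bl in node[1:]:
            for leaf, d in depths(child).items():
                out[leaf] = d + bl
        return out

    dist = {}
    splits = set()
    all_leaves = frozenset(labels)
    anchor = labels[0]

    def walk(node):
        if node[0] == "leaf":
            return {node[1]}
        below = set()
        for child, bl in node[1:]:
            sub = walk(child)
            below |= sub
        (left, bl), (right, br) = node[1], node[2]
        dl, dr = depths(left), depths(right)
        for la, da in dl.items():
            for lb, db in dr.items():
                dist[frozenset((la, lb))] = da + bl + db + br
        side = frozenset(below)
        if 2 <= len(side) <= n_leaves - 2:
            canon = side if anchor not in side else all_leaves - side
            splits.add(canon)
        return below

    walk(root)
    return labels, dist, splits


def tree_splits(tree, labels):
    """Nontrivial splits of a dendropy tree, canonicalized as in
    random_additive_case."""
    all_leaves = frozenset(labels)
    anchor = sorted(labels)[0]
    splits = set()
    for node in tree.preorder_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= len(labels) - 2:
            canon = (below if anchor not in below
                     else all_leaves - below)
            splits.add(canon)
    return splits


def make_records(seqs: dict[str, str], species=None, phylum="P"):
    return [
        ReferenceRecord(id=rid, species=(species or {}).get(rid, rid),
                        phylum=phylum, aligned_seq=seq)
        for rid, seq in seqs.items()
    ]
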