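import math
import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplicirc.refdb import (
    DistanceError,
    DistanceMatrix,
    build_reference_panel,
    distance_matrix,
    kimura2p_distance,
    leaf_order,
    neighbor_joining,
    select_one_per_species,
)
from conftest import make_records, random_additive_case, tree_splits

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestSelectOnePerSpecies:
    def test_one_record_kept_per_species_and_seeded(self):
        records = make_records(
            {"a1": "ACGT", "a2": "ACGA", "a3": "ACGC", "b1": "AAAA"},
            species={"a1": "S", "a2": "S", "a3": "S", "b1": "T"})
        first = select_one_per_species(records, seed=42)
        assert len(first) == 2
        assert {r.species for r in first} == {"S", "T"}
        assert select_one_per_species(records, seed=42) == first

    def test_selection_independent_of_input_order(self):
        records = make_records(
            {"a1": "ACGT", "a2": "ACGA", "a3": "ACGC"},
            species={"a1": "S", "a2": "S", "a3": "S"})
        shuffled = list(reversed(records))
        assert (select_one_per_species(records, seed=3)
                == select_one_per_species(shuffled, seed=3))

    def test_already_unique_is_identity(self):
        records = make_records({"a": "ACGT", "b": "AAAA"})
        assert set(select_one_per_species(records, 0)) == set(records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_one_per_species([], 0)


class TestKimura2P:
    def test_identical_sequences_have_zero_distance(self):
        assert kimura2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_p10_q05(self):
        # 100 columns, 10 transitions (A<->G), 5 transversions (A<->C)
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert kimura2p_distance(a, b) == pytest.approx(expected,
                                                        abs=1e-9)
        assert expected == pytest.approx(0.170182, abs=1e-6)

    def test_differences_only_in_gapped_columns_ignored(self):
        assert kimura2p_distance("AC-TA", "ACGTA") == 0.0
        assert kimura2p_distance("ACNTA", "ACGTA") == 0.0

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(DistanceError):
            kimura2p_distance("----", "ACGT")

    def test_saturation_is_error_not_infinity(self):
        with pytest.raises(DistanceError, match="saturat"):
            kimura2p_distance("A" * 10, "G" * 10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kimura2p_distance("ACG", "ACGT")

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_symmetry(self, data):
        a = data.draw(dna)
        b = data.draw(st.text(alphabet="ACGT", min_size=len(a),
                              max_size=len(a)))
        try:
            d_ab = kimura2p_distance(a, b)
        except DistanceError:
            with pytest.raises(DistanceError):
                kimura2p_distance(b, a)
            return
        assert d_ab == pytest.approx(kimura2p_distance(b, a), abs=0)
        assert d_ab >= 0.0


class TestDistanceMatrix:
    def test_identical_pair_gives_zero_matrix(self):
        dm = distance_matrix(make_records({"a": "ACGT", "b": "ACGT"}))
        assert np.array_equal(dm.d, np.zeros((2, 2)))

    def test_matches_per_pair_recomputation(self):
        records = make_records({"a": "ACGTACGTAC", "b": "ACGAACGTAC",
                                "c": "ACGTACTTAC"})
        dm = distance_matrix(records)
        for i, ri in enumerate(records):
            for j, rj in enumerate(records):
                if i == j:
                    continue
                assert dm.d[i, j] == pytest.approx(
                    kimura2p_distance(ri.aligned_seq, rj.aligned_seq))
        assert np.allclose(dm.d, dm.d.T)

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(make_records({"a": "ACGT"}))

    def test_error_names_offending_pair(self):
        records = make_records({"a": "A" * 10, "b": "G" * 10})
        with pytest.raises(DistanceError, match=r"\(a, b\)"):
            distance_matrix(records)


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda x, y: pdm.patristic_distance(taxa[x], taxa[y])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(ids=("A", "B", "C"),
                            d=np.array([[0.0, 3.0, 4.0],
                                        [3.0, 0.0, 5.0],
                                        [4.0, 5.0, 0.0]]))
        tree = neighbor_joining(dm)
        pd = _patristic(tree)
        assert pd("A", "B") == pytest.approx(3.0, abs=1e-12)
        assert pd("A", "C") == pytest.approx(4.0, abs=1e-12)
        assert pd("B", "C") == pytest.approx(5.0, abs=1e-12)

    def test_four_taxon_additive_matrix_recovered(self):
        ids = ("A", "B", "C", "D")
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids=ids, d=d))
        pd = _patristic(tree)
        for i, x in enumerate(ids):
            for y in ids[i + 1:]:
                assert pd(x, y) == pytest.approx(
                    d[ids.index(x), ids.index(y)], abs=1e-9)
        # the only nontrivial split is AB|CD (canonical side omits A)
        assert tree_splits(tree, ids) == {frozenset({"C", "D"})}

    def test_equidistant_matrix_paths_equal_constant(self):
        ids = tuple("ABCD")
        d = np.full((4, 4), 2.0) - 2.0 * np.eye(4)
        tree = neighbor_joining(DistanceMatrix(ids=ids, d=d))
        pd = _patristic(tree)
        for i, x in enumerate(ids):
            for y in ids[i + 1:]:
                assert pd(x, y) == pytest.approx(2.0, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(ids=("A", "B"),
                            d=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_random_additive_matrices_recovered_exactly(self):
        rng = random.Random(20240915)
        for trial in range(40):
            n = rng.randrange(4, 9)
            labels, dist, splits = random_additive_case(n, rng)
            d = np.zeros((n, n))
            for i, x in enumerate(labels):
                for j, y in enumerate(labels):
                    if i != j:
                        d[i, j] = dist[frozenset((x, y))]
            tree = neighbor_joining(
                DistanceMatrix(ids=tuple(labels), d=d))
            pd = _patristic(tree)
            for i, x in enumerate(labels):
                for y in labels[i + 1:]:
                    assert pd(x, y) == pytest.approx(
                        dist[frozenset((x, y))], abs=1e-9)
            assert tree_splits(tree, labels) == splits

    def test_agrees_with_scikit_bio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        rng = random.Random(5)
        labels, dist, splits = random_additive_case(6, rng)
        n = len(labels)
        d = np.zeros((n, n))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i != j:
                    d[i, j] = dist[frozenset((x, y))]
        import io

        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        buf = io.StringIO()
        sk_tree.write(buf, format="newick")
        sk_dendro = dendropy.Tree.get(data=buf.getvalue(),
                                      schema="newick")
        assert tree_splits(sk_dendro, labels) == splits
        ours = neighbor_joining(DistanceMatrix(ids=tuple(labels), d=d))
        assert tree_splits(ours, labels) == splits

    def test_negative_branch_lengths_clamped(self):
        # a slightly non-additive matrix that drives one branch negative
        ids = tuple("ABCD")
        d = np.array([[0.0, 0.1, 2.0, 2.0],
                      [0.1, 0.0, 2.0, 2.0],
                      [2.0, 2.0, 0.0, 0.1],
                      [2.0, 2.0, 0.1, 0.0]])
        tree = neighbor_joining(DistanceMatrix(ids=ids, d=d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0


class TestLeafOrder:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)

    def test_deterministic_on_rerun(self):
        t = self._tree("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        assert leaf_order(t) == leaf_order(t)

    def test_cherries_stay_adjacent_in_the_cycle(self):
        ids = ("A", "B", "C", "D")
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        order = leaf_order(neighbor_joining(DistanceMatrix(ids=ids, d=d)))
        pos = {x: i for i, x in enumerate(order)}
        n = len(order)

        def adjacent(x, y):
            return (pos[x] - pos[y]) % n in (1, n - 1)

        assert adjacent("A", "B")
        assert adjacent("C", "D")

    def test_invariant_under_cherry_swap_in_serialization(self):
        a = self._tree("((A:1,B:2):1,C:1,(D:1,E:1):1);")
        b = self._tree("((B:2,A:1):1,(E:1,D:1):1,C:1);")
        assert leaf_order(a) == leaf_order(b)


class TestBuildPanel:
    def test_panel_covers_all_species(self, small_sim, small_panel):
        assert len(small_panel.leaf_order) == 8
        assert sorted(small_panel.leaf_order) == small_panel.ids
        phyla = {r.phylum for r in small_panel.records}
        assert set(small_panel.phylum_palette) == phyla
        assert len(set(small_panel.phylum_palette.values())) == len(phyla)

    def test_rerun_same_seed_byte_identical_manifest(self, small_sim,
                                                     tmp_path):
        args = (small_sim["reference_fasta"], small_sim["taxonomy_tsv"])
        p1 = build_reference_panel(*args, seed=5)
        p2 = build_reference_panel(*args, seed=5)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        p1.save(d1)
        p2.save(d2)
        for name in ("manifest.json", "distances.tsv", "tree.nwk",
                     "leaf_order.txt"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_save_load_roundtrip(self, small_panel, tmp_path):
        from amplicirc.refdb import load_panel

        small_panel.save(tmp_path / "panel")
        loaded = load_panel(tmp_path / "panel")
        assert loaded.leaf_order == small_panel.leaf_order
        assert loaded.phylum_palette == small_panel.phylum_palette
        assert np.allclose(loaded.distances.d, small_panel.distances.d)
        assert [r.id for r in loaded.records] == small_panel.ids

    def test_missing_taxonomy_id_named_in_error(self, small_sim,
                                                tmp_path):
        import pandas as pd

        tax = pd.read_csv(small_sim["taxonomy_tsv"], sep="\t")
        tax = tax[tax["id"] != "REF003"]
        cut = tmp_path / "tax.tsv"
        tax.to_csv(cut, sep="\t", index=False)
        with pytest.raises(ValueError, match="REF003"):
            build_reference_panel(small_sim["reference_fasta"], cut,
                                  seed=0)
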