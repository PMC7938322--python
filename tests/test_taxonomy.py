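"""Taxonomy construction, depths, LCS and Wu-Palmer similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxorsa import (
    NodeLookupError,
    SchemeError,
    SizeError,
    TaxonomyFormatError,
    TaxonomyStructureError,
    TaxonomyTree,
    map_to_superordinates,
    parse_taxonomy,
    random_taxonomy,
    superordinates_at_level,
    taxonomy_similarity_matrix,
)

from conftest import random_tree, wu_palmer_oracle


class TestParsing:
    def test_minimal_edge_list(self):
        tree = parse_taxonomy("child\tparent\nB\tA\nC\tA\n", "edge_list", ["B", "C"])
        assert tree.root == "A"
        assert tree.leaf_set == ("B", "C")
        assert tree.depth_of("B") == 2

    def test_newick_matches_edge_list(self):
        from_newick = parse_taxonomy("((B,C)A)root;", "newick", ["B", "C"])
        from_edges = parse_taxonomy(
            "child\tparent\nA\troot\nB\tA\nC\tA\n", "edge_list", ["B", "C"]
        )
        assert dict(from_newick.parent_of) == dict(from_edges.parent_of)
        assert from_newick.root == from_edges.root

    def test_cycle_is_a_structure_error(self):
        with pytest.raises(TaxonomyStructureError):
            parse_taxonomy(
                "child\tparent\nB\tA\nA\tB\nC\tA\n", "edge_list", ["C"]
            )

    def test_missing_leaf_is_a_lookup_error(self):
        with pytest.raises(NodeLookupError):
            parse_taxonomy("child\tparent\nB\tA\n", "edge_list", ["Z"])

    def test_unlabeled_internal_newick_rejected(self):
        with pytest.raises(TaxonomyFormatError):
            parse_taxonomy("((B,C))root;", "newick", ["B", "C"])

    def test_bad_header_rejected(self):
        with pytest.raises(TaxonomyFormatError):
            parse_taxonomy("kid\tparent\nB\tA\n", "edge_list", ["B"])

    def test_multi_parent_dag_reduced_to_deepest_parent(self):
        # D has parents B (depth 2) and C (depth 3): the deeper parent wins,
        # so depth(D) = 4 under the deepest-path convention.
        text = "child\tparent\nB\tA\nC\tB\nD\tB\nD\tC\n"
        tree = parse_taxonomy(text, "edge_list", ["D"])
        assert tree.parent_of["D"] == "C"
        assert tree.depth_of("D") == 4

    def test_duplicate_edge_rejected(self):
        with pytest.raises(TaxonomyFormatError):
            parse_taxonomy("child\tparent\nB\tA\nB\tA\n", "edge_list", ["B"])


class TestInvariants:
    def test_two_roots_rejected(self):
        with pytest.raises(TaxonomyStructureError):
            parse_taxonomy("child\tparent\nB\tA\nD\tC\n", "edge_list", ["B"])

    def test_ancestral_leaf_set_rejected(self):
        with pytest.raises(TaxonomyStructureError):
            TaxonomyTree(
                parent_of={"A": "root", "B": "A"}, root="root", leaf_set=("A", "B")
            )

    def test_duplicate_leaf_set_rejected(self):
        with pytest.raises(TaxonomyFormatError):
            TaxonomyTree(parent_of={"A": "root"}, root="root", leaf_set=("A", "A"))


class TestDepthAndLCS:
    def test_depth_convention(self, tiny_tree):
        assert tiny_tree.depth_of("root") == 1
        assert tiny_tree.depth_of("A") == 2
        assert tiny_tree.depth_of("B") == 3

    def test_depth_recurrence_on_random_trees(self):
        rng = np.random.default_rng(0)
        tree = random_tree(rng, n_internal=10, n_leaves=15)
        for node, parent in tree.parent_of.items():
            assert tree.depth_of(parent) == tree.depth_of(node) - 1

    def test_lcs_self_containment_and_disjoint(self, tiny_tree):
        assert tiny_tree.lowest_common_subsumer("B", "B") == "B"
        assert tiny_tree.lowest_common_subsumer("B", "A") == "A"
        assert tiny_tree.lowest_common_subsumer("B", "C") == "A"

    def test_disjoint_branches_meet_at_root(self, binary_tree):
        assert binary_tree.lowest_common_subsumer("r.0.0.0.0", "r.1.1.1.1") == "r"

    def test_unknown_node_lookup_error(self, tiny_tree):
        with pytest.raises(NodeLookupError):
            tiny_tree.depth_of("nope")
        with pytest.raises(NodeLookupError):
            tiny_tree.lowest_common_subsumer("B", "nope")


class TestWuPalmer:
    def test_identity_is_one(self, tiny_tree, binary_tree):
        assert tiny_tree.wu_palmer_similarity("B", "B") == 1.0
        leaf = binary_tree.leaf_set[5]
        assert binary_tree.wu_palmer_similarity(leaf, leaf) == 1.0

    def test_sibling_leaves_value(self, tiny_tree):
        # depths 3 and 3, LCS at depth 2: 2*2/(3+3)
        assert tiny_tree.wu_palmer_similarity("B", "C") == pytest.approx(2 / 3)

    def test_root_lcs_forces_formula(self):
        tree = parse_taxonomy(
            "child\tparent\nA\tr\nB\tr\nC\tA\n", "edge_list", ["C", "B"]
        )
        # depths 3 and 2, LCS = root at depth 1
        assert tree.wu_palmer_similarity("C", "B") == pytest.approx(2 * 1 / (3 + 2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, n_internal=8, n_leaves=10)
        leaves = tree.leaf_set
        x = leaves[int(rng.integers(len(leaves)))]
        y = leaves[int(rng.integers(len(leaves)))]
        assert tree.wu_palmer_similarity(x, y) == tree.wu_palmer_similarity(y, x)

    def test_monotone_in_lcs_depth(self, binary_tree):
        # fixed leaf depths: deeper LCS means strictly larger similarity
        a = "r.0.0.0.0"
        partners = ["r.0.0.0.1", "r.0.0.1.0", "r.0.1.0.0", "r.1.0.0.0"]
        sims = [binary_tree.wu_palmer_similarity(a, p) for p in partners]
        assert sims == sorted(sims, reverse=True)
        assert len(set(sims)) == len(sims)


class TestSimilarityMatrix:
    def test_matches_pairwise_calls(self, binary_tree):
        matrix = taxonomy_similarity_matrix(binary_tree)
        names = matrix.names
        for i in range(0, len(names), 3):
            for j in range(0, i, 2):
                assert matrix.values[i, j] == pytest.approx(
                    binary_tree.wu_palmer_similarity(names[i], names[j])
                )

    def test_symmetric_unit_diagonal(self, binary_tree):
        matrix = taxonomy_similarity_matrix(binary_tree)
        assert np.array_equal(matrix.values, matrix.values.T)
        assert np.array_equal(np.diag(matrix.values), np.ones(len(matrix.names)))

    def test_matches_root_path_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            tree = random_tree(rng, n_internal=12, n_leaves=20)
            if len(tree.leaf_set) < 2:
                continue
            matrix = taxonomy_similarity_matrix(tree)
            for i, x in enumerate(matrix.names):
                for j, y in enumerate(matrix.names[:i]):
                    assert matrix.values[i, j] == wu_palmer_oracle(tree, x, y)

    def test_single_leaf_rejected(self):
        tree = TaxonomyTree(parent_of={"A": "root"}, root="root", leaf_set=("A",))
        with pytest.raises(SizeError):
            taxonomy_similarity_matrix(tree)


class TestSuperordinates:
    def test_root_covers_everything(self, binary_tree):
        scheme = map_to_superordinates(binary_tree, ["r"])
        assert set(scheme.assignment.values()) == {"r"}

    def test_disjoint_partition(self, binary_tree):
        scheme = map_to_superordinates(binary_tree, ["r.0", "r.1"])
        assert scheme.members("r.0") == binary_tree.leaf_set[:8]
        assert scheme.members("r.1") == binary_tree.leaf_set[8:]
        assert "unassigned" not in scheme.assignment.values()

    def test_uncovered_leaf_is_unassigned(self, binary_tree):
        scheme = map_to_superordinates(binary_tree, ["r.0"])
        assert scheme.assignment["r.1.0.0.0"] == "unassigned"
        assert scheme.assignment["r.0.1.0.0"] == "r.0"

    def test_ancestral_names_rejected(self, binary_tree):
        with pytest.raises(SchemeError):
            map_to_superordinates(binary_tree, ["r.0", "r.0.1"])

    def test_level_helper(self, binary_tree):
        names = superordinates_at_level(binary_tree, 2)
        assert names == ("r.0.0", "r.0.1", "r.1.0", "r.1.1")
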