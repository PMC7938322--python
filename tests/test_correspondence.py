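"""Correspondence statistics and the permutation structure test."""

import numpy as np
import pytest

from taxorsa import (
    ActivationSet,
    AlignmentError,
    DegenerateInputError,
    SimilarityMatrix,
    SizeError,
    branch_correspondence,
    coarse_correspondence,
    correspondence_summary,
    fine_correspondence,
    map_to_superordinates,
    matrix_correspondence,
    structure_variance_test,
    superordinate_similarity_matrix,
    taxonomy_similarity_matrix,
)
from taxorsa.representation import category_mean_patterns, category_rsm

from conftest import lower_triangle_oracle, pearson_oracle


def sym(values, names, kind="representational"):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(names=tuple(names), values=values, kind=kind)


@pytest.fixture(scope="module")
def binary_rep(binary_acts, binary_tax):
    rep = category_rsm(category_mean_patterns(binary_acts))
    return rep.reindex(binary_tax.names)


class TestMatrixCorrespondence:
    def test_self_correspondence_is_one(self, binary_tax):
        assert matrix_correspondence(binary_tax, binary_tax) == pytest.approx(1.0)

    def test_positive_affine_image_is_one(self, binary_tax):
        affine = sym(0.5 * binary_tax.values + 0.2, binary_tax.names)
        assert matrix_correspondence(affine, binary_tax) == pytest.approx(1.0)

    def test_hand_written_4x4_matches_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-1, 1, (4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        b = rng.uniform(-1, 1, (4, 4))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 1.0)
        names = list("wxyz")
        expected = pearson_oracle(lower_triangle_oracle(a), lower_triangle_oracle(b))
        assert matrix_correspondence(sym(a, names), sym(b, names)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_name_mismatch_is_alignment_error(self, binary_tax):
        shuffled = binary_tax.submatrix(binary_tax.names[::-1])
        with pytest.raises(AlignmentError):
            matrix_correspondence(shuffled, binary_tax)

    def test_constant_triangle_is_degenerate(self):
        names = list("abc")
        flat = sym(np.full((3, 3), 0.5) + 0.5 * np.eye(3), names)
        varied = sym(np.eye(3) * 0.5 + 0.5, names)
        varied.values[1, 0] = varied.values[0, 1] = 0.2
        with pytest.raises(DegenerateInputError):
            matrix_correspondence(flat, varied)

    def test_invariant_to_simultaneous_reordering(self, binary_rep, binary_tax):
        base = matrix_correspondence(binary_rep, binary_tax)
        order = list(binary_tax.names[::-1])
        again = matrix_correspondence(
            binary_rep.submatrix(order), binary_tax.submatrix(order)
        )
        assert again == pytest.approx(base, abs=1e-12)


class TestBranchCorrespondence:
    def test_root_branch_equals_global(self, binary_rep, binary_tax, binary_tree):
        assert branch_correspondence(
            binary_rep, binary_tax, binary_tree, "r"
        ) == pytest.approx(matrix_correspondence(binary_rep, binary_tax))

    def test_matches_masking_oracle(self, binary_rep, binary_tax, binary_tree):
        branch = "r.0"
        leaves = [l for l in binary_tax.names if l.startswith("r.0.")]
        idx = [binary_tax.names.index(l) for l in leaves]
        expected = pearson_oracle(
            lower_triangle_oracle(binary_rep.values[np.ix_(idx, idx)]),
            lower_triangle_oracle(binary_tax.values[np.ix_(idx, idx)]),
        )
        assert branch_correspondence(
            binary_rep, binary_tax, binary_tree, branch
        ) == pytest.approx(expected, abs=1e-12)

    def test_small_branch_is_size_error(self, binary_rep, binary_tax, binary_tree):
        with pytest.raises(SizeError):
            branch_correspondence(binary_rep, binary_tax, binary_tree, "r.0.0.0")


class TestSuperordinateMatrix:
    def test_singleton_groups_reproduce_sub_rsm(self, binary_tree, binary_rep):
        scheme = map_to_superordinates(
            binary_tree, ["r.0.0.0", "r.0.1.0", "r.1.0.0", "r.1.1.0"]
        )
        # keep one category per superordinate
        keep = {g: ms[0] for g, ms in
                ((n, scheme.members(n)) for n in scheme.superordinate_names)}
        assignment = {}
        for leaf, g in scheme.assignment.items():
            if g != "unassigned" and leaf == keep[g]:
                assignment[leaf] = g
            else:
                assignment[leaf] = "unassigned"
        from taxorsa import SuperordinateScheme

        singles = SuperordinateScheme(scheme.superordinate_names, assignment)
        got = superordinate_similarity_matrix(binary_rep, singles)
        sub = binary_rep.submatrix([keep[n] for n in got.names])
        assert np.allclose(got.values, sub.values)

    def test_block_constant_input_recovers_block_values(self, binary_tree):
        scheme = map_to_superordinates(binary_tree, ["r.0.0", "r.0.1", "r.1.0"])
        names = binary_tree.leaf_set
        values = np.eye(len(names))
        group_of = {l: scheme.assignment[l] for l in names}
        block = {("r.0.0", "r.0.0"): 0.8, ("r.0.1", "r.0.1"): 0.7,
                 ("r.1.0", "r.1.0"): 0.6, ("r.0.0", "r.0.1"): 0.4,
                 ("r.0.0", "r.1.0"): 0.2, ("r.0.1", "r.1.0"): 0.1}
        for i, a in enumerate(names):
            for j, b in enumerate(names[:i]):
                ga, gb = group_of[a], group_of[b]
                if "unassigned" in (ga, gb):
                    v = 0.0
                else:
                    v = block.get((ga, gb), block.get((gb, ga)))
                values[i, j] = values[j, i] = v
        got = superordinate_similarity_matrix(sym(values, names), scheme)
        for (ga, gb), v in block.items():
            ia, ib = got.names.index(ga), got.names.index(gb)
            assert got.values[ia, ib] == pytest.approx(v)

    def test_three_groups_of_two_match_hand_averages(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(-1, 1, (6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        names = list("abcdef")
        from taxorsa import SuperordinateScheme

        scheme = SuperordinateScheme(
            ("G1", "G2", "G3"),
            {"a": "G1", "b": "G1", "c": "G2", "d": "G2", "e": "G3", "f": "G3"},
        )
        got = superordinate_similarity_matrix(sym(values, names), scheme)
        assert got.values[got.names.index("G1"), got.names.index("G2")] == (
            pytest.approx(np.mean([values[0, 2], values[0, 3],
                                   values[1, 2], values[1, 3]]))
        )
        assert got.values[got.names.index("G1"), got.names.index("G1")] == (
            pytest.approx(values[0, 1])
        )


class TestCoarseAndFine:
    def test_affine_rep_gives_coarse_one(self, binary_tax, binary_scheme):
        rep = sym(0.7 * binary_tax.values + 0.1, binary_tax.names)
        assert coarse_correspondence(
            rep, binary_tax, binary_scheme
        ) == pytest.approx(1.0)

    def test_anti_ordered_matrices_give_negative_coarse(self, binary_tax,
                                                        binary_scheme):
        rep = sym(1.0 - binary_tax.values + np.eye(len(binary_tax.names)),
                  binary_tax.names)
        assert coarse_correspondence(rep, binary_tax, binary_scheme) < 0

    def test_coarse_composes_the_two_oracles(self, binary_rep, binary_tax,
                                             binary_scheme):
        rep_s = superordinate_similarity_matrix(binary_rep, binary_scheme)
        tax_s = superordinate_similarity_matrix(binary_tax, binary_scheme)
        expected = pearson_oracle(
            lower_triangle_oracle(rep_s.values),
            lower_triangle_oracle(tax_s.reindex(rep_s.names).values),
        )
        assert coarse_correspondence(
            binary_rep, binary_tax, binary_scheme
        ) == pytest.approx(expected, abs=1e-12)

    def test_fine_equals_one_on_equal_submatrices(self, binary_tax, binary_scheme):
        mean, by = fine_correspondence(binary_tax, binary_tax, binary_scheme)
        assert mean == pytest.approx(1.0)
        assert len(by) == 4

    def test_small_superordinates_are_skipped(self, binary_rep, binary_tax,
                                              binary_tree):
        # level-3 superordinates hold 2 categories each: all skipped
        from taxorsa import superordinates_at_level

        scheme = map_to_superordinates(
            binary_tree, superordinates_at_level(binary_tree, 3)
        )
        with pytest.raises(DegenerateInputError):
            fine_correspondence(binary_rep, binary_tax, scheme)

    def test_fine_mean_averages_per_group_oracles(self, binary_rep, binary_tax,
                                                  binary_scheme):
        mean, by = fine_correspondence(binary_rep, binary_tax, binary_scheme)
        expected = {}
        for name in binary_scheme.superordinate_names:
            members = list(binary_scheme.members(name))
            idx = [binary_tax.names.index(m) for m in members]
            expected[name] = pearson_oracle(
                lower_triangle_oracle(binary_rep.values[np.ix_(idx, idx)]),
                lower_triangle_oracle(binary_tax.values[np.ix_(idx, idx)]),
            )
        assert by == pytest.approx(expected, abs=1e-12)
        assert mean == pytest.approx(np.mean(list(expected.values())), abs=1e-12)

    def test_summary_bundles_consistent_pair_counts(self, binary_rep, binary_tax,
                                                    binary_scheme, binary_tree):
        res = correspondence_summary(
            binary_rep, binary_tax, scheme=binary_scheme, tree=binary_tree,
            branches=("r.0",),
        )
        assert res.n_pairs_global == 16 * 15 // 2
        assert res.n_pairs_coarse == 4 * 3 // 2
        assert all(n == 6 for n in res.n_pairs_fine.values())
        assert "r.0" in res.r_by_branch


class TestStructureVarianceTest:
    def test_identical_stimuli_give_p_one(self):
        row = np.array([1.0, 2.0, 5.0, 3.0])
        acts = ActivationSet(
            stimulus_ids=tuple(f"s{i}" for i in range(6)),
            category_labels=("a", "a", "b", "b", "c", "c"),
            responses=np.tile(row, (6, 1)),
        )
        res = structure_variance_test(acts, n_permutations=49, seed=0)
        assert res.observed_variance == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hierarchical_data_give_minimal_p(self, binary_acts):
        res = structure_variance_test(binary_acts, n_permutations=99, seed=5)
        assert res.p_value == pytest.approx(1 / 100)

    def test_seed_fixes_null_distribution(self, binary_acts):
        a = structure_variance_test(binary_acts, n_permutations=20, seed=9)
        b = structure_variance_test(binary_acts, n_permutations=20, seed=9)
        assert np.array_equal(a.null_variances, b.null_variances)

    def test_single_stimulus_categories_warn(self):
        rng = np.random.default_rng(2)
        acts = ActivationSet(
            stimulus_ids=("s0", "s1", "s2"),
            category_labels=("a", "b", "c"),
            responses=rng.standard_normal((3, 8)),
        )
        with pytest.warns(UserWarning):
            structure_variance_test(acts, n_permutations=5, seed=1)
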