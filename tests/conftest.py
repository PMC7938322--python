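"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from taxorsa import (
    HierParams,
    TaxonomyTree,
    hierarchical_activations,
    map_to_superordinates,
    random_taxonomy,
    superordinates_at_level,
    taxonomy_similarity_matrix,
)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; never share code with the
# implementation they check)


def root_path_oracle(tree: TaxonomyTree, node: str) -> list[str]:
    path = [node]
    while path[-1] != tree.root:
        path.append(tree.parent_of[path[-1]])
    return list(reversed(path))


def wu_palmer_oracle(tree: TaxonomyTree, x: str, y: str) -> float:
    """Enumerate both root paths and intersect them."""
    px, py = root_path_oracle(tree, x), root_path_oracle(tree, y)
    common = set(px) & set(py)
    n = max(len(root_path_oracle(tree, c)) for c in common)
    return 2.0 * n / (len(px) + len(py))


def pearson_oracle(a, b) -> float:
    """Direct covariance / sigma formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


def lower_triangle_oracle(values: np.ndarray) -> np.ndarray:
    out = []
    for i in range(values.shape[0]):
        for j in range(i):
            out.append(values[i, j])
    return np.array(out)


def random_tree(rng: np.random.Generator, n_internal: int,
                n_leaves: int) -> TaxonomyTree:
    """Grow a random (unbalanced) tree by attaching nodes to random
    existing nodes; the leaf set is the topological leaves, which are
    mutually non-ancestral by construction."""
    parent_of: dict[str, str] = {}
    nodes = ["root"]
    for k in range(n_internal):
        name = f"i{k}"
        parent_of[name] = nodes[int(rng.integers(len(nodes)))]
        nodes.append(name)
    for k in range(n_leaves):
        name = f"L{k}"
        parent_of[name] = nodes[int(rng.integers(len(nodes)))]
    has_child = set(parent_of.values())
    leaves = [n for n in list(parent_of) if n not in has_child]
    return TaxonomyTree(parent_of=parent_of, root="root", leaf_set=tuple(leaves))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def tiny_tree() -> TaxonomyTree:
    """root -> A -> {B, C}: the smallest tree with a non-trivial pair."""
    return TaxonomyTree(
        parent_of={"A": "root", "B": "A", "C": "A"},
        root="root",
        leaf_set=("B", "C"),
    )


@pytest.fixture(scope="session")
def binary_tree() -> TaxonomyTree:
    """Balanced depth-4 binary taxonomy: 16 leaves, the smallest tree
    supporting both coarse (level-2) and fine analyses."""
    return random_taxonomy(4, 2)


@pytest.fixture(scope="session")
def default_tree() -> TaxonomyTree:
    """The generator's default taxonomy: depth 4, branching 3, 81 leaves."""
    return random_taxonomy(4, 3)


@pytest.fixture(scope="session")
def binary_scheme(binary_tree):
    return map_to_superordinates(
        binary_tree, superordinates_at_level(binary_tree, 2)
    )


@pytest.fixture(scope="session")
def binary_tax(binary_tree):
    return taxonomy_similarity_matrix(binary_tree)


@pytest.fixture(scope="session")
def binary_acts(binary_tree):
    params = HierParams(depth=4, branching=2, n_units=150, noise_sd=0.4,
                        n_stimuli_per_category=6, seed=11)
    return hierarchical_activations(binary_tree, params)
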