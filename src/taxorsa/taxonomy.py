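"""Rooted concept hierarchies and Wu-Palmer taxonomic similarity.

A :class:`TaxonomyTree` is a rooted tree over concept names together with an
ordered *leaf set*: the categories under analysis. Depths follow the
node-counting convention, ``depth(root) = 1``, so that the Wu-Palmer
similarity

    sim(x, y) = 2 * depth(lcs(x, y)) / (depth(x) + depth(y))

is well defined everywhere and equals 1 exactly when ``x == y``. The leaf
set need not consist of topological leaves, but no member may be an
ancestor of another, which guarantees ``sim < 1`` off the diagonal.

Edge-list input may describe a DAG (ontologies such as WordNet allow
multiple hypernyms); it is reduced to a tree by keeping, for every node,
a parent that lies on a maximal-depth root path (ties broken by
lexicographically smallest parent name). The reduction is logged.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    NodeLookupError,
    SchemeError,
    SizeError,
    TaxonomyFormatError,
    TaxonomyStructureError,
)
from .representation import SimilarityMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxonomyTree:
    """Rooted labeled hierarchy of concepts.

    Parameters
    ----------
    parent_of
        Map from every non-root node to its unique parent.
    root
        Name of the root concept.
    leaf_set
        Ordered list of designated leaf concepts (the categories under
        analysis). Matrices built from the tree inherit this order.
    """

    parent_of: Mapping[str, str]
    root: str
    leaf_set: tuple[str, ...]
    _depth: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        parent_of = dict(self.parent_of)
        object.__setattr__(self, "parent_of", parent_of)
        object.__setattr__(self, "leaf_set", tuple(self.leaf_set))
        if self.root in parent_of:
            raise TaxonomyStructureError(f"root {self.root!r} has a parent")
        nodes = set(parent_of) | {self.root}
        for child, parent in parent_of.items():
            if parent not in nodes:
                raise TaxonomyStructureError(
                    f"parent {parent!r} of {child!r} is not a node"
                )
        # Walk each node up to the root once; a revisit within one walk is a
        # cycle, and every walk must terminate at the root.
        depth: dict[str, int] = {self.root: 1}
        for start in parent_of:
            chain = []
            node = start
            while node not in depth:
                if node in chain:
                    raise TaxonomyStructureError(f"cycle through {node!r}")
                chain.append(node)
                if node not in parent_of:
                    raise TaxonomyStructureError(
                        f"{node!r} is not reachable from root {self.root!r}"
                    )
                node = parent_of[node]
            base = depth[node]
            for offset, name in enumerate(reversed(chain), start=1):
                depth[name] = base + offset
        object.__setattr__(self, "_depth", depth)

        seen = set()
        for leaf in self.leaf_set:
            if leaf not in nodes:
                raise NodeLookupError(f"leaf {leaf!r} is not a node of the tree")
            if leaf in seen:
                raise TaxonomyFormatError(f"duplicate leaf {leaf!r} in leaf_set")
            seen.add(leaf)
        for leaf in self.leaf_set:
            for anc in self._ancestors(leaf):
                if anc != leaf and anc in seen:
                    raise TaxonomyStructureError(
                        f"leaf_set member {anc!r} is an ancestor of {leaf!r}"
                    )

    # -- basic queries ---------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._depth)

    def __contains__(self, name: str) -> bool:
        return name in self._depth

    def _require(self, name: str) -> None:
        if name not in self._depth:
            raise NodeLookupError(f"unknown concept {name!r}")

    def _ancestors(self, name: str) -> Iterable[str]:
        """Yield ``name`` and every ancestor up to the root."""
        node = name
        while True:
            yield node
            if node == self.root:
                return
            node = self.parent_of[node]

    def root_path(self, name: str) -> tuple[str, ...]:
        """Nodes on the root-to-``name`` path, root first."""
        self._require(name)
        return tuple(reversed(list(self._ancestors(name))))

    def depth_of(self, name: str) -> int:
        """Node count on the root path, ``depth_of(root) == 1``."""
        self._require(name)
        return self._depth[name]

    def is_ancestor(self, anc: str, desc: str) -> bool:
        """True if ``anc`` is ``desc`` or an ancestor of ``desc``."""
        self._require(anc)
        self._require(desc)
        return anc in self._ancestors(desc)

    def leaves_under(self, branch: str) -> tuple[str, ...]:
        """Leaf-set members descending from ``branch``, in leaf-set order."""
        self._require(branch)
        return tuple(l for l in self.leaf_set if self.is_ancestor(branch, l))

    # -- Wu-Palmer -------------------------------------------------------

    def lowest_common_subsumer(self, x: str, y: str) -> str:
        """Deepest node that is an ancestor-or-self of both concepts."""
        self._require(x)
        self._require(y)
        px, py = self.root_path(x), self.root_path(y)
        k = min(len(px), len(py))
        last = 0
        while last < k and px[last] == py[last]:
            last += 1
        return px[last - 1]

    def wu_palmer_similarity(self, x: str, y: str) -> float:
        """``2 * depth(lcs) / (depth(x) + depth(y))``, in (0, 1]."""
        lcs = self.lowest_common_subsumer(x, y)
        return 2.0 * self._depth[lcs] / (self._depth[x] + self._depth[y])

    def similarity_matrix(self) -> SimilarityMatrix:
        """All-pairs Wu-Palmer similarity over the leaf set.

        Row/column order follows ``leaf_set``; the matrix is exactly
        symmetric with unit diagonal.
        """
        if len(self.leaf_set) < 2:
            raise SizeError("similarity matrix needs a leaf_set of size >= 2")
        paths = [self.root_path(l) for l in self.leaf_set]
        depths = np.array([len(p) for p in paths], dtype=float)
        n = len(paths)
        values = np.eye(n)
        for i in range(n):
            for j in range(i):
                pi, pj = paths[i], paths[j]
                k = min(len(pi), len(pj))
                d = 0
                while d < k and pi[d] == pj[d]:
                    d += 1
                values[i, j] = values[j, i] = 2.0 * d / (depths[i] + depths[j])
        return SimilarityMatrix(names=self.leaf_set, values=values, kind="taxonomic")


@dataclass(frozen=True)
class SuperordinateScheme:
    """Grouping of leaf categories under named internal nodes."""

    superordinate_names: tuple[str, ...]
    assignment: Mapping[str, str]

    def members(self, name: str) -> tuple[str, ...]:
        return tuple(l for l, s in self.assignment.items() if s == name)

    @property
    def assigned(self) -> tuple[str, ...]:
        return tuple(l for l, s in self.assignment.items() if s != UNASSIGNED)


# ---------------------------------------------------------------------------
# construction


def parse_taxonomy(
    source: str | os.PathLike,
    format: str,
    leaf_set: Sequence[str],
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from a Newick or edge-list document.

    ``source`` may be a path or the document text itself. The Newick
    dialect requires internal-node labels (superordinates must be
    nameable); branch lengths are ignored. The edge-list format is a TSV
    with header ``child<TAB>parent``; multi-parent input is reduced to a
    tree by the deepest-parent convention.
    """
    text = _read_source(source)
    if format == "newick":
        parent_of, root = _parse_newick(text)
    elif format == "edge_list":
        parent_of, root = _parse_edge_list(text)
    else:
        raise TaxonomyFormatError(f"unknown taxonomy format {format!r}")
    return TaxonomyTree(parent_of=parent_of, root=root, leaf_set=tuple(leaf_set))


def _read_source(source: str | os.PathLike) -> str:
    s = os.fspath(source)
    if "\n" not in s and ";" not in s and "\t" not in s and os.path.exists(s):
        with open(s, "r", encoding="utf-8") as fh:
            return fh.read()
    return s


def _parse_newick(text: str) -> tuple[dict[str, str], str]:
    import dendropy

    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TaxonomyFormatError(f"malformed Newick document: {exc}") from exc

    def name_of(node) -> str | None:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label or None

    parent_of: dict[str, str] = {}
    seen: set[str] = set()
    root_name = name_of(tree.seed_node)
    if root_name is None:
        raise TaxonomyFormatError("Newick root node must be labeled")
    for node in tree.preorder_node_iter():
        name = name_of(node)
        if name is None:
            raise TaxonomyFormatError(
                "all Newick nodes (including internal nodes) must be labeled"
            )
        if name in seen:
            raise TaxonomyFormatError(f"duplicate node name {name!r}")
        seen.add(name)
        if node.parent_node is not None:
            parent_of[name] = name_of(node.parent_node)
    return parent_of, root_name


def _parse_edge_list(text: str) -> tuple[dict[str, str], str]:
    import pandas as pd

    try:
        table = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    except Exception as exc:
        raise TaxonomyFormatError(f"malformed edge list: {exc}") from exc
    if list(table.columns[:2]) != ["child", "parent"]:
        raise TaxonomyFormatError(
            "edge list must start with header 'child<TAB>parent', "
            f"got {list(table.columns)!r}"
        )
    if table.isna().any().any():
        raise TaxonomyFormatError("edge list contains empty fields")

    parents: dict[str, list[str]] = {}
    for child, parent in zip(table["child"], table["parent"]):
        parents.setdefault(child, [])
        if parent in parents[child]:
            raise TaxonomyFormatError(f"duplicate edge {child!r} -> {parent!r}")
        parents[child].append(parent)
    nodes = set(parents) | {p for ps in parents.values() for p in ps}
    roots = sorted(nodes - set(parents))
    if len(roots) != 1:
        raise TaxonomyStructureError(
            f"expected exactly one root, found {len(roots)}: {roots!r}"
        )
    root = roots[0]

    # Longest root path per node over the DAG; topological order detects
    # cycles. Reduction then keeps a deepest parent per node.
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    for child, ps in parents.items():
        for parent in ps:
            graph.add_edge(parent, child)
    try:
        order = list(nx.topological_sort(graph))
    except nx.NetworkXUnfeasible as exc:
        raise TaxonomyStructureError("edge list contains a cycle") from exc
    depth = {root: 1}
    for node in order:
        if node == root:
            continue
        depth[node] = 1 + max(depth[p] for p in parents[node])
    parent_of: dict[str, str] = {}
    for node, ps in parents.items():
        best = sorted(ps, key=lambda p: (-depth[p], p))[0]
        if len(ps) > 1:
            logger.info(
                "node %r has %d parents; keeping deepest parent %r",
                node, len(ps), best,
            )
        parent_of[node] = best
    return parent_of, root


# ---------------------------------------------------------------------------
# functional wrappers (operation-style API)


def depth_of(tree: TaxonomyTree, x: str) -> int:
    return tree.depth_of(x)


def lowest_common_subsumer(tree: TaxonomyTree, x: str, y: str) -> str:
    return tree.lowest_common_subsumer(x, y)


def wu_palmer_similarity(tree: TaxonomyTree, x: str, y: str) -> float:
    return tree.wu_palmer_similarity(x, y)


def taxonomy_similarity_matrix(tree: TaxonomyTree) -> SimilarityMatrix:
    return tree.similarity_matrix()


def map_to_superordinates(
    tree: TaxonomyTree, superordinate_names: Sequence[str]
) -> SuperordinateScheme:
    """Assign each leaf to the unique named ancestor, else ``unassigned``.

    The named concepts must be internal (non-leaf-set) nodes and mutually
    non-ancestral, so the assignment is unambiguous.
    """
    names = tuple(superordinate_names)
    for name in names:
        tree._require(name)
        if name in tree.leaf_set:
            raise SchemeError(f"superordinate {name!r} is a leaf-set member")
    for a in names:
        for b in names:
            if a != b and tree.is_ancestor(a, b):
                raise SchemeError(
                    f"superordinates must be mutually non-ancestral: "
                    f"{a!r} subsumes {b!r}"
                )
    named = set(names)
    assignment: dict[str, str] = {}
    for leaf in tree.leaf_set:
        hit = [a for a in tree._ancestors(leaf) if a in named]
        assignment[leaf] = hit[0] if hit else UNASSIGNED
    return SuperordinateScheme(superordinate_names=names, assignment=assignment)


def superordinates_at_level(tree: TaxonomyTree, level: int) -> tuple[str, ...]:
    """Internal nodes at taxonomy level ``level`` (root is level 0).

    Convenience for building schemes on balanced taxonomies; nodes are
    returned in sorted name order.
    """
    if level < 1:
        raise SchemeError("superordinate level must be >= 1")
    leaves = set(tree.leaf_set)
    picked = tuple(sorted(
        n for n in tree.nodes if tree.depth_of(n) == level + 1 and n not in leaves
    ))
    if not picked:
        raise SchemeError(f"no internal nodes at level {level}")
    return picked
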