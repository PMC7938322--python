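"""Readers and writers for the pipeline's file formats.

Formats are plain text wherever practical: activation tables as TSV/CSV
(``stimulus_id``, ``category``, then one column per unit) or HDF5 with
the same logical layout; similarity matrices as TSV with a name header
row and column; taxonomies as Newick (internal labels required) or
child/parent edge-list TSV; reports as JSON. Writers store full
precision so write-then-read round trips are exact.
"""

from __future__ import annotations

import json
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .representation import ActivationSet, CategoryPatterns, SimilarityMatrix
from .taxonomy import TaxonomyTree, SuperordinateScheme

_FLOAT_FMT = "%.17g"


def _sep_for(path: str) -> str:
    return "," if os.fspath(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# activation tables


def load_activation_table(path: str | os.PathLike) -> ActivationSet:
    """Read an activation table (TSV/CSV/HDF5 chosen by extension)."""
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        return _load_activation_h5(path)
    sep = _sep_for(path)
    try:
        table = pd.read_csv(path, sep=sep, dtype={0: str, 1: str},
                            float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed table: {exc}") from exc
    cols = list(table.columns)
    if cols[:2] != ["stimulus_id", "category"]:
        raise ParseError(
            f"{path}: header must start with 'stimulus_id' and 'category', "
            f"got {cols[:2]!r}"
        )
    if len(cols) < 3:
        raise ParseError(f"{path}: no unit columns found")
    unit_cols = cols[2:]
    try:
        responses = table[unit_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric unit value: {exc}") from exc
    bad = np.flatnonzero(~np.isfinite(responses).all(axis=1))
    if bad.size:
        raise ParseError(
            f"{path}: non-finite value at data line {bad[0] + 2}"
        )
    return ActivationSet(
        stimulus_ids=tuple(table["stimulus_id"]),
        category_labels=tuple(table["category"]),
        responses=responses,
        layer_tag=os.path.splitext(os.path.basename(path))[0],
    )


def write_activation_table(acts: ActivationSet, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        _write_activation_h5(acts, path)
        return
    table = pd.DataFrame(
        acts.responses,
        columns=[f"unit_{k + 1:04d}" for k in range(acts.n_units)],
    )
    table.insert(0, "category", list(acts.category_labels))
    table.insert(0, "stimulus_id", list(acts.stimulus_ids))
    table.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


def _load_activation_h5(path: str) -> ActivationSet:
    import h5py

    with h5py.File(path, "r") as fh:
        for key in ("stimulus_id", "category", "responses"):
            if key not in fh:
                raise ParseError(f"{path}: missing dataset {key!r}")
        return ActivationSet(
            stimulus_ids=tuple(s.decode() for s in fh["stimulus_id"][()]),
            category_labels=tuple(s.decode() for s in fh["category"][()]),
            responses=fh["responses"][()],
            layer_tag=fh.attrs.get("layer_tag", ""),
        )


def _write_activation_h5(acts: ActivationSet, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "stimulus_id", data=[s.encode() for s in acts.stimulus_ids]
        )
        fh.create_dataset(
            "category", data=[s.encode() for s in acts.category_labels]
        )
        fh.create_dataset("responses", data=acts.responses)
        fh.attrs["layer_tag"] = acts.layer_tag


# ---------------------------------------------------------------------------
# similarity matrices and patterns


def write_matrix(matrix: SimilarityMatrix, path: str | os.PathLike) -> None:
    matrix.to_dataframe().to_csv(
        path, sep=_sep_for(os.fspath(path)), float_format=_FLOAT_FMT,
        index_label="category",
    )


def load_matrix(
    path: str | os.PathLike, kind: str = "representational"
) -> SimilarityMatrix:
    path = os.fspath(path)
    try:
        table = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                            float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: malformed matrix: {exc}") from exc
    if list(table.index) != list(table.columns):
        raise ParseError(f"{path}: row and column names differ")
    return SimilarityMatrix(
        names=tuple(table.columns), values=table.to_numpy(dtype=float), kind=kind
    )


def write_patterns(patterns: CategoryPatterns, path: str | os.PathLike) -> None:
    table = pd.DataFrame(
        patterns.patterns,
        index=list(patterns.category_names),
        columns=[f"unit_{k + 1:04d}" for k in range(patterns.patterns.shape[1])],
    )
    table.insert(0, "n_stimuli", list(patterns.n_stimuli))
    table.to_csv(path, sep=_sep_for(os.fspath(path)),
                 float_format=_FLOAT_FMT, index_label="category")


# ---------------------------------------------------------------------------
# taxonomies and schemes


def write_edge_list(tree: TaxonomyTree, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        for child in sorted(tree.parent_of):
            fh.write(f"{child}\t{tree.parent_of[child]}\n")


def to_newick(tree: TaxonomyTree) -> str:
    children: dict[str, list[str]] = {}
    for child, parent in tree.parent_of.items():
        children.setdefault(parent, []).append(child)

    def render(node: str) -> str:
        kids = sorted(children.get(node, []))
        if not kids:
            return node
        return "(" + ",".join(render(k) for k in kids) + ")" + node

    return render(tree.root) + ";"


def write_newick(tree: TaxonomyTree, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree) + "\n")


def load_leaf_set(path: str | os.PathLike) -> tuple[str, ...]:
    """One category name per line; blank lines ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        return tuple(line.strip() for line in fh if line.strip())


def write_scheme(scheme: SuperordinateScheme, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category\tsuperordinate\n")
        for leaf, name in scheme.assignment.items():
            fh.write(f"{leaf}\t{name}\n")


def load_scheme(path: str | os.PathLike) -> SuperordinateScheme:
    path = os.fspath(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns) != ["category", "superordinate"]:
        raise ParseError(
            f"{path}: header must be 'category<TAB>superordinate'"
        )
    assignment = dict(zip(table["category"], table["superordinate"]))
    names = tuple(dict.fromkeys(
        s for s in table["superordinate"] if s != "unassigned"
    ))
    return SuperordinateScheme(superordinate_names=names, assignment=assignment)


# ---------------------------------------------------------------------------
# stage manifests and reports


def load_stage_manifest(
    path: str | os.PathLike,
) -> list[dict]:
    """TSV with columns stage_index, stage_label, activation_path and an
    optional performance column; rows sorted by stage_index."""
    path = os.fspath(path)
    table = pd.read_csv(path, sep="\t")
    required = ["stage_index", "stage_label", "activation_path"]
    if list(table.columns)[: len(required)] != required:
        raise ParseError(
            f"{path}: header must start with {required!r}"
        )
    rows = table.to_dict("records")
    rows.sort(key=lambda r: int(r["stage_index"]))
    return rows


def write_report(report: Mapping, path: str | os.PathLike) -> None:
    """Deterministic JSON: sorted keys, no timestamps, full float repr."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def load_report(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
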