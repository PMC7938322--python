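"""Category response patterns and representational similarity matrices.

Stimulus-level activation tables are averaged within category to obtain
one response pattern per category; the representational similarity
matrix (RSM) is the matrix of Pearson correlations between those
patterns across units. Activations are used as loaded — no rectification
or standardization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    AlignmentError,
    DegeneratePatternError,
    ParameterError,
    SizeError,
)


@dataclass(frozen=True)
class ActivationSet:
    """Stimuli x units response table with per-stimulus category labels."""

    stimulus_ids: tuple[str, ...]
    category_labels: tuple[str, ...]
    responses: np.ndarray
    layer_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimulus_ids", tuple(self.stimulus_ids))
        object.__setattr__(self, "category_labels", tuple(self.category_labels))
        responses = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", responses)
        if responses.ndim != 2:
            raise ParameterError("responses must be a 2-D stimuli x units array")
        n = responses.shape[0]
        if not (len(self.stimulus_ids) == len(self.category_labels) == n):
            raise SizeError(
                "stimulus_ids, category_labels and responses rows must agree: "
                f"{len(self.stimulus_ids)}, {len(self.category_labels)}, {n}"
            )
        if n == 0:
            raise SizeError("activation set has no stimuli")
        if not np.all(np.isfinite(responses)):
            raise ParameterError("responses contain non-finite values")

    @property
    def n_units(self) -> int:
        return self.responses.shape[1]

    @property
    def categories(self) -> tuple[str, ...]:
        """Category names in first-appearance order."""
        return tuple(dict.fromkeys(self.category_labels))


@dataclass(frozen=True)
class CategoryPatterns:
    """Per-category mean response patterns (categories x units)."""

    category_names: tuple[str, ...]
    patterns: np.ndarray
    n_stimuli: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "category_names", tuple(self.category_names))
        object.__setattr__(self, "n_stimuli", tuple(int(k) for k in self.n_stimuli))
        patterns = np.asarray(self.patterns, dtype=float)
        object.__setattr__(self, "patterns", patterns)
        if patterns.shape[0] != len(self.category_names):
            raise SizeError("pattern rows must match category_names")
        if any(k < 1 for k in self.n_stimuli):
            raise SizeError("every category must have >= 1 stimulus")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric category x category similarity matrix with a name index.

    ``kind`` distinguishes taxonomic, representational and superordinate
    matrices; representational and taxonomic kinds carry a unit diagonal.
    """

    names: tuple[str, ...]
    values: np.ndarray
    kind: str = "representational"

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.names)
        if values.shape != (n, n):
            raise SizeError(
                f"matrix shape {values.shape} does not match {n} names"
            )
        if n != len(set(self.names)):
            raise AlignmentError("duplicate category names")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise ParameterError("similarity matrix must be symmetric")

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major; the convention used
        by every correspondence statistic (diagonal excluded)."""
        i, j = np.tril_indices(len(self.names), k=-1)
        return self.values[i, j]

    def submatrix(self, names: Sequence[str]) -> "SimilarityMatrix":
        """Restrict to ``names`` in the given order."""
        index = {n: k for k, n in enumerate(self.names)}
        try:
            idx = [index[n] for n in names]
        except KeyError as exc:
            raise AlignmentError(f"unknown category {exc.args[0]!r}") from exc
        return SimilarityMatrix(
            names=tuple(names),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
        )

    def reindex(self, names: Sequence[str]) -> "SimilarityMatrix":
        """Reorder to ``names``; requires an identical name set."""
        if set(names) != set(self.names):
            raise AlignmentError("reindex requires the same category set")
        return self.submatrix(names)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.names),
                            columns=list(self.names))


def category_mean_patterns(acts: ActivationSet) -> CategoryPatterns:
    """Average stimulus responses within each category, per unit.

    Category order is the first-appearance order of the labels; shuffling
    stimulus rows does not change the result.
    """
    cats = acts.categories
    index = {c: k for k, c in enumerate(cats)}
    codes = np.fromiter((index[c] for c in acts.category_labels), dtype=int,
                        count=len(acts.category_labels))
    sums = np.zeros((len(cats), acts.n_units))
    np.add.at(sums, codes, acts.responses)
    counts = np.bincount(codes, minlength=len(cats))
    return CategoryPatterns(
        category_names=cats,
        patterns=sums / counts[:, None],
        n_stimuli=tuple(int(k) for k in counts),
    )


def category_rsm(
    patterns: CategoryPatterns, method: str = "pearson"
) -> SimilarityMatrix:
    """Correlate category patterns across units into an RSM.

    Entry (i, j) is the Pearson (or, optionally, Spearman) correlation of
    pattern i and pattern j over units; the diagonal is set to exactly 1.
    A category whose pattern is constant across units has no defined
    correlation and raises :class:`DegeneratePatternError`.
    """
    X = patterns.patterns
    if X.shape[0] < 2:
        raise SizeError("RSM needs >= 2 categories")
    if X.shape[1] < 2:
        raise SizeError("RSM needs >= 2 units")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ParameterError(f"unknown correlation method {method!r}")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise DegeneratePatternError(
            "zero-variance response pattern for category "
            f"{patterns.category_names[bad[0]]!r}"
        )
    values = np.corrcoef(X)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        names=patterns.category_names, values=values, kind="representational"
    )
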