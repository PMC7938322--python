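"""Agreement between representational and taxonomic similarity.

Correspondence is the correlation between the strictly-lower-triangle
entries of a representational similarity matrix and a taxonomic one over
the same categories — globally, restricted to a taxonomy branch, at the
coarse superordinate level (between-group means), or at the fine level
(within each superordinate group, averaged).

A permutation test asks whether the spread of pairwise representational
similarities exceeds what label-shuffled data produce: permuting the
stimulus-to-category assignment destroys category structure while
preserving the activation distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import (
    AlignmentError,
    DegenerateInputError,
    DegeneratePatternError,
    ParameterError,
    SizeError,
)
from .representation import (
    ActivationSet,
    SimilarityMatrix,
    category_mean_patterns,
    category_rsm,
)
from .taxonomy import SuperordinateScheme, TaxonomyTree

logger = logging.getLogger(__name__)


def _correlate(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if a.size < 3:
        raise SizeError(f"correlation needs >= 3 pairs, got {a.size}")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateInputError("constant lower triangle; correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ParameterError(f"unknown correlation method {method!r}")


def matrix_correspondence(
    rep: SimilarityMatrix, tax: SimilarityMatrix, method: str = "pearson"
) -> float:
    """Correlation of the two matrices' strictly-lower-triangle entries.

    Both matrices must carry identical name lists in identical order; the
    diagonal is excluded so self-similarity never inflates the statistic.
    """
    if rep.names != tax.names:
        raise AlignmentError(
            "matrices must index the same categories in the same order"
        )
    if len(rep.names) < 3:
        raise SizeError("correspondence needs >= 3 categories")
    return _correlate(rep.lower_triangle(), tax.lower_triangle(), method)


def branch_correspondence(
    rep: SimilarityMatrix,
    tax: SimilarityMatrix,
    tree: TaxonomyTree,
    branch: str,
    method: str = "pearson",
) -> float:
    """Correspondence over pairs whose categories both descend from ``branch``."""
    leaves = [l for l in tree.leaves_under(branch) if l in rep.names]
    if len(leaves) < 3:
        raise SizeError(
            f"branch {branch!r} covers {len(leaves)} categories; need >= 3"
        )
    return matrix_correspondence(rep.submatrix(leaves), tax.submatrix(leaves), method)


def superordinate_similarity_matrix(
    rep: SimilarityMatrix, scheme: SuperordinateScheme
) -> SimilarityMatrix:
    """Average category similarities into a superordinate-level matrix.

    Entry (A, B) for A != B is the mean of the category-pair similarities
    across groups; entry (A, A) is the mean within-group off-diagonal
    similarity (1 for a singleton group). Unassigned leaves are excluded.
    """
    index = {n: k for k, n in enumerate(rep.names)}
    groups = []
    for name in scheme.superordinate_names:
        members = [m for m in scheme.members(name) if m in index]
        if members:
            groups.append((name, np.array([index[m] for m in members])))
    if len(groups) < 3:
        raise SizeError(
            f"need >= 3 superordinates with assigned categories, got {len(groups)}"
        )
    n = len(groups)
    values = np.empty((n, n))
    for a, (_, ia) in enumerate(groups):
        block = rep.values[np.ix_(ia, ia)]
        if ia.size == 1:
            values[a, a] = 1.0
        else:
            tri = block[np.tril_indices(ia.size, k=-1)]
            values[a, a] = tri.mean()
        for b in range(a):
            ib = groups[b][1]
            values[a, b] = values[b, a] = rep.values[np.ix_(ia, ib)].mean()
    return SimilarityMatrix(
        names=tuple(name for name, _ in groups), values=values, kind="superordinate"
    )


def coarse_correspondence(
    rep: SimilarityMatrix,
    tax: SimilarityMatrix,
    scheme: SuperordinateScheme,
    method: str = "pearson",
) -> float:
    """Correspondence between superordinate-averaged matrices.

    Only between-group (off-diagonal) pairs enter the correlation; the
    within-group diagonal means are computed but excluded, since the
    taxonomic diagonal is degenerate at 1.
    """
    rep_s = superordinate_similarity_matrix(rep, scheme)
    tax_s = superordinate_similarity_matrix(tax, scheme)
    return matrix_correspondence(rep_s, tax_s.reindex(rep_s.names), method)


def fine_correspondence(
    rep: SimilarityMatrix,
    tax: SimilarityMatrix,
    scheme: SuperordinateScheme,
    method: str = "pearson",
    min_categories: int = 3,
) -> tuple[float, dict[str, float]]:
    """Within-superordinate correspondence, averaged across groups.

    Groups with fewer than ``min_categories`` assigned categories, or a
    constant taxonomic sub-triangle, are skipped (and logged) rather than
    averaged; the mean over retained groups is unweighted.
    """
    by_super: dict[str, float] = {}
    for name in scheme.superordinate_names:
        members = [m for m in scheme.members(name) if m in rep.names]
        if len(members) < min_categories:
            logger.info("skipping superordinate %r: %d categories", name, len(members))
            continue
        sub_tax = tax.submatrix(members)
        if np.ptp(sub_tax.lower_triangle()) == 0.0:
            logger.info("skipping superordinate %r: constant taxonomic triangle", name)
            continue
        by_super[name] = matrix_correspondence(
            rep.submatrix(members), sub_tax, method
        )
    if not by_super:
        raise DegenerateInputError(
            "no superordinate retained for fine correspondence"
        )
    return float(np.mean(list(by_super.values()))), by_super


@dataclass(frozen=True)
class CorrespondenceResult:
    """Bundle of correspondence statistics for one activation set."""

    r_global: float
    r_coarse: float | None
    r_fine_mean: float | None
    r_fine_by_superordinate: dict[str, float]
    r_by_branch: dict[str, float]
    n_pairs_global: int
    n_pairs_coarse: int | None
    n_pairs_fine: dict[str, int]


def correspondence_summary(
    rep: SimilarityMatrix,
    tax: SimilarityMatrix,
    scheme: SuperordinateScheme | None = None,
    tree: TaxonomyTree | None = None,
    branches: tuple[str, ...] = (),
    method: str = "pearson",
) -> CorrespondenceResult:
    """Compute global, branch, coarse and fine correspondence in one pass."""
    n = len(rep.names)
    r_global = matrix_correspondence(rep, tax, method)
    r_by_branch = {}
    for branch in branches:
        if tree is None:
            raise ParameterError("branch correspondence requires the taxonomy tree")
        r_by_branch[branch] = branch_correspondence(rep, tax, tree, branch, method)
    r_coarse = r_fine_mean = None
    n_pairs_coarse = None
    r_fine_by = {}
    n_pairs_fine = {}
    if scheme is not None:
        r_coarse = coarse_correspondence(rep, tax, scheme, method)
        k = len(superordinate_similarity_matrix(rep, scheme).names)
        n_pairs_coarse = k * (k - 1) // 2
        r_fine_mean, r_fine_by = fine_correspondence(rep, tax, scheme, method)
        for name in r_fine_by:
            m = len([x for x in scheme.members(name) if x in rep.names])
            n_pairs_fine[name] = m * (m - 1) // 2
    return CorrespondenceResult(
        r_global=r_global,
        r_coarse=r_coarse,
        r_fine_mean=r_fine_mean,
        r_fine_by_superordinate=r_fine_by,
        r_by_branch=r_by_branch,
        n_pairs_global=n * (n - 1) // 2,
        n_pairs_coarse=n_pairs_coarse,
        n_pairs_fine=n_pairs_fine,
    )


# ---------------------------------------------------------------------------
# permutation structure test


@dataclass(frozen=True)
class StructureTestResult:
    """Outcome of the label-permutation variance test."""

    observed_variance: float
    null_variances: np.ndarray
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "null_variances", np.asarray(self.null_variances, dtype=float)
        )


def _rsm_lower_variance(responses: np.ndarray, codes: np.ndarray,
                        n_cats: int, method: str) -> float:
    counts = np.bincount(codes, minlength=n_cats).astype(float)
    sums = np.zeros((n_cats, responses.shape[1]))
    np.add.at(sums, codes, responses)
    X = sums / counts[:, None]
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    sd = X.std(axis=1)
    if np.any(sd == 0.0):
        raise DegeneratePatternError("zero-variance pattern")
    values = np.corrcoef(X)
    i, j = np.tril_indices(n_cats, k=-1)
    return float(np.var(values[i, j]))


def structure_variance_test(
    acts: ActivationSet,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> StructureTestResult:
    """Permutation test for category structure in an RSM.

    The observed statistic is the variance of the strictly-lower-triangle
    entries of the category RSM. Each permutation shuffles the
    stimulus-to-category label assignment as a block (category sizes are
    preserved) and recomputes the statistic; the upper-tail p-value uses
    the add-one rule ``p = (1 + #{null >= observed}) / (1 + B)`` so a
    finite permutation count never reports p = 0.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    patterns = category_mean_patterns(acts)
    if len(patterns.category_names) < 3:
        raise SizeError("structure test needs >= 3 categories")
    if min(patterns.n_stimuli) < 2:
        warnings.warn(
            "some categories have a single stimulus; the label permutation "
            "has little to shuffle",
            stacklevel=2,
        )
    observed = float(np.var(category_rsm(patterns, method).lower_triangle()))

    index = {c: k for k, c in enumerate(patterns.category_names)}
    codes = np.fromiter(
        (index[c] for c in acts.category_labels), dtype=int,
        count=len(acts.category_labels),
    )
    n_cats = len(patterns.category_names)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(codes)
        try:
            null[b] = _rsm_lower_variance(acts.responses, perm, n_cats, method)
        except DegeneratePatternError:
            # one resample, then give up: repeated degeneracy means the
            # data cannot support the test
            perm = rng.permutation(codes)
            null[b] = _rsm_lower_variance(acts.responses, perm, n_cats, method)
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_permutations)
    return StructureTestResult(
        observed_variance=observed,
        null_variances=null,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )
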