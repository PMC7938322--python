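"""Synthetic taxonomies and hierarchical category activations.

The generative model mirrors the structure the analysis is designed to
detect. Every node of the taxonomy below the root, at level ``l`` (the
root is level 0), draws an independent Gaussian feature vector across
units with standard deviation ``level_sd[l]``. A category *prototype* is
the sum of the vectors along its root path, so two categories sharing
``k`` of ``D`` ancestral levels have prototype correlation

    rho = sum_{l<=k} sd_l^2 / sum_{l<=D} sd_l^2   (= k/D for equal sds)

— an increasing function of Wu-Palmer similarity on a balanced tree.
Stimuli are prototypes plus independent Gaussian noise.

Training dynamics are modeled by scaling the level-``l`` contribution at
stage ``t`` by ``alpha_l(t) = A_l * (1 - exp(-t / tau_l))`` with shared
underlying draws across stages, so trajectories are smooth and reflect
measurement rather than re-simulation. ``A_l`` is 1 up to the task level
``g`` and the attenuation factor ``lambda`` beyond it: an objective that
discriminates categories only at level ``g`` never fully develops the
deeper distinctions. A co-occurrence knob adds a shared background
vector to paired categories, emulating objects that appear together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .representation import ActivationSet
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class HierParams:
    """Parameters of the hierarchical activation generator.

    ``level_sd`` is the standard deviation of the ancestral feature
    contribution at each level below root (a scalar applies to all
    levels); ``noise_sd`` is the per-stimulus noise standard deviation,
    in the same activation units.
    """

    depth: int = 4
    branching: int | tuple[int, ...] = 3
    n_units: int = 200
    level_sd: float | tuple[float, ...] = 1.0
    noise_sd: float = 0.5
    n_stimuli_per_category: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        branching = self.branching
        if not isinstance(branching, int):
            branching = tuple(int(b) for b in branching)
            object.__setattr__(self, "branching", branching)
            if len(branching) != self.depth:
                raise ParameterError("per-level branching must have `depth` entries")
        if min(self.branching_by_level()) < 2:
            raise ParameterError("branching must be >= 2")
        if self.n_units < 2:
            raise ParameterError("n_units must be >= 2")
        if min(self.level_sd_by_level()) < 0 or self.noise_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.n_stimuli_per_category < 1:
            raise ParameterError("n_stimuli_per_category must be >= 1")

    def branching_by_level(self) -> tuple[int, ...]:
        if isinstance(self.branching, int):
            return (self.branching,) * self.depth
        return self.branching

    def level_sd_by_level(self) -> tuple[float, ...]:
        if isinstance(self.level_sd, (int, float)):
            return (float(self.level_sd),) * self.depth
        sds = tuple(float(s) for s in self.level_sd)
        if len(sds) != self.depth:
            raise ParameterError("per-level level_sd must have `depth` entries")
        return sds


@dataclass(frozen=True)
class DynamicsParams:
    """Stagewise growth of ancestral signal and task-level truncation.

    ``tau_by_level`` sets how fast each level's contribution saturates
    (stage units); choosing them non-decreasing with depth yields the
    coarse-before-fine emergence pattern. Levels deeper than
    ``task_level`` saturate at ``attenuation`` instead of 1.
    """

    tau_by_level: tuple[float, ...]
    task_level: int
    attenuation: float = 1.0
    stages: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        tau = tuple(float(t) for t in self.tau_by_level)
        object.__setattr__(self, "tau_by_level", tau)
        object.__setattr__(self, "stages", tuple(float(s) for s in self.stages))
        if any(t <= 0 for t in tau):
            raise ParameterError("time constants must be > 0")
        if not 1 <= self.task_level <= len(tau):
            raise ParameterError("task_level must lie in [1, depth]")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ParameterError("attenuation must lie in [0, 1]")
        if any(s < 0 for s in self.stages):
            raise ParameterError("stage times must be >= 0")

    def asymptote_by_level(self) -> tuple[float, ...]:
        return tuple(
            1.0 if l <= self.task_level else self.attenuation
            for l in range(1, len(self.tau_by_level) + 1)
        )

    def alpha_at(self, t: float) -> tuple[float, ...]:
        return tuple(
            a * (1.0 - np.exp(-t / tau))
            for a, tau in zip(self.asymptote_by_level(), self.tau_by_level)
        )


def random_taxonomy(
    depth: int, branching: int | Sequence[int], seed: int = 0
) -> TaxonomyTree:
    """Balanced taxonomy with path-encoding node names.

    ``branching`` may be a single factor or one factor per level. The
    construction is deterministic (``seed`` is accepted for interface
    symmetry with the stochastic generators).
    """
    params = HierParams(depth=depth,
                        branching=branching if isinstance(branching, int)
                        else tuple(branching),
                        seed=seed)
    bs = params.branching_by_level()
    parent_of: dict[str, str] = {}
    frontier = ["r"]
    for b in bs:
        nxt = []
        for parent in frontier:
            for i in range(b):
                child = f"{parent}.{i}"
                parent_of[child] = parent
                nxt.append(child)
        frontier = nxt
    return TaxonomyTree(parent_of=parent_of, root="r", leaf_set=tuple(frontier))


def _draw_components(
    tree: TaxonomyTree, n_units: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Unit-variance feature draw per non-root node, in sorted-name order."""
    return {
        node: rng.standard_normal(n_units)
        for node in sorted(n for n in tree.nodes if n != tree.root)
    }


def _assemble(
    tree: TaxonomyTree,
    params: HierParams,
    components: Mapping[str, np.ndarray],
    noise: np.ndarray,
    alpha_by_level: Sequence[float],
    layer_tag: str,
) -> ActivationSet:
    sds = params.level_sd_by_level()
    n_stim = params.n_stimuli_per_category
    ids, labels, rows = [], [], []
    pos = 0
    for leaf in tree.leaf_set:
        path = tree.root_path(leaf)[1:]  # exclude root: no shared global offset
        proto = np.zeros(params.n_units)
        for level, node in enumerate(path, start=1):
            proto += sds[level - 1] * alpha_by_level[level - 1] * components[node]
        for i in range(n_stim):
            ids.append(f"{leaf}#{i}")
            labels.append(leaf)
            rows.append(proto + params.noise_sd * noise[pos])
            pos += 1
    return ActivationSet(
        stimulus_ids=tuple(ids),
        category_labels=tuple(labels),
        responses=np.array(rows),
        layer_tag=layer_tag,
    )


def _check_tree_depth(tree: TaxonomyTree, params: HierParams) -> None:
    max_level = max(tree.depth_of(l) for l in tree.leaf_set) - 1
    if max_level > params.depth:
        raise ParameterError(
            f"tree has levels down to {max_level} but params.depth = {params.depth}"
        )


def hierarchical_activations(
    tree: TaxonomyTree, params: HierParams
) -> ActivationSet:
    """Sample a fully developed hierarchical activation table."""
    _check_tree_depth(tree, params)
    rng = np.random.default_rng(params.seed)
    components = _draw_components(tree, params.n_units, rng)
    n = len(tree.leaf_set) * params.n_stimuli_per_category
    noise = rng.standard_normal((n, params.n_units))
    return _assemble(
        tree, params, components, noise, (1.0,) * params.depth, "synthetic"
    )


def truncated_activations(
    tree: TaxonomyTree, params: HierParams, task_level: int, attenuation: float
) -> ActivationSet:
    """Fully developed activations under a task-granularity truncation.

    Levels deeper than ``task_level`` contribute with amplitude
    ``attenuation``; draws match :func:`hierarchical_activations` at the
    same seed, so the two differ only in the level scalings.
    """
    dyn = DynamicsParams(
        tau_by_level=(1.0,) * params.depth,
        task_level=task_level,
        attenuation=attenuation,
    )
    _check_tree_depth(tree, params)
    rng = np.random.default_rng(params.seed)
    components = _draw_components(tree, params.n_units, rng)
    n = len(tree.leaf_set) * params.n_stimuli_per_category
    noise = rng.standard_normal((n, params.n_units))
    return _assemble(
        tree, params, components, noise, dyn.asymptote_by_level(),
        f"task_level={task_level}",
    )


def staged_activations(
    tree: TaxonomyTree, hier: HierParams, dyn: DynamicsParams
) -> list[ActivationSet]:
    """Activation tables along a training trajectory.

    All stages share one set of underlying draws; only the per-level
    scalings ``alpha_l(t)`` change, so as ``t`` grows (with
    ``task_level = depth``) the output converges to
    :func:`hierarchical_activations` with the same seed.
    """
    if len(dyn.tau_by_level) != hier.depth:
        raise ParameterError("tau_by_level must have one entry per level")
    if not dyn.stages:
        raise ParameterError("DynamicsParams.stages must be non-empty")
    _check_tree_depth(tree, hier)
    rng = np.random.default_rng(hier.seed)
    components = _draw_components(tree, hier.n_units, rng)
    n = len(tree.leaf_set) * hier.n_stimuli_per_category
    noise = rng.standard_normal((n, hier.n_units))
    return [
        _assemble(tree, hier, components, noise, dyn.alpha_at(t), f"t={t:g}")
        for t in dyn.stages
    ]


def apply_cooccurrence(
    acts: ActivationSet,
    pairing: Mapping[str, str],
    strength: float,
    seed: int = 0,
    background_sd: float = 1.0,
) -> ActivationSet:
    """Add a shared background vector to each pair of co-occurring categories.

    ``pairing`` must be symmetric (``pairing[a] == b`` implies
    ``pairing[b] == a``) with disjoint pairs. The background is drawn per
    unordered pair, so applying with (A, B) equals applying with (B, A).
    Strength 0 returns the input unchanged.
    """
    if not 0.0 <= strength <= 1.0:
        raise ParameterError("strength must lie in [0, 1]")
    pairs = set()
    for a, b in pairing.items():
        if a == b:
            raise ParameterError(f"category {a!r} paired with itself")
        if pairing.get(b) != a:
            raise ParameterError(f"pairing not symmetric for {a!r} -> {b!r}")
        pairs.add(tuple(sorted((a, b))))
    flat = [c for p in pairs for c in p]
    if len(flat) != len(set(flat)):
        raise ParameterError("categories must be disjointly paired")
    known = set(acts.categories)
    for c in flat:
        if c not in known:
            raise ParameterError(f"paired category {c!r} not in activation set")
    if strength == 0.0 or not pairs:
        return acts
    rng = np.random.default_rng(seed)
    responses = acts.responses.copy()
    labels = np.asarray(acts.category_labels)
    for a, b in sorted(pairs):
        background = strength * background_sd * rng.standard_normal(acts.n_units)
        mask = (labels == a) | (labels == b)
        responses[mask] += background
    return replace(acts, responses=responses)
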