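"""Developmental trajectories of correspondence across training stages.

Given an ordered sequence of activation sets — one per training stage —
the trajectory records global, coarse and fine correspondence per stage.
A *plateau* is operationalized as the first stage whose value comes
within an absolute tolerance of the final stage's value; stages are
opaque ordered labels with no assumption of equal spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ParameterError, SizeError
from .correspondence import correspondence_summary
from .representation import (
    ActivationSet,
    SimilarityMatrix,
    category_mean_patterns,
    category_rsm,
)
from .taxonomy import SuperordinateScheme


@dataclass(frozen=True)
class TrajectoryRecord:
    """Stage-ordered correspondence series (1-based stage indices)."""

    stage_index: tuple[int, ...]
    stage_label: tuple[str, ...]
    r_global: tuple[float, ...]
    r_coarse: tuple[float, ...]
    r_fine_mean: tuple[float, ...]
    performance: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.stage_index)
        series = [self.stage_label, self.r_global, self.r_coarse, self.r_fine_mean]
        if self.performance is not None:
            series.append(self.performance)
        if any(len(s) != n for s in series):
            raise SizeError("all trajectory series must have the same length")
        if any(b <= a for a, b in zip(self.stage_index, self.stage_index[1:])):
            raise ParameterError("stage_index must be strictly increasing")

    def series(self, name: str) -> tuple[float, ...]:
        value = getattr(self, name)
        if value is None:
            raise ParameterError(f"series {name!r} not recorded")
        return value


def correspondence_trajectory(
    stages: Sequence[ActivationSet],
    tax: SimilarityMatrix,
    scheme: SuperordinateScheme,
    stage_labels: Sequence[str] | None = None,
    performance: Sequence[float] | None = None,
    method: str = "pearson",
) -> TrajectoryRecord:
    """Run the correspondence statistics over an ordered stage sequence.

    Every stage must cover exactly the categories of ``tax``; the stage
    RSM is re-indexed to the taxonomy's category order before comparing.
    """
    if not stages:
        raise SizeError("trajectory needs >= 1 stage")
    labels = (
        tuple(stage_labels)
        if stage_labels is not None
        else tuple(a.layer_tag or f"stage {k + 1}" for k, a in enumerate(stages))
    )
    if len(labels) != len(stages):
        raise SizeError("stage_labels length must match stages")
    r_global, r_coarse, r_fine = [], [], []
    for k, acts in enumerate(stages):
        rep = category_rsm(category_mean_patterns(acts))
        if set(rep.names) != set(tax.names):
            raise AlignmentError(
                f"stage {k + 1} ({labels[k]!r}) categories do not match the taxonomy"
            )
        rep = rep.reindex(tax.names)
        res = correspondence_summary(rep, tax, scheme=scheme, method=method)
        r_global.append(res.r_global)
        r_coarse.append(res.r_coarse)
        r_fine.append(res.r_fine_mean)
    return TrajectoryRecord(
        stage_index=tuple(range(1, len(stages) + 1)),
        stage_label=labels,
        r_global=tuple(r_global),
        r_coarse=tuple(r_coarse),
        r_fine_mean=tuple(r_fine),
        performance=tuple(performance) if performance is not None else None,
    )


def plateau_stage(
    series: Sequence[float],
    epsilon: float = 0.05,
    stage_index: Sequence[int] | None = None,
) -> int:
    """First stage whose value is within ``epsilon`` of the final value.

    Returns the 1-based stage index (or the matching entry of
    ``stage_index`` when given). Monotone in ``epsilon``: a larger
    tolerance never yields a later stage.
    """
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise SizeError("plateau_stage needs a non-empty series")
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    idx = (
        tuple(stage_index)
        if stage_index is not None
        else tuple(range(1, values.size + 1))
    )
    if len(idx) != values.size:
        raise SizeError("stage_index length must match series")
    threshold = values[-1] - epsilon
    hit = int(np.argmax(values >= threshold))  # first True; final stage always >=
    return idx[hit]
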