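"""MVC calibration, torque-to-class mapping and train/test splitting.

Effort levels are expressed as fractions of each direction's maximum
voluntary contraction (MVC), measured from maximum-effort trials.  A torque
observation is assigned to the class whose configured level is nearest,
so the boundary between two adjacent classes sits exactly midway between
their levels (e.g. flexion between 15 % and 25 % MVC belongs to the 20 %
class); midpoint ties break toward the lower level, the conservative choice
for an assistive device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    MOVEMENT_DIRECTIONS,
    ClassConfig,
    Direction,
    Excerpt,
    Recording,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MvcCalibration:
    """Per-direction maximum torque magnitude (N·m)."""

    values: Mapping[Direction, float]

    def __post_init__(self) -> None:
        for d in MOVEMENT_DIRECTIONS:
            if self.values.get(d, 0.0) <= 0:
                raise ValueError(f"MVC for {d.value} must be positive and present")

    def __getitem__(self, direction: Direction) -> float:
        return self.values[direction]


def compute_mvc(max_effort_runs: Mapping[Direction, Sequence[Recording]]) -> MvcCalibration:
    """MVC per direction: the maximum absolute torque over all repetitions."""
    values: dict[Direction, float] = {}
    for d in MOVEMENT_DIRECTIONS:
        runs = max_effort_runs.get(d)
        if not runs:
            raise ValueError(f"no maximum-effort runs for direction {d.value!r}")
        values[d] = max(float(np.max(np.abs(r.torque))) for r in runs)
    return MvcCalibration(values=values)


def assign_class(
    direction: Direction,
    torque_fraction: float,
    config: ClassConfig,
) -> int:
    """Class id whose level is nearest ``torque_fraction`` (|torque|/MVC).

    Rest counts as level 0 for every direction; midpoint ties go to the
    lower level.  Total over torque_fraction >= 0.
    """
    if torque_fraction < 0:
        raise ValueError("torque_fraction must be >= 0 (use |torque|/MVC)")
    rest = config.rest_class()
    if direction is Direction.REST:
        return rest.class_id
    candidates = [(0.0, rest.class_id)]
    candidates += [(c.level, c.class_id) for c in config.classes_for(direction)]
    # nearest level; ties broken toward the lower level (candidates are
    # level-sorted, and min() keeps the earliest of equal keys); distances
    # rounded so float noise cannot flip an exact-midpoint tie
    _, best = min(candidates, key=lambda lc: round(abs(lc[0] - torque_fraction), 9))
    return best


def label_excerpts(
    excerpts: Sequence[Excerpt],
    mvc: MvcCalibration,
    config: ClassConfig,
    steadiness_threshold: float = 0.05,
) -> list[Excerpt]:
    """Attach torque-derived class labels to steady excerpts.

    The label is ``assign_class(direction, mean |torque| / MVC)``.  Excerpts
    whose torque standard deviation exceeds ``steadiness_threshold`` × MVC
    are not steady holds (they straddle a ramp) and are excluded with a log
    entry.
    """
    out: list[Excerpt] = []
    for i, ex in enumerate(excerpts):
        if ex.direction is Direction.REST:
            mvc_nm = min(mvc.values[d] for d in MOVEMENT_DIRECTIONS)
        else:
            mvc_nm = mvc[ex.direction]
        torque = ex.recording.torque
        if float(np.std(torque)) > steadiness_threshold * mvc_nm:
            logger.warning(
                "excerpt %d (%s, iteration %d) excluded: torque std %.3g exceeds "
                "steadiness threshold", i, ex.direction.value, ex.iteration,
                float(np.std(torque)),
            )
            continue
        fraction = float(np.mean(np.abs(torque))) / mvc_nm
        cid = assign_class(ex.direction, fraction, config)
        out.append(replace(ex, class_id=cid))
    return out


def train_test_split(
    features: pd.DataFrame,
    per_class_test: int = 30,
    seed: int | None = None,
    random: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out ``per_class_test`` segments per class.

    The default holdout is chronological — the last segments of each class
    in acquisition order — mimicking a train-then-use session; pass
    ``random=True`` (with ``seed``) for a shuffled holdout instead.
    Returns ``(train, test)``; together they partition the input rows.
    """
    if "label" not in features.columns:
        raise ValueError("feature matrix must carry a 'label' column")
    counts = features["label"].value_counts()
    too_small = counts[counts <= per_class_test]
    if per_class_test > 0 and len(too_small):
        raise ValueError(
            f"classes with <= {per_class_test} segments: {dict(too_small)}"
        )
    if per_class_test == 0:
        return features.copy(), features.iloc[0:0].copy()
    test_idx: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for _, group in features.groupby("label", sort=False):
        if random:
            test_idx.append(rng.choice(group.index.to_numpy(), per_class_test, replace=False))
        else:
            test_idx.append(group.index.to_numpy()[-per_class_test:])
    test_index = np.concatenate(test_idx)
    mask = features.index.isin(test_index)
    return features.loc[~mask].copy(), features.loc[mask].copy()
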