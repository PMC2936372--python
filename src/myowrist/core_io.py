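"""Domain types, file readers/writers and run configuration.

The package operates on synchronized recordings of four forearm muscles
(extensor carpi radialis ECR, extensor digitorum ED, palmaris longus PL,
flexor carpi ulnaris FCU) together with the isometric wrist torque measured
by a reaction torque sensor.  One recording covers one movement axis —
flexion/extension or ulnar/radial deviation — because the two axes are
acquired on two separate rigs.

Sign convention (applied consistently everywhere): flexion and ulnar
deviation are positive torque, extension and radial deviation negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DEFAULT_SAMPLE_RATE = 1024.0
#: channel order fixed across the whole package
DEFAULT_CHANNELS: tuple[str, ...] = ("ECR", "ED", "PL", "FCU")


class SchemaError(ValueError):
    """A file or table does not have the expected columns/fields."""


class FormatError(ValueError):
    """A file has the right columns but malformed content."""


class Direction(str, enum.Enum):
    REST = "rest"
    FLEXION = "flexion"
    EXTENSION = "extension"
    ULNAR = "ulnar"
    RADIAL = "radial"


class Axis(str, enum.Enum):
    FLEXION_EXTENSION = "flexion_extension"
    ULNAR_RADIAL = "ulnar_radial"


#: torque sign per direction: flexion/ulnar positive, extension/radial negative
DIRECTION_SIGN: dict[Direction, int] = {
    Direction.REST: 0,
    Direction.FLEXION: +1,
    Direction.EXTENSION: -1,
    Direction.ULNAR: +1,
    Direction.RADIAL: -1,
}

DIRECTION_AXIS: dict[Direction, Axis] = {
    Direction.FLEXION: Axis.FLEXION_EXTENSION,
    Direction.EXTENSION: Axis.FLEXION_EXTENSION,
    Direction.ULNAR: Axis.ULNAR_RADIAL,
    Direction.RADIAL: Axis.ULNAR_RADIAL,
}

MOVEMENT_DIRECTIONS: tuple[Direction, ...] = (
    Direction.FLEXION,
    Direction.EXTENSION,
    Direction.ULNAR,
    Direction.RADIAL,
)

#: highest effort level (fraction of MVC) used per direction
TOP_FRACTION: dict[Direction, float] = {
    Direction.FLEXION: 0.5,
    Direction.EXTENSION: 0.5,
    Direction.ULNAR: 0.4,
    Direction.RADIAL: 0.4,
}


@dataclass
class Recording:
    """Synchronized multichannel sEMG plus one wrist-torque trace.

    Parameters
    ----------
    sample_rate : float
        Samples per second (1024 for the standard acquisition).
    channels : tuple of str
        EMG channel names, ordered; ``emg`` columns follow this order.
    emg : ndarray, shape (n_samples, n_channels)
        EMG in millivolts.
    torque : ndarray, shape (n_samples,)
        Wrist torque in N·m, signed (flexion/ulnar positive).
    axis : Axis
        Which rig (movement axis) the recording comes from.
    metadata : dict
        Free-form provenance: subject/protocol ids, seed, plateau table.
    """

    sample_rate: float
    channels: tuple[str, ...]
    emg: np.ndarray
    torque: np.ndarray
    axis: Axis = Axis.FLEXION_EXTENSION
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        self.channels = tuple(self.channels)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.emg.ndim != 2 or self.emg.shape[1] != len(self.channels):
            raise ValueError(
                f"emg must be (n_samples, {len(self.channels)}), got {self.emg.shape}"
            )
        if self.torque.ndim != 1 or self.torque.shape[0] != self.emg.shape[0]:
            raise ValueError("torque and emg must have equal length")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.emg[:, self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def slice(self, start: int, stop: int, **metadata) -> "Recording":
        """Return a copy restricted to ``[start, stop)`` samples."""
        md = dict(self.metadata)
        md.update(metadata)
        return Recording(
            sample_rate=self.sample_rate,
            channels=self.channels,
            emg=self.emg[start:stop].copy(),
            torque=self.torque[start:stop].copy(),
            axis=self.axis,
            metadata=md,
        )


@dataclass(frozen=True)
class SegmentSpec:
    """Sliding-window parameters: 256-sample (250 ms) windows stepped by
    128 samples (125 ms) at 1024 Hz."""

    window_samples: int = 256
    step_samples: int = 128

    def __post_init__(self) -> None:
        if not (0 < self.step_samples <= self.window_samples):
            raise ValueError(
                f"require 0 < step ({self.step_samples}) <= window ({self.window_samples})"
            )


@dataclass(frozen=True)
class ClassDef:
    class_id: int
    direction: Direction
    level: float  # fraction of MVC, 0 for rest


@dataclass
class ClassConfig:
    """The direction × %MVC class map, either the full nineteen-class
    variant or its thirteen-class reduction, plus (optional) per-direction
    MVC torques used to convert levels to N·m."""

    variant: str
    classes: tuple[ClassDef, ...]
    mvc: dict[Direction, float] | None = None

    def __post_init__(self) -> None:
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class ids")

    @property
    def class_ids(self) -> list[int]:
        return [c.class_id for c in self.classes]

    def by_id(self, class_id: int) -> ClassDef:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(f"no class with id {class_id}")

    def rest_class(self) -> ClassDef:
        for c in self.classes:
            if c.direction is Direction.REST:
                return c
        raise KeyError("no rest class in config")

    def classes_for(self, direction: Direction) -> list[ClassDef]:
        """Movement classes of one direction, sorted by level."""
        out = [c for c in self.classes if c.direction is direction]
        if not out:
            raise KeyError(f"no classes for direction {direction.value!r}")
        return sorted(out, key=lambda c: c.level)

    def lookup(self, direction: Direction, level: float) -> ClassDef:
        """The class with exactly this (direction, level)."""
        if direction is Direction.REST or level == 0:
            return self.rest_class()
        for c in self.classes_for(direction):
            if abs(c.level - level) < 1e-9:
                return c
        raise KeyError(f"no class for {direction.value} at level {level}")

    def with_mvc(self, mvc: Mapping[Direction, float]) -> "ClassConfig":
        return replace(self, mvc=dict(mvc))


#: class ids dropped when collapsing nineteen classes to thirteen
REDUCED_CLASS_IDS: frozenset[int] = frozenset({3, 5, 8, 10, 13, 17})


def _nineteen_classes() -> tuple[ClassDef, ...]:
    out = [ClassDef(1, Direction.REST, 0.0)]
    cid = 2
    for direction in MOVEMENT_DIRECTIONS:
        top = TOP_FRACTION[direction]
        level = 0.1
        while level <= top + 1e-9:
            out.append(ClassDef(cid, direction, round(level, 1)))
            cid += 1
            level += 0.1
    return tuple(out)


def load_class_config(variant: str, mvc: Mapping[Direction, float] | None = None) -> ClassConfig:
    """Build the class map.

    ``variant='nineteen'`` gives rest plus five torque levels (10–50 % MVC)
    for flexion and extension and four (10–40 %) for ulnar and radial
    deviation.  ``variant='thirteen'`` removes every second movement level
    (class ids 3, 5, 8, 10, 13 and 17), leaving classes spaced 20 % MVC
    apart for a smoother accuracy/granularity trade-off.
    """
    full = _nineteen_classes()
    if variant == "nineteen":
        classes = full
    elif variant == "thirteen":
        classes = tuple(c for c in full if c.class_id not in REDUCED_CLASS_IDS)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'nineteen' or 'thirteen'")
    return ClassConfig(variant=variant, classes=classes,
                       mvc=dict(mvc) if mvc is not None else None)


@dataclass
class Excerpt:
    """A steady-state slice of a recording attributed to one class.

    ``class_id`` is the label attached by the generator (the commanded
    plateau) or by the torque-based labeler; ``None`` if not yet labeled.
    """

    recording: Recording
    direction: Direction
    level: float
    iteration: int
    class_id: int | None = None
    source: str = ""


# ---------------------------------------------------------------------------
# Recording file format: CSV with header time,ECR,ED,PL,FCU,torque, preceded
# by one comment line carrying the axis so that round trips are lossless.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingSchema:
    time: str = "time"
    emg: tuple[str, ...] = DEFAULT_CHANNELS
    torque: str = "torque"
    sample_rate: float | None = None  # None: infer from the time column


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Serialize to delimited text; refuses empty or non-finite recordings."""
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty Recording")
    if not (np.isfinite(rec.emg).all() and np.isfinite(rec.torque).all()):
        raise ValueError("refusing to write a Recording containing NaN/inf samples")
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame({"time": t})
    for i, ch in enumerate(rec.channels):
        df[ch] = rec.emg[:, i]
    df["torque"] = rec.torque
    with open(path, "w") as fh:
        fh.write(f"# axis={rec.axis.value} sample_rate={rec.sample_rate:g}\n")
        df.to_csv(fh, index=False)
    return path


def read_recording(
    path: str | Path,
    schema: RecordingSchema | None = None,
    axis: Axis | None = None,
) -> Recording:
    """Read a delimited-text recording.

    The sample rate is inferred from the time column and cross-checked
    against ``schema.sample_rate`` when given (mismatch beyond 1 % is an
    error).  ``axis`` overrides the axis stated in the file's comment line.
    """
    schema = schema or RecordingSchema()
    path = Path(path)
    header_axis, header_rate = _parse_header_comment(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed delimited text ({exc})") from exc

    wanted = [schema.time, *schema.emg, schema.torque]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df[wanted].isna().any().any():
        raise FormatError(f"{path}: ragged rows / missing values")

    t = df[schema.time].to_numpy(float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    inferred = 1.0 / float(np.median(dt))
    declared = schema.sample_rate if schema.sample_rate is not None else header_rate
    if declared is not None and abs(inferred - declared) / declared > 0.01:
        raise FormatError(
            f"{path}: time column implies {inferred:.6g} Hz but schema says {declared:g} Hz"
        )
    rate = declared if declared is not None else inferred

    emg = df[list(schema.emg)].to_numpy(float)
    torque = df[schema.torque].to_numpy(float)
    rec_axis = axis or header_axis or Axis.FLEXION_EXTENSION
    return Recording(
        sample_rate=float(rate),
        channels=schema.emg,
        emg=emg,
        torque=torque,
        axis=rec_axis,
        metadata={"path": str(path)},
    )


def _parse_header_comment(path: Path) -> tuple[Axis | None, float | None]:
    with open(path) as fh:
        first = fh.readline()
    axis = rate = None
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("axis="):
                try:
                    axis = Axis(token.split("=", 1)[1])
                except ValueError:
                    pass
            elif token.startswith("sample_rate="):
                rate = float(token.split("=", 1)[1])
    return axis, rate


# ---------------------------------------------------------------------------
# Run configuration (YAML/JSON): windowing, class variant, grid, seeds.
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    segment: SegmentSpec = field(default_factory=SegmentSpec)
    variant: str = "nineteen"
    iterations_per_class: int = 6
    seed: int = 0
    c_grid: tuple[float, ...] | None = None
    gamma_grid: tuple[float, ...] | None = None
    folds: int = 8


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seg = raw.get("segment", {})
    cfg = RunConfig(
        segment=SegmentSpec(
            window_samples=int(seg.get("window_samples", 256)),
            step_samples=int(seg.get("step_samples", 128)),
        ),
        variant=str(raw.get("variant", "nineteen")),
        iterations_per_class=int(raw.get("iterations_per_class", 6)),
        seed=int(raw.get("seed", 0)),
        folds=int(raw.get("folds", 8)),
    )
    if "c_grid" in raw:
        cfg.c_grid = tuple(float(v) for v in raw["c_grid"])
    if "gamma_grid" in raw:
        cfg.gamma_grid = tuple(float(v) for v in raw["gamma_grid"])
    return cfg
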