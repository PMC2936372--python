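"""Protocol-driven synthetic sEMG + torque generator.

The generator emulates the stepped isometric torque protocols used to
collect training data for torque-level classification: the subject holds
0, 10, 20, ... % of their maximum voluntary contraction (MVC) for 10 s per
step, ascending to 50 % MVC for flexion/extension (40 % for the deviations)
and back down, three repetitions each, on two rigs (one per movement axis).

The sEMG surrogate is amplitude-modulated band-limited (20–500 Hz)
Gaussian noise: every feature the downstream classifier uses (rms, AR
coefficients, waveform length) is an amplitude or spectral-shape statistic,
so this minimal model carries exactly the structure the pipeline assumes.
Per-muscle amplitude follows a direction-specific activation map built from
the muscles' anatomical roles: PL and FCU drive flexion, ED and ECR drive
extension, FCU dominates ulnar deviation and ECR radial deviation.

Imperfect effort tracking — the subject wavering around the commanded
torque level — is modeled as a slow Gaussian drift added to the commanded
level fraction and shared between the torque trace and the EMG envelopes.
This drift is what makes windows near class boundaries genuinely ambiguous
and produces the adjacent-level confusion pattern seen in practice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage, signal

from .core_io import (
    DEFAULT_CHANNELS,
    DEFAULT_SAMPLE_RATE,
    DIRECTION_AXIS,
    DIRECTION_SIGN,
    MOVEMENT_DIRECTIONS,
    TOP_FRACTION,
    Axis,
    ClassConfig,
    Direction,
    Excerpt,
    Recording,
)

__all__ = [
    "ActivationMap",
    "ProtocolSpec",
    "ProtocolMode",
    "DEFAULT_MVC_NM",
    "synth_emg_block",
    "synth_protocol_run",
    "synth_mvc_session",
    "synth_study",
]

#: plausible maximum wrist torques (N·m) per direction; wrist flexion is the
#: strongest action, the deviations the weakest.
DEFAULT_MVC_NM: dict[Direction, float] = {
    Direction.FLEXION: 10.0,
    Direction.EXTENSION: 7.0,
    Direction.ULNAR: 6.0,
    Direction.RADIAL: 5.0,
}

_EMG_BAND_HZ = (20.0, 500.0)
_FIR_TAPS = 257


class ProtocolMode(str, enum.Enum):
    MAX_EFFORT = "max_effort"
    ASCENDING_STEPS = "ascending_steps"
    DESCENDING_STEPS = "descending_steps"


@dataclass(frozen=True)
class ActivationMap:
    """Maps (direction, effort level) to per-muscle activation in [0, 1].

    ``weights[direction]`` holds each muscle's activation at the direction's
    top effort level; activation scales linearly with level/top_fraction and
    is clipped to [0, 1].  Default weights follow the anatomical roles:
    primary mover 1.0, main synergist 0.6, the remaining muscles 0.1 —
    strong enough separation between directions for classification while
    adjacent levels of one direction stay close.

    ``baseline_noise_mv`` is the resting EMG amplitude (electrode/thermal
    noise floor); ``gain_mv`` the extra amplitude at full activation.
    """

    weights: Mapping[Direction, Mapping[str, float]] = field(
        default_factory=lambda: {
            Direction.FLEXION: {"PL": 1.0, "FCU": 0.6, "ED": 0.1, "ECR": 0.1},
            Direction.EXTENSION: {"ED": 1.0, "ECR": 0.6, "PL": 0.1, "FCU": 0.1},
            Direction.ULNAR: {"FCU": 1.0, "PL": 0.6, "ED": 0.1, "ECR": 0.1},
            Direction.RADIAL: {"ECR": 1.0, "ED": 0.6, "PL": 0.1, "FCU": 0.1},
        }
    )
    baseline_noise_mv: float = 0.01
    gain_mv: float = 1.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def channel_weights(self, direction: Direction) -> np.ndarray:
        """Top-effort weights in channel order; zeros at rest."""
        if direction is Direction.REST:
            return np.zeros(len(self.channels))
        w = self.weights[direction]
        return np.array([w.get(ch, 0.0) for ch in self.channels])

    def activation(self, direction: Direction, level: float) -> np.ndarray:
        """Per-muscle activation fraction at ``level`` (fraction of MVC)."""
        if direction is Direction.REST or level <= 0:
            return np.zeros(len(self.channels))
        top = TOP_FRACTION[direction]
        return np.clip(self.channel_weights(direction) * (level / top), 0.0, 1.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """One acquisition protocol: a stepped (or maximum-effort) torque hold."""

    direction: Direction
    mode: ProtocolMode = ProtocolMode.ASCENDING_STEPS
    step_fraction: float = 0.1
    hold_seconds: float = 10.0
    top_fraction: float | None = None  # default: direction's standard top
    repetitions: int = 3
    ramp_seconds: float = 1.0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        top = self.resolved_top
        if not (0 < top <= 1):
            raise ValueError(f"top_fraction must lie in (0, 1], got {top}")

    @property
    def resolved_top(self) -> float:
        if self.top_fraction is not None:
            return self.top_fraction
        return TOP_FRACTION[self.direction]

    def plateau_levels(self) -> list[float]:
        """Commanded MVC fractions of the successive holds."""
        if self.mode is ProtocolMode.MAX_EFFORT:
            return [1.0]
        n = int(round(self.resolved_top / self.step_fraction))
        ascending = [round(i * self.step_fraction, 10) for i in range(n + 1)]
        if self.mode is ProtocolMode.ASCENDING_STEPS:
            return ascending
        return ascending[::-1]


def _bandlimited_carrier(n: int, sample_rate: float, rng: np.random.Generator,
                         n_channels: int = 4) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the sEMG energy band.

    White noise filtered by a linear-phase FIR bandpass; the output is
    rescaled by the exact white-noise gain sqrt(sum h^2) so the sample
    standard deviation is an unbiased estimate of 1.
    """
    low, high = _EMG_BAND_HZ
    high = min(high, 0.999 * sample_rate / 2)
    taps = signal.firwin(_FIR_TAPS, [low, high], pass_zero=False, fs=sample_rate)
    white = rng.standard_normal((n + _FIR_TAPS - 1, n_channels))
    out = signal.fftconvolve(white, taps[:, None], mode="valid", axes=0)
    return out / np.sqrt(np.sum(taps**2))


def synth_emg_block(
    activation: Sequence[float],
    duration_s: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.SeedSequence | None = 0,
    baseline_noise_mv: float = 0.01,
    gain_mv: float = 1.0,
) -> np.ndarray:
    """Generate one constant-activation EMG block.

    Each channel is zero-mean 20–500 Hz Gaussian noise with standard
    deviation ``baseline_noise_mv + gain_mv * activation`` (mV).  Identical
    seeds give bit-identical blocks.

    Returns an ``(n_samples, n_channels)`` array.
    """
    act = np.asarray(activation, dtype=float)
    if np.any(act < 0) or np.any(act > 1):
        raise ValueError(f"activation must lie in [0, 1], got {act}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * sample_rate))
    rng = np.random.default_rng(seed)
    carrier = _bandlimited_carrier(n, sample_rate, rng, n_channels=act.size)
    std = baseline_noise_mv + gain_mv * act
    return carrier * std[None, :]


def _tracking_drift(n: int, sample_rate: float, rng: np.random.Generator,
                    std: float, tau_s: float) -> np.ndarray:
    """Slow zero-mean Gaussian drift (fraction of MVC) modeling imperfect
    effort tracking; Gaussian-smoothed white noise renormalized to ``std``."""
    if std <= 0:
        return np.zeros(n)
    sigma = tau_s * sample_rate
    raw = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")
    # white noise through a gaussian kernel of scale sigma has std ~ (4*pi*sigma^2)^-1/4
    gain = (4 * np.pi * sigma**2) ** -0.25
    return raw * (std / gain)


def synth_protocol_run(
    protocol: ProtocolSpec,
    amap: ActivationMap,
    mvc_nm: float,
    seed: int | np.random.SeedSequence | None = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    tracking_drift_std: float = 0.02,
    tracking_drift_tau_s: float = 2.0,
    torque_sensor_noise_nm: float | None = None,
) -> Recording:
    """Simulate one protocol repetition as a full Recording.

    The commanded level profile is a staircase of ``hold_seconds`` plateaus
    joined by linear ramps of ``ramp_seconds``.  The subject's effective
    effort is the commanded level plus slow tracking drift
    (``tracking_drift_std``, fraction of MVC, correlation time
    ``tracking_drift_tau_s``); it drives both the torque trace and the EMG
    envelopes, so torque and muscle activity waver together.  The torque
    sensor adds white noise (default 1 % of MVC).  Plateau boundaries are
    recorded in ``metadata['plateaus']`` as (start, stop, level) tuples.
    """
    rng = np.random.default_rng(seed)
    levels = protocol.plateau_levels()
    hold_n = int(round(protocol.hold_seconds * sample_rate))
    ramp_n = int(round(protocol.ramp_seconds * sample_rate))

    pieces: list[np.ndarray] = []
    plateaus: list[tuple[int, int, float]] = []
    pos = 0
    for i, lev in enumerate(levels):
        if i > 0 and ramp_n > 0:
            pieces.append(np.linspace(levels[i - 1], lev, ramp_n, endpoint=False))
            pos += ramp_n
        pieces.append(np.full(hold_n, lev))
        plateaus.append((pos, pos + hold_n, lev))
        pos += hold_n
    commanded = np.concatenate(pieces)
    n = commanded.size

    drift = _tracking_drift(n, sample_rate, rng, tracking_drift_std, tracking_drift_tau_s)
    effective = np.clip(commanded + drift, 0.0, 1.0)

    sign = DIRECTION_SIGN[protocol.direction]
    sensor_std = torque_sensor_noise_nm if torque_sensor_noise_nm is not None else 0.01 * mvc_nm
    torque = sign * effective * mvc_nm + rng.normal(0.0, sensor_std, n)

    top = protocol.resolved_top
    weights = amap.channel_weights(protocol.direction)
    activation = np.clip(effective[:, None] * (weights[None, :] / top), 0.0, 1.0)
    envelope = amap.baseline_noise_mv + amap.gain_mv * activation
    emg = _bandlimited_carrier(n, sample_rate, rng, n_channels=len(amap.channels)) * envelope

    return Recording(
        sample_rate=sample_rate,
        channels=amap.channels,
        emg=emg,
        torque=torque,
        axis=DIRECTION_AXIS[protocol.direction],
        metadata={
            "direction": protocol.direction.value,
            "mode": protocol.mode.value,
            "mvc_nm": mvc_nm,
            "plateaus": plateaus,
            "commanded_levels": levels,
        },
    )


def synth_mvc_session(
    amap: ActivationMap,
    mvc_nm: Mapping[Direction, float] | None = None,
    repetitions: int = 3,
    hold_seconds: float = 5.0,
    seed: int = 0,
) -> dict[Direction, list[Recording]]:
    """Maximum-effort calibration trials: ``repetitions`` max-torque holds
    per movement direction, for MVC estimation."""
    mvc_nm = dict(mvc_nm or DEFAULT_MVC_NM)
    root = np.random.SeedSequence(seed)
    out: dict[Direction, list[Recording]] = {}
    for direction, child in zip(MOVEMENT_DIRECTIONS, root.spawn(len(MOVEMENT_DIRECTIONS))):
        spec = ProtocolSpec(direction=direction, mode=ProtocolMode.MAX_EFFORT,
                            hold_seconds=hold_seconds, repetitions=repetitions)
        out[direction] = [
            synth_protocol_run(spec, amap, mvc_nm[direction], seed=s)
            for s in child.spawn(repetitions)
        ]
    return out


def synth_study(
    amap: ActivationMap,
    class_config: ClassConfig,
    iterations_per_class: int = 6,
    hold_extract_s: float = 6.0,
    seed: int = 0,
    mvc_nm: Mapping[Direction, float] | None = None,
    hold_seconds: float = 10.0,
    **run_kwargs,
) -> list[Excerpt]:
    """Generate the full labeled study: steady-state excerpts for every class.

    For each movement direction, ascending and descending staircase runs are
    simulated in alternation (3 repetitions of each for the default six
    iterations per class, mirroring an acquisition session of one ascending
    and one descending protocol per direction, three repetitions each).  The
    central ``hold_extract_s`` seconds of every plateau become one excerpt
    tagged with the commanded class.  Rest excerpts are taken from the rest
    plateaus of the flexion-axis runs.

    Returns the excerpts ordered by class id, then iteration.
    """
    if iterations_per_class < 1:
        raise ValueError("iterations_per_class must be >= 1")
    if hold_extract_s > hold_seconds:
        raise ValueError(
            f"cannot extract {hold_extract_s} s from {hold_seconds} s holds"
        )
    mvc_nm = dict(mvc_nm or DEFAULT_MVC_NM)
    root = np.random.SeedSequence(seed)

    n_runs_per_dir = int(np.ceil(iterations_per_class / 2)) * 2  # asc/desc pairs
    per_class: dict[int, list[Excerpt]] = {c.class_id: [] for c in class_config.classes}
    rest_id = class_config.rest_class().class_id

    dir_seeds = root.spawn(len(MOVEMENT_DIRECTIONS))
    for direction, dseed in zip(MOVEMENT_DIRECTIONS, dir_seeds):
        run_seeds = dseed.spawn(n_runs_per_dir)
        for run_idx, rseed in enumerate(run_seeds):
            mode = (ProtocolMode.ASCENDING_STEPS if run_idx % 2 == 0
                    else ProtocolMode.DESCENDING_STEPS)
            spec = ProtocolSpec(direction=direction, mode=mode, hold_seconds=hold_seconds)
            rec = synth_protocol_run(spec, amap, mvc_nm[direction], seed=rseed, **run_kwargs)
            source = f"{direction.value}/{mode.value}/rep{run_idx // 2}"
            for start, stop, level in rec.metadata["plateaus"]:
                if level == 0.0:
                    if direction is not Direction.FLEXION:
                        continue  # rest excerpts come from one rig only
                    cid = rest_id
                    cdir = Direction.REST
                else:
                    try:
                        cid = class_config.lookup(direction, level).class_id
                    except KeyError:
                        cid = None  # level dropped in the reduced variant
                    cdir = direction
                if cid is None or len(per_class[cid]) >= iterations_per_class:
                    continue
                extract_n = int(round(hold_extract_s * rec.sample_rate))
                mid = (start + stop) // 2
                lo = mid - extract_n // 2
                excerpt = rec.slice(
                    lo, lo + extract_n,
                    class_id=cid, level=level, source=source, source_start=lo,
                )
                per_class[cid].append(
                    Excerpt(
                        recording=excerpt,
                        direction=cdir,
                        level=level,
                        iteration=len(per_class[cid]),
                        class_id=cid,
                        source=source,
                    )
                )

    short = {cid: len(v) for cid, v in per_class.items() if len(v) < iterations_per_class}
    if short:
        raise RuntimeError(f"could not fill all classes: {short}")
    out: list[Excerpt] = []
    for cid in class_config.class_ids:
        out.extend(per_class[cid])
    return out
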