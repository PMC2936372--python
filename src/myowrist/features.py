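"""Sliding-window segmentation and time-domain sEMG features.

Each EMG channel is cut into 256-sample (250 ms) windows stepped by 128
samples (125 ms), and three feature families are computed per window:

* root-mean-square amplitude  r = sqrt(mean(x_i^2)) — contraction intensity;
* autoregressive model coefficients a_1..a_4 of the predictor
  y(t) = sum_i a_i y(t-i) + e(t), estimated by the Burg method — spectral
  shape, robust on short windows;
* waveform length  l = sum |x_k - x_{k-1}| — cumulative complexity.

Four channels × (1 + 4 + 1) features give the 24-dimensional feature vector
used by the classifier.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import burg as _burg

from .core_io import DEFAULT_CHANNELS, Excerpt, SegmentSpec

logger = logging.getLogger(__name__)

AR_ORDER = 4
#: per-channel feature names, in order
CHANNEL_FEATURES = ("rms", "a1", "a2", "a3", "a4", "wl")


class DegenerateSegmentError(ValueError):
    """The segment is constant (or too short) and has no AR representation."""


def feature_columns(channels: Sequence[str] = DEFAULT_CHANNELS) -> list[str]:
    """The 24 feature-column names: per channel, rms then a1..a4 then wl."""
    return [f"{ch}_{feat}" for ch in channels for feat in CHANNEL_FEATURES]


def segment_starts(n_samples: int, spec: SegmentSpec = SegmentSpec()) -> np.ndarray:
    """Start offsets of all full windows; trailing partial windows dropped.

    ``floor((n - window)/step) + 1`` starts when ``n >= window``, else none.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if n_samples < spec.window_samples:
        return np.empty(0, dtype=int)
    count = (n_samples - spec.window_samples) // spec.step_samples + 1
    return np.arange(count) * spec.step_samples


def rms(segment: np.ndarray) -> float:
    """Root-mean-square amplitude of one window."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    return float(np.sqrt(np.mean(x**2)))


def waveform_length(segment: np.ndarray) -> float:
    """Sum of absolute consecutive sample differences."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    return float(np.sum(np.abs(np.diff(x))))


def ar_coefficients(segment: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Burg-method AR coefficients a_1..a_order (predictor sign convention:
    positive coefficients predict from past values).

    Raises :class:`DegenerateSegmentError` for constant or too-short
    segments, which carry no spectral information.
    """
    x = np.asarray(segment, dtype=float)
    if x.size <= order:
        raise DegenerateSegmentError(
            f"segment of {x.size} samples cannot support AR({order})"
        )
    if np.ptp(x) == 0:
        raise DegenerateSegmentError("constant segment has no AR representation")
    coeffs, _sigma2 = _burg(x, order=order, demean=True)
    if not np.all(np.isfinite(coeffs)):
        raise DegenerateSegmentError("AR estimation did not converge to finite values")
    return np.asarray(coeffs, dtype=float)


def window_features(
    window: np.ndarray,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    ar_order: int = AR_ORDER,
) -> np.ndarray:
    """The 24-vector for one multichannel window of shape (n, n_channels).

    Degenerate (constant) channels get zeros for the AR features — rms and
    waveform length are still well defined — so that streaming pipelines
    survive silent channels; a warning is logged.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != len(channels):
        raise ValueError(f"window must be (n, {len(channels)}), got {window.shape}")
    out = np.empty(len(channels) * len(CHANNEL_FEATURES))
    for c, ch in enumerate(channels):
        x = window[:, c]
        base = c * len(CHANNEL_FEATURES)
        out[base] = rms(x)
        try:
            out[base + 1 : base + 1 + ar_order] = ar_coefficients(x, ar_order)
        except DegenerateSegmentError:
            logger.warning("degenerate window on channel %s: AR features set to 0", ch)
            out[base + 1 : base + 1 + ar_order] = 0.0
        out[base + 5] = waveform_length(x)
    return out


def build_feature_matrix(
    excerpts: Sequence[Excerpt],
    spec: SegmentSpec = SegmentSpec(),
) -> pd.DataFrame:
    """Feature matrix over all excerpts: one row per window position.

    Windows are aligned across the four channels; each row carries the 24
    ordered features plus ``label`` (the excerpt's class id), ``source`` and
    ``start_sample`` provenance columns.
    """
    if not excerpts:
        raise ValueError("no excerpts given")
    channels = excerpts[0].recording.channels
    cols = feature_columns(channels)
    rows: list[np.ndarray] = []
    labels: list[int | None] = []
    sources: list[str] = []
    starts: list[int] = []
    for i, ex in enumerate(excerpts):
        rec = ex.recording
        if rec.channels != channels:
            raise ValueError(
                f"excerpt {i}: channels {rec.channels} != {channels}"
            )
        for s in segment_starts(rec.n_samples, spec):
            rows.append(window_features(rec.emg[s : s + spec.window_samples], channels))
            labels.append(ex.class_id)
            sources.append(ex.source or f"excerpt{i}")
            starts.append(int(s))
    df = pd.DataFrame(np.vstack(rows), columns=cols)
    df["label"] = labels
    df["source"] = sources
    df["start_sample"] = starts
    return df
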