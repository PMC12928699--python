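"""Deterministic epoch conditioning.

Average re-referencing, stimulus-locked segmentation with a half-open
window, anti-aliased integer-factor down-sampling, zero-phase high-pass
filtering, and the gaze-based trial exclusion rule (trials with gaze
deviating more than 3.75 degrees from fixation are dropped).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .io import EpochSet

__all__ = [
    "rereference_average",
    "segment_epochs",
    "downsample",
    "highpass",
    "exclude_eye_trials",
]

logger = logging.getLogger(__name__)

EYE_EXCLUSION_THRESHOLD_DEG = 3.75


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the average of all sensors (common-mode rejection).

    After re-referencing the sensor mean is zero at every trial and sample.
    Idempotent; requires at least two sensors.
    """
    if epochs.n_sensors < 2:
        raise ValueError("average re-referencing requires >= 2 sensors")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data, labels=epochs.labels.copy())


def segment_epochs(
    continuous: np.ndarray,
    sample_rate: float,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-0.1, 0.5),
    labels: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous recording.

    ``continuous`` is (sensors, samples).  The epoch window is half-open,
    ``[t0, t1)``: at 512 Hz the default window of [-0.1, 0.5) yields 307
    samples.  The sample at time 0 is the first sample at or after each
    onset.  Onsets too close to a recording edge are dropped with a warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    t0, t1 = window_s
    n_samp = int(np.floor((t1 - t0) * sample_rate))
    off0 = int(np.round(t0 * sample_rate))
    n_total = continuous.shape[1]
    onsets_s = np.asarray(onsets_s, dtype=float)
    starts = np.ceil(onsets_s * sample_rate - 1e-9).astype(int) + off0
    ok = (starts >= 0) & (starts + n_samp <= n_total)
    if not np.all(ok):
        logger.warning("dropping %d onset(s) too close to the recording edge",
                       int((~ok).sum()))
    starts = starts[ok]
    data = np.stack([continuous[:, s : s + n_samp] for s in starts]) if starts.size else (
        np.empty((0, continuous.shape[0], n_samp))
    )
    times = t0 + np.arange(n_samp) / sample_rate
    if labels is None:
        labels = pd.DataFrame({"onset_s": onsets_s[ok]})
    else:
        labels = labels.iloc[np.flatnonzero(ok)].reset_index(drop=True)
    return EpochSet(data=data, times=times, sample_rate=sample_rate, labels=labels)


def downsample(epochs: EpochSet, factor: int) -> EpochSet:
    """Anti-alias low-pass then decimate by an integer factor."""
    if factor != int(factor) or factor < 1:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(epochs, labels=epochs.labels.copy())
    data = sp_signal.decimate(epochs.data, factor, axis=2, ftype="fir", zero_phase=True)
    return replace(
        epochs,
        data=data,
        times=epochs.times[::factor],
        sample_rate=epochs.sample_rate / factor,
        labels=epochs.labels.copy(),
    )


def highpass(
    data: np.ndarray | EpochSet,
    cutoff_hz: float = 0.25,
    sample_rate: float | None = None,
    order: int = 2,
):
    """Zero-phase Butterworth high-pass (forward-backward filtering).

    Removes DC and slow drifts without shifting stimulus-locked latencies.
    Accepts an :class:`EpochSet` (filtered along time) or a raw array whose
    last axis is time (``sample_rate`` then required).
    """
    if isinstance(data, EpochSet):
        out = highpass(data.data, cutoff_hz, data.sample_rate, order)
        return replace(data, data=out, labels=data.labels.copy())
    if sample_rate is None:
        raise ValueError("sample_rate required for raw-array input")
    nyq = sample_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = sp_signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def exclude_eye_trials(
    epochs: EpochSet,
    gaze: np.ndarray,
    threshold_deg: float = EYE_EXCLUSION_THRESHOLD_DEG,
) -> tuple[EpochSet, pd.DataFrame]:
    """Flag trials whose gaze deviates beyond ``threshold_deg`` from fixation.

    ``gaze`` is (trials, 2, samples) in degrees; the deviation metric is the
    Euclidean distance of 2-D gaze from fixation, maximised over the whole
    epoch.  Returns the epochs with updated ``kept`` flags plus a
    per-condition exclusion report.
    """
    gaze = np.asarray(gaze, dtype=float)
    if gaze.ndim != 3 or gaze.shape[0] != epochs.n_trials or gaze.shape[1] != 2:
        raise ValueError(
            f"gaze shape {gaze.shape} does not match {epochs.n_trials} trials of 2-D traces"
        )
    deviation = np.sqrt(gaze[:, 0] ** 2 + gaze[:, 1] ** 2).max(axis=1)
    keep = deviation <= threshold_deg
    labels = epochs.labels.copy()
    labels["kept"] = labels["kept"].to_numpy(dtype=bool) & keep
    labels["max_gaze_deviation_deg"] = deviation
    out = replace(epochs, labels=labels)
    if "condition" in labels.columns:
        report = (
            labels.groupby("condition", sort=True)["kept"]
            .agg(n_total="size", n_kept="sum")
            .reset_index()
        )
    else:
        report = pd.DataFrame(
            {"condition": ["all"], "n_total": [len(labels)], "n_kept": [int(keep.sum())]}
        )
    report["n_excluded"] = report["n_total"] - report["n_kept"]
    return out, report
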