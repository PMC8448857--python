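"""Artifact interpolation, downsampling, and epoching of raw TMS-EEG.

The pipeline mirrors standard concurrent TMS-EEG practice: the pulse
spike artifact (typically 4-10 ms) is excised by replacing every sample
from 1 ms before to 13 ms after each pulse with shape-preserving
piecewise-cubic Hermite (PCHIP, Fritsch-Carlson) interpolation through
the surrounding clean samples; the cleaned recording is low-pass filtered
and decimated to the analysis rate (100 Hz); finally the continuous data
are cut into epochs spanning 300 ms before to 900 ms after the pre-cue
onset.  The identical procedure is applied to sham trials using their
virtual pulse times, so no processing step can differ between conditions.

Window endpoints are closed on both sides at the native rate: at 2500 Hz
a [-1, +13] ms window spans exactly 36 samples.  No re-referencing is
performed anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

#: Artifact replacement window around each pulse, ms (closed interval).
ARTIFACT_WINDOW: tuple[float, float] = (-1.0, 13.0)

_TIME_EPS = 1e-6  # ms; guards float comparisons on the sample grid


@dataclass
class RawRecording:
    """Continuous multi-channel recording.

    ``data`` is (n_channels, n_samples) in microvolt; ``times`` is the
    sample grid in ms (uniform, ascending); ``fs`` in Hz.  Event times
    (cue onsets, pulse times) are carried in ms on the same clock.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    ch_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[1] != self.times.size:
            raise ValueError("times length must match the sample axis")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match the channel axis")


@dataclass
class EpochSet:
    """Epoched data: (n_trials, n_channels, n_samples), t=0 at pre-cue onset.

    ``trial_info`` carries one row per trial (condition labels and pulse
    times p1..p4 in ms); all trials share ``times`` and channel order.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    ch_names: tuple[str, ...]
    trial_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[2] != np.asarray(self.times).size:
            raise ValueError("times length must match the sample axis")
        if len(self.trial_info) not in (0, self.data.shape[0]):
            raise ValueError("trial_info must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask or index array."""
        info = (
            self.trial_info.iloc[np.asarray(mask)].reset_index(drop=True)
            if len(self.trial_info)
            else self.trial_info
        )
        return EpochSet(self.data[mask], self.times, self.fs, self.ch_names, info)


def artifact_mask(times: np.ndarray, pulse_times_ms: np.ndarray) -> np.ndarray:
    """Boolean mask of samples inside any closed [-1, +13] ms pulse window."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.size, dtype=bool)
    lo, hi = ARTIFACT_WINDOW
    for tp in np.atleast_1d(pulse_times_ms):
        mask |= (times >= tp + lo - _TIME_EPS) & (times <= tp + hi + _TIME_EPS)
    return mask


def interpolate_artifacts(
    raw: RawRecording, pulse_times_ms: np.ndarray | list[float]
) -> RawRecording:
    """Replace pulse-artifact windows with PCHIP-interpolated data.

    Every sample whose time lies in the closed interval
    ``[t_p - 1 ms, t_p + 13 ms]`` around any pulse is replaced by
    monotone shape-preserving piecewise-cubic interpolation anchored on
    the remaining clean samples; all other samples are returned
    bit-identical.  Applied identically regardless of active/sham.
    """
    pulses = np.sort(np.atleast_1d(np.asarray(pulse_times_ms, dtype=float)))
    if pulses.size == 0:
        return replace(raw, data=raw.data.copy())
    lo, hi = ARTIFACT_WINDOW
    if pulses[0] + lo < raw.times[0] - _TIME_EPS or (
        pulses[-1] + hi > raw.times[-1] + _TIME_EPS
    ):
        raise ValueError("artifact window extends beyond the recording")
    if np.any(np.diff(pulses) < (hi - lo)):
        raise ValueError("artifact windows overlap; pulses too close")

    mask = artifact_mask(raw.times, pulses)
    out = raw.data.copy()
    # PCHIP slopes are local, so fitting through all clean samples is
    # equivalent to interpolating each window from its neighbors.
    interp = PchipInterpolator(raw.times[~mask], raw.data[:, ~mask], axis=1)
    out[:, mask] = interp(raw.times[mask])
    return replace(raw, data=out)


def downsample(raw: RawRecording, target_fs: float) -> RawRecording:
    """Anti-alias low-pass then decimate to ``target_fs``.

    The filter is an 8th-order zero-phase Butterworth with cutoff at
    ``0.4 * target_fs`` (40 Hz for the standard 100 Hz analysis rate);
    the decimation factor must be an integer.  Event times stay in ms on
    the original clock (the decimated ``times`` grid keeps its origin).
    """
    ratio = raw.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"target_fs {target_fs} must divide fs {raw.fs}")
    if q == 1:
        return replace(raw, data=raw.data.copy())
    sos = butter(8, 0.4 * target_fs, btype="low", fs=raw.fs, output="sos")
    filtered = sosfiltfilt(sos, raw.data, axis=1)
    return RawRecording(
        filtered[:, ::q], raw.times[::q], target_fs, raw.ch_names
    )


def epoch(
    raw: RawRecording,
    cue_onsets_ms: np.ndarray | list[float],
    window: tuple[float, float] = (-300.0, 900.0),
    trial_info: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut the recording into per-cue epochs with t=0 at cue onset.

    The sample convention is half-open ``[start, end)``: a [-300, 900) ms
    window at 100 Hz yields 120 samples with sample 30 at t=0.  Cues whose
    window falls outside the recording are skipped with a warning.
    """
    w0, w1 = window
    n = int(round((w1 - w0) * raw.fs / 1000.0))
    dt = 1000.0 / raw.fs
    rel_times = w0 + np.arange(n) * dt

    trials, kept = [], []
    for k, cue in enumerate(np.atleast_1d(np.asarray(cue_onsets_ms, dtype=float))):
        start = cue + w0
        i0 = int(round((start - raw.times[0]) / dt))
        if i0 < 0 or i0 + n > raw.times.size or (
            abs(raw.times[i0] - start) > dt / 2.0
        ):
            warnings.warn(
                f"cue at {cue:.1f} ms: epoch window outside recording; "
                "trial skipped",
                stacklevel=2,
            )
            continue
        trials.append(raw.data[:, i0 : i0 + n])
        kept.append(k)

    data = np.stack(trials) if trials else np.empty((0, raw.data.shape[0], n))
    info = (
        trial_info.iloc[kept].reset_index(drop=True)
        if trial_info is not None
        else pd.DataFrame(index=range(len(kept)))
    )
    return EpochSet(data, rel_times, raw.fs, raw.ch_names, info)
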