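"""Morlet time-frequency decomposition and phase-locked signatures.

Two phase-locked indices quantify entrainment:

* evoked oscillation amplitude — the waveforms are averaged across
  trials first and the average is wavelet-transformed; amplitude is the
  modulus of the complex coefficient (square root of power).  Activity
  that is not phase-locked across trials cancels in the average.
* inter-trial phase coherence (ITPC, phase-locking value) — each trial
  is transformed separately and the per-trial phases theta are combined
  as ``|sum_i exp(1j*theta_i) / N|``: 0 for random phases, 1 for perfect
  alignment.

The wavelets are complex Morlets with c cycles (default 5):
``w(t) = exp(-t**2 / (2*sigma_t**2)) * exp(2j*pi*f*t)`` with
``sigma_t = c / (2*pi*f)``.  The closed-form resolution trade-off is
``FWHM_time = c*sqrt(2*ln 2)/(pi*f)`` seconds and
``FWHM_freq = 2*sqrt(2*ln 2)*f/c`` Hz — 0.19 s and 4.71 Hz at 10 Hz with
c = 5.  Kernels are normalized to unit gain: a unit-amplitude sinusoid
at a center frequency yields amplitude 1.0 there, so amplitude maps read
in microvolt.  No padding is applied; coefficients within 2.5 envelope
SDs of an epoch edge are flagged invalid and excluded from statistics
(beyond that margin the envelope weight falling outside the epoch is
under ~4% of peak).

Phase convention: for ``x(t) = cos(2*pi*f*(t - t0))`` the coefficient at
time t has phase ``2*pi*f*(t - t0)`` wrapped to [-pi, pi) — the angle of
the positive-frequency analytic component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, welch

from .preprocess import EpochSet, RawRecording

_LN2 = np.log(2.0)


def _half_max_width(x: np.ndarray, y: np.ndarray) -> float:
    """Width of the half-maximum region of a unimodal profile.

    Crossings are located by linear interpolation between samples, so the
    estimate is not limited to the grid resolution.
    """
    i = int(np.argmax(y))
    h = y[i] / 2.0
    j = i
    while j > 0 and y[j] > h:
        j -= 1
    left = x[j] + (x[j + 1] - x[j]) * (h - y[j]) / (y[j + 1] - y[j])
    j = i
    while j < y.size - 1 and y[j] > h:
        j += 1
    right = x[j - 1] + (x[j] - x[j - 1]) * (h - y[j - 1]) / (y[j] - y[j - 1])
    return float(right - left)


def measured_kernel_fwhms(
    bank: "WaveletBank", freq: float, fs: float = 10_000.0, n_fft: int = 2**18
) -> tuple[float, float]:
    """Measure (temporal, spectral) FWHM of an implemented kernel.

    The temporal width is read off the amplitude envelope; the spectral
    width off the zero-padded FFT magnitude.  Should agree with the
    closed forms :func:`fwhm_time` / :func:`fwhm_freq`.
    """
    k = bank.kernel(freq, fs)
    t = (np.arange(k.size) - k.size // 2) / fs
    width_t = _half_max_width(t, np.abs(k))
    spec = np.abs(np.fft.fft(k, n_fft))
    freqs = np.fft.fftfreq(n_fft, 1.0 / fs)
    pos = slice(0, n_fft // 2)
    width_f = _half_max_width(freqs[pos], spec[pos])
    return width_t, width_f


def fwhm_time(freq: float, cycles: float = 5.0) -> float:
    """Temporal FWHM (s) of the Morlet amplitude envelope at ``freq`` Hz."""
    return cycles * np.sqrt(2.0 * _LN2) / (np.pi * freq)


def fwhm_freq(freq: float, cycles: float = 5.0) -> float:
    """Spectral FWHM (Hz) of the Morlet frequency response at ``freq`` Hz."""
    return 2.0 * np.sqrt(2.0 * _LN2) * freq / cycles


@dataclass(frozen=True)
class WaveletBank:
    """Family of complex Morlet kernels on a common frequency grid."""

    freqs: np.ndarray = field(
        default_factory=lambda: np.arange(3.0, 50.0 + 0.5, 1.0)
    )
    cycles: float = 5.0
    support_sigmas: float = 4.0  # kernel truncated at +/- this many sigma_t
    edge_sigmas: float = 2.5  # coefficients closer than this to an edge -> invalid

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.atleast_1d(np.asarray(self.freqs, float)))
        if np.any(self.freqs <= 0):
            raise ValueError("wavelet frequencies must be positive")
        if self.cycles <= 0:
            raise ValueError("cycles must be positive")

    def sigma_t(self, freq: float) -> float:
        """Gaussian envelope SD in seconds."""
        return self.cycles / (2.0 * np.pi * freq)

    def kernel(self, freq: float, fs: float) -> np.ndarray:
        """Complex Morlet kernel sampled at ``fs``, unit gain, zero mean.

        Unit gain means convolution with ``cos(2*pi*freq*t)`` returns
        modulus 1.0 at the center frequency; the kernel mean is removed
        so a DC offset in the signal cannot leak into the coefficient.
        """
        if freq > fs / 2.0:
            raise ValueError(f"frequency {freq} Hz above Nyquist ({fs / 2} Hz)")
        st = self.sigma_t(freq)
        half = int(np.ceil(self.support_sigmas * st * fs))
        t = np.arange(-half, half + 1) / fs
        k = np.exp(-(t**2) / (2.0 * st**2)) * np.exp(2j * np.pi * freq * t)
        k = k - k.mean()
        # response of conv(x, k) to cos(2*pi*f*t) has modulus |K(f)|/2
        gain = np.abs(np.sum(k * np.exp(-2j * np.pi * freq * t))) / 2.0
        return k / gain

    def half_support(self, freq: float, fs: float) -> int:
        """Kernel half-length in samples at ``fs``."""
        return int(np.ceil(self.support_sigmas * self.sigma_t(freq) * fs))

    def edge_margin(self, freq: float, fs: float) -> int:
        """Edge-invalid margin in samples at ``fs``.

        Inside this margin the Gaussian envelope places more than
        ``exp(-edge_sigmas**2 / 2)`` of its peak weight (about 4% at the
        default 2.5 sigma) on samples outside the epoch, so the
        coefficient is flagged and excluded from statistics.
        """
        return int(np.ceil(self.edge_sigmas * self.sigma_t(freq) * fs))


@dataclass
class TFMap:
    """Time-frequency map with axis metadata.

    ``data`` is complex (per-trial coefficients: trials x channels x
    freqs x times) or non-negative real (amplitude/ITPC: channels x
    freqs x times).  ``valid`` flags, per (freq, time), coefficients far
    enough from the epoch edges to be uncontaminated.
    """

    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: tuple[str, ...]
    quantity: str  # "coefficients" | "evoked_amplitude" | "itpc" | "phase"
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones((len(self.freqs), len(self.times)), bool)

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 0.5:
            warnings.warn(f"nearest frequency to {f} Hz is {self.freqs[i]} Hz")
        return i

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times - t_ms)))


def _transform_array(
    data: np.ndarray, fs: float, times: np.ndarray, bank: WaveletBank
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve (..., n_samples) with every kernel; return (coefs, valid)."""
    n = data.shape[-1]
    coefs = np.empty(data.shape[:-1] + (bank.freqs.size, n), complex)
    valid = np.zeros((bank.freqs.size, n), bool)
    for i, f in enumerate(bank.freqs):
        k = bank.kernel(f, fs)
        k_nd = k.reshape((1,) * (data.ndim - 1) + (-1,))
        coefs[..., i, :] = fftconvolve(data, k_nd, mode="same", axes=-1)
        margin = bank.edge_margin(f, fs)
        if margin < n:
            valid[i, margin : n - margin] = True
    return coefs, valid


def wavelet_transform(epochs: EpochSet, bank: WaveletBank | None = None) -> TFMap:
    """Per-trial complex Morlet coefficients (trials x channels x freqs x times)."""
    bank = bank or WaveletBank()
    coefs, valid = _transform_array(epochs.data, epochs.fs, epochs.times, bank)
    return TFMap(coefs, bank.freqs, epochs.times, epochs.ch_names, "coefficients", valid)


def evoked_amplitude(epochs: EpochSet, bank: WaveletBank | None = None) -> TFMap:
    """Evoked oscillation amplitude: transform of the trial-average waveform.

    Amplitude is the modulus of the complex coefficient (square root of
    power); only phase-locked activity survives the cross-trial average.
    """
    if epochs.n_trials == 0:
        raise ValueError("evoked amplitude needs at least one trial")
    bank = bank or WaveletBank()
    avg = epochs.data.mean(axis=0)
    coefs, valid = _transform_array(avg, epochs.fs, epochs.times, bank)
    return TFMap(
        np.abs(coefs), bank.freqs, epochs.times, epochs.ch_names,
        "evoked_amplitude", valid,
    )


def itpc(trial_tf: TFMap) -> TFMap:
    """Inter-trial phase coherence ``|sum_i exp(1j*theta_i)/N|`` per bin.

    Takes the per-trial complex coefficient map (trial axis first) and
    collapses it to channels x freqs x times.  A pure phase statistic:
    per-trial amplitudes are discarded before averaging.
    """
    if trial_tf.quantity != "coefficients" or trial_tf.data.ndim != 4:
        raise ValueError("itpc expects a per-trial complex coefficient TFMap")
    n = trial_tf.data.shape[0]
    if n < 2:
        raise ValueError("ITPC requires at least two trials")
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = trial_tf.data / np.abs(trial_tf.data)
    phasors[~np.isfinite(phasors)] = 0.0
    out = np.abs(phasors.mean(axis=0))
    return TFMap(
        out, trial_tf.freqs, trial_tf.times, trial_tf.ch_names, "itpc",
        trial_tf.valid.copy(),
    )


def pre_tms_phase(
    trial_tf: TFMap,
    freq: float = 10.0,
    t_ms: float = -95.0,
    channels: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Per-trial oscillatory phase at (freq, t_ms), wrapped to [-pi, pi).

    The default (10 Hz, -95 ms) reads the alpha phase 200 ms before the
    first pulse of the burst.  If ``channels`` is given, the complex
    coefficients are averaged across those channels before taking the
    angle.  Raises if the requested point is edge-contaminated.
    """
    fi = trial_tf.freq_index(freq)
    ti = trial_tf.time_index(t_ms)
    if not trial_tf.valid[fi, ti]:
        raise ValueError(
            f"({freq} Hz, {t_ms} ms) lies in the edge-flagged region"
        )
    coefs = trial_tf.data[:, :, fi, ti]
    if channels is not None:
        idx = [trial_tf.ch_names.index(c) for c in channels]
        coefs = coefs[:, idx]
    phases = np.angle(coefs.mean(axis=1))
    return np.mod(phases + np.pi, 2.0 * np.pi) - np.pi


def estimate_iaf(
    rest: RawRecording | np.ndarray,
    fs: float | None = None,
    band: tuple[float, float] = (7.0, 13.0),
    seg_seconds: float = 2.0,
) -> float:
    """Individual alpha frequency from a resting-state recording.

    Welch's periodogram (Hann segments of ``seg_seconds``, 50% overlap,
    0.5 Hz resolution at the default) is computed on the (first-channel)
    recording and the frequency of the maximum peak inside ``band`` is
    returned.  If the band argmax sits on the band edge with no interior
    local maximum, the boundary value is still returned but flagged with
    a warning (no clear alpha peak).
    """
    if isinstance(rest, RawRecording):
        x, fs = rest.data[0], rest.fs
    else:
        x = np.asarray(rest, float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
    if x.size / fs < 10.0:
        raise ValueError("rest recording must be at least 10 s long")
    nperseg = int(round(seg_seconds * fs))
    freqs, pxx = welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    bf, bp = freqs[in_band], pxx[in_band]
    i = int(np.argmax(bp))
    # flag recordings with no credible alpha peak: the band argmax sits on
    # the band edge, or the dominant rhythm (ignoring slow 1/f drift below
    # 2 Hz) lies outside the search band
    above_drift = freqs >= 2.0
    global_peak = freqs[above_drift][int(np.argmax(pxx[above_drift]))]
    if i in (0, bp.size - 1) or not band[0] <= global_peak <= band[1]:
        warnings.warn(
            f"no clear alpha peak in {band} Hz (dominant rhythm at "
            f"{global_peak:.2f} Hz); returning in-band boundary/argmax "
            f"{bf[i]:.2f} Hz",
            stacklevel=2,
        )
    return float(bf[i])
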