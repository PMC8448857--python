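"""Synthetic TMS-EEG generator: trial schedules, pulse trains, and raw trials.

The generator implements the minimal dynamical account of alpha-band
entrainment by a short rhythmic pulse burst: each simulated participant
carries an intrinsic alpha oscillator (frequency ``iaf``) whose phase
advances freely at ``2*pi*iaf`` and, at every *active* magnetic pulse,
jumps a fraction ``reset_strength`` (kappa) of the wrapped distance to a
preferred reset phase.  Partial resets accumulate over the four-pulse
burst, producing the progressive phase alignment that the downstream
inter-trial phase coherence (ITPC) analysis is designed to detect.  Sham
trials carry neither the reset nor the stimulation artifact, and the
arrhythmic condition jitters the two middle pulses so that the same pulse
energy is delivered without a consistent 10 Hz rhythm.

Trial structure (times in ms relative to the visual pre-cue at t=0):
pulses at 105/205/305/405 in the rhythmic condition; in the arrhythmic
condition pulses 2 and 3 are jittered by a bimodal mixture
0.5*N(+30, 10) + 0.5*N(-30, 10), resampled until the train is strictly
increasing with at least 20 ms between pulses (which keeps the artifact
interpolation windows non-overlapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import CHANNELS_63, occipital_gain_map

#: Rhythmic-condition pulse onsets, ms after pre-cue onset (25 ms cue +
#: 80 ms gap -> first pulse at 105 ms; 100 ms inter-pulse interval).
RHYTHMIC_PULSES: tuple[float, float, float, float] = (105.0, 205.0, 305.0, 405.0)

#: Minimum admissible gap between consecutive pulses, ms.
MIN_PULSE_GAP: float = 20.0

#: Half-width / full-width of the bimodal jitter mixture, ms.
JITTER_MODE: float = 30.0
JITTER_SD: float = 10.0


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class OscillatorModel:
    """Parameters of one simulated participant's alpha oscillator.

    Parameters
    ----------
    iaf
        Individual alpha frequency in Hz, within the 7-13 Hz search band.
    alpha_amp
        Oscillation amplitude at the source, microvolt.
    reset_strength
        kappa in [0, 1]: fraction of the wrapped phase distance to
        ``reset_phase`` removed by each active pulse.  0 leaves the phase
        untouched; 1 is a hard reset.
    reset_phase
        Preferred phase (radians) toward which active pulses pull.
    noise_exponent
        Spectral slope of the background noise (power ~ 1/f**exponent).
    noise_amp
        RMS of the background noise per channel, microvolt.
    artifact_amp
        Peak amplitude of the pulse spike artifact at the source, microvolt.
    artifact_duration
        Duration of the spike artifact in ms; physiological range 4-10 ms.
    phase_dependent_reset
        Optional modulation depth in [0, 1]: the per-trial reset efficacy
        is scaled by ``(1 + depth*cos(phi_pre - reset_phase)) / (1 + depth)``
        where ``phi_pre`` is the oscillator phase 200 ms before the first
        pulse.  0 (default) disables the modulation; positive values make
        entrainment depend on the pre-burst alpha phase.
    """

    iaf: float = 10.0
    alpha_amp: float = 10.0
    reset_strength: float = 0.8
    reset_phase: float = 0.0
    noise_exponent: float = 1.0
    noise_amp: float = 5.0
    artifact_amp: float = 60.0
    artifact_duration: float = 7.0
    phase_dependent_reset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reset_strength <= 1.0:
            raise ValueError("reset_strength (kappa) must lie in [0, 1]")
        if not 7.0 <= self.iaf <= 13.0:
            raise ValueError("iaf must lie in the 7-13 Hz alpha search band")
        if not 4.0 <= self.artifact_duration <= 10.0:
            raise ValueError("artifact_duration must lie in [4, 10] ms")
        if not 0.0 <= self.phase_dependent_reset <= 1.0:
            raise ValueError("phase_dependent_reset must lie in [0, 1]")
        for name in ("alpha_amp", "noise_amp", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PulseTrain:
    """Four pulse onsets (ms after pre-cue onset) plus the rhythmicity tag."""

    onsets: tuple[float, float, float, float]
    rhythmicity: str  # "rhythmic" | "arrhythmic"

    def __post_init__(self) -> None:
        o = self.onsets
        if len(o) != 4:
            raise ValueError("a pulse train has exactly four onsets")
        if o[0] != RHYTHMIC_PULSES[0] or o[3] != RHYTHMIC_PULSES[3]:
            raise ValueError(
                "first and last pulses are fixed at "
                f"{RHYTHMIC_PULSES[0]:.0f}/{RHYTHMIC_PULSES[3]:.0f} ms in "
                "both rhythmicity conditions"
            )
        gaps = np.diff(o)
        if np.any(gaps < MIN_PULSE_GAP):
            raise ValueError(f"pulse gaps must be >= {MIN_PULSE_GAP} ms")
        if self.rhythmicity == "rhythmic" and not np.allclose(gaps, 100.0):
            raise ValueError("rhythmic trains have exact 100 ms gaps")
        if self.rhythmicity not in ("rhythmic", "arrhythmic"):
            raise ValueError("rhythmicity must be 'rhythmic' or 'arrhythmic'")


def sample_arrhythmic_jitter(
    seed: int | np.random.Generator, max_attempts: int = 1000
) -> tuple[float, float]:
    """Draw jitter offsets (ms) for pulses 2 and 3 of an arrhythmic train.

    Each offset is drawn independently from the equal-weight bimodal
    mixture ``0.5*N(+30, 10) + 0.5*N(-30, 10)``; the pair is jointly
    resampled until the implied train 105 / 205+j2 / 305+j3 / 405 ms is
    strictly increasing with >= 20 ms gaps.
    """
    rng = _rng(seed)
    for _ in range(max_attempts):
        signs = rng.choice((-1.0, 1.0), size=2)
        j2, j3 = signs * JITTER_MODE + rng.normal(0.0, JITTER_SD, size=2)
        onsets = (105.0, 205.0 + j2, 305.0 + j3, 405.0)
        if np.all(np.diff(onsets) >= MIN_PULSE_GAP):
            return float(j2), float(j3)
    raise RuntimeError(
        f"no admissible jitter pair found in {max_attempts} attempts"
    )


def make_pulse_train(
    rhythmicity: str, seed: int | np.random.Generator | None = None
) -> PulseTrain:
    """Build one pulse train; arrhythmic trains require a seed/generator."""
    if rhythmicity == "rhythmic":
        return PulseTrain(RHYTHMIC_PULSES, "rhythmic")
    if seed is None:
        raise ValueError("arrhythmic trains need a seed")
    j2, j3 = sample_arrhythmic_jitter(seed)
    onsets = (105.0, 205.0 + j2, 305.0 + j3, 405.0)
    return PulseTrain(onsets, "arrhythmic")


def make_trial_schedule(
    n_blocks: int = 8, trials_per_block: int = 64, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Blocked, balanced trial schedule as a tidy table.

    Rhythmicity is a block-level factor (half the blocks rhythmic, half
    arrhythmic, block order seeded); stimulation (active/sham) and target
    side (left/right) are balanced and order-randomized within each block.
    Every trial, sham included, gets a pulse train: sham trials use the
    same "virtual" pulse times so preprocessing can be applied identically.

    Returns a DataFrame with columns ``block, trial, rhythmicity,
    stimulation, target_side, p1..p4`` (pulse onsets in ms).
    """
    if n_blocks % 2:
        raise ValueError("n_blocks must be even (half rhythmic, half arrhythmic)")
    if trials_per_block % 4:
        raise ValueError(
            "trials_per_block must be divisible by 4 "
            "(stimulation x target-side balance)"
        )
    rng = _rng(seed)
    block_rhythm = np.array(
        ["rhythmic"] * (n_blocks // 2) + ["arrhythmic"] * (n_blocks // 2)
    )
    rng.shuffle(block_rhythm)

    cell = trials_per_block // 4
    rows = []
    for b, rhythm in enumerate(block_rhythm):
        stim = np.repeat(["active", "active", "sham", "sham"], cell)
        side = np.tile(np.repeat(["left", "right"], cell), 2)
        order = rng.permutation(trials_per_block)
        for k, idx in enumerate(order):
            train = make_pulse_train(rhythm, rng)
            rows.append(
                {
                    "block": b,
                    "trial": b * trials_per_block + k,
                    "rhythmicity": rhythm,
                    "stimulation": stim[idx],
                    "target_side": side[idx],
                    "p1": train.onsets[0],
                    "p2": train.onsets[1],
                    "p3": train.onsets[2],
                    "p4": train.onsets[3],
                }
            )
    return pd.DataFrame(rows)


def trial_pulses(trial: pd.Series | dict) -> tuple[float, float, float, float]:
    """Pulse onsets of one schedule row."""
    return tuple(float(trial[k]) for k in ("p1", "p2", "p3", "p4"))


def time_axis(t_span: tuple[float, float], fs: float) -> np.ndarray:
    """Half-open sample grid [t0, t1) in ms at sampling rate ``fs`` Hz."""
    t0, t1 = t_span
    n = int(round((t1 - t0) * fs / 1000.0))
    return t0 + np.arange(n) * (1000.0 / fs)


def one_over_f_noise(
    n_samples: int,
    fs: float,
    exponent: float,
    rms: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, target RMS.

    Returns an (n_series, n_samples) array.  Synthesized in the Fourier
    domain: white complex Gaussian coefficients shaped by f**(-exponent/2),
    DC removed.
    """
    if rms == 0.0:
        return np.zeros((n_series, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    coef = rng.standard_normal((n_series, freqs.size)) + 1j * rng.standard_normal(
        (n_series, freqs.size)
    )
    x = np.fft.irfft(coef * shape, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0.0] = 1.0
    return x / std * rms


def _spike_artifact(
    t_ms: np.ndarray, onset: float, amp: float, duration: float
) -> np.ndarray:
    """Seeded damped 250 Hz ring starting at ``onset``, lasting ``duration`` ms."""
    dt = t_ms - onset
    env = np.where(
        (dt >= 0.0) & (dt <= duration), np.exp(-dt / (duration / 3.0)), 0.0
    )
    return amp * env * np.cos(2.0 * np.pi * 0.25 * dt)  # 250 Hz = 0.25/ms


def oscillator_phase(
    model: OscillatorModel,
    t_ms: np.ndarray,
    phi0: float,
    active_pulses: tuple[float, ...] = (),
) -> np.ndarray:
    """Phase trajectory with partial resets at active pulse times.

    Between pulses the phase advances at ``2*pi*iaf``; at each active
    pulse it jumps by ``kappa_eff * wrap(reset_phase - phi)`` where the
    wrapped distance lies in (-pi, pi].  With ``phase_dependent_reset``
    set, kappa_eff additionally depends on the phase 200 ms before the
    first pulse (same factor for all four pulses of the trial).
    """
    omega = 2.0 * np.pi * model.iaf / 1000.0  # rad per ms
    kappa = model.reset_strength
    if model.phase_dependent_reset > 0.0 and active_pulses:
        phi_pre = phi0 + omega * (min(active_pulses) - 200.0)
        depth = model.phase_dependent_reset
        kappa *= (1.0 + depth * np.cos(phi_pre - model.reset_phase)) / (1.0 + depth)

    phi = phi0 + omega * t_ms
    shift = 0.0
    for tp in sorted(active_pulses):
        phi_pre_pulse = phi0 + omega * tp + shift
        delta = kappa * _wrap(model.reset_phase - phi_pre_pulse)
        shift += delta
        phi = np.where(t_ms >= tp, phi + delta, phi)
    return phi


def _wrap(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap to (-pi, pi]."""
    return -(np.mod(-np.asarray(angle) + np.pi, 2.0 * np.pi) - np.pi)


def simulate_epoch(
    model: OscillatorModel,
    trial: pd.Series | dict,
    ch_names: tuple[str, ...] = CHANNELS_63,
    fs: float = 2500.0,
    t_span: tuple[float, float] = (-300.0, 900.0),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one raw trial, (n_channels, n_samples) in microvolt.

    The alpha oscillator (plus, on active trials, the spike artifact) is
    projected onto the scalp through a fixed right-occipital gain map
    peaking at O2/PO4; background 1/f noise is independent per channel.
    Sham trials receive neither phase resets nor artifacts.  The initial
    oscillator phase is uniform on [0, 2pi) per trial.
    """
    if fs < 1000.0:
        raise ValueError("fs must be >= 1000 Hz to resolve artifact windows")
    rng = _rng(seed)
    t = time_axis(t_span, fs)
    pulses = trial_pulses(trial)
    if pulses[0] < t_span[0] or pulses[-1] + model.artifact_duration >= t_span[1]:
        raise ValueError("t_span does not cover the pulse train")

    active = trial["stimulation"] == "active"
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    phi = oscillator_phase(model, t, phi0, pulses if active else ())
    source = model.alpha_amp * np.cos(phi)

    if active:
        for tp in pulses:
            amp = model.artifact_amp * (0.8 + 0.4 * rng.uniform())
            source = source + _spike_artifact(t, tp, amp, model.artifact_duration)

    gain = occipital_gain_map(tuple(ch_names))
    noise = one_over_f_noise(
        t.size, fs, model.noise_exponent, model.noise_amp, rng, len(ch_names)
    )
    return gain[:, None] * source[None, :] + noise


def simulate_rest(
    model: OscillatorModel,
    duration: float = 120.0,
    fs: float = 2500.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Eyes-closed resting-state single-channel recording (1D, microvolt).

    A stationary alpha oscillator at ``model.iaf`` (no pulses) over 1/f
    background noise; used to exercise the individual-alpha-frequency
    estimator.  ``duration`` is in seconds and must be >= 10 s.
    """
    if duration < 10.0:
        raise ValueError("rest duration must be >= 10 s")
    rng = _rng(seed)
    n = int(round(duration * fs))
    t_s = np.arange(n) / fs
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    x = model.alpha_amp * np.cos(2.0 * np.pi * model.iaf * t_s + phi0)
    return x + one_over_f_noise(n, fs, model.noise_exponent, model.noise_amp, rng)[0]


def simulate_observer(
    contrast: float,
    dmax: float = 2.4,
    c50: float = 0.16,
    exponent: float = 2.0,
    n_trials: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate an unbiased signal-detection observer in the tilt task.

    Sensitivity follows the Naka-Rushton contrast response
    ``d'(c) = dmax * c**n / (c**n + c50**n)``; the observer is unbiased,
    so on clockwise-signal trials P(respond cw) = Phi(d'/2) and on
    counterclockwise trials P(respond cw) = Phi(-d'/2).

    Returns a per-trial table with columns ``contrast, signal, response,
    correct``.
    """
    from scipy.stats import norm

    from .psychophysics import naka_rushton

    if not 0.0 < contrast <= 1.0:
        raise ValueError("contrast must lie in (0, 1]")
    rng = _rng(seed)
    dprime = naka_rushton(contrast, dmax, c50, exponent)
    hit_rate = norm.cdf(dprime / 2.0)
    fa_rate = norm.cdf(-dprime / 2.0)

    signal = rng.choice(["cw", "ccw"], size=n_trials)
    p_cw = np.where(signal == "cw", hit_rate, fa_rate)
    response = np.where(rng.uniform(size=n_trials) < p_cw, "cw", "ccw")
    return pd.DataFrame(
        {
            "contrast": contrast,
            "signal": signal,
            "response": response,
            "correct": signal == response,
        }
    )
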