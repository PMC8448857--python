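# Methods

This note documents the generative model behind `entraineeg.synth`, the
numerical conventions of the analysis chain, the parameter defaults and
why they were chosen, and the limits of what the synthetic tests can
show about real recordings.

## The experiment being modeled

Each trial: a 25 ms visual pre-cue (t = 0 at its onset), a 500 ms
inter-stimulus interval during which a four-pulse TMS burst is
delivered, then a brief two-Gabor tilt-discrimination display.  The
burst starts 105 ms after pre-cue onset.  In the *rhythmic* condition
the pulses are exactly 100 ms apart (105/205/305/405 ms, a 10 Hz
driver); in the *arrhythmic* control the first and last pulses keep
their times while pulses 2 and 3 are jittered per trial by the bimodal
mixture ½·N(+30, 10) + ½·N(−30, 10) ms, resampled jointly until all
inter-pulse gaps are ≥ 20 ms.  The 20 ms floor is the package's choice
(not dictated by the design): it guarantees the −1…+13 ms artifact
windows of neighboring pulses can never overlap.  *Active* and *sham*
stimulation and left/right target side are balanced and shuffled within
blocks; rhythmicity is a block-level factor (half the blocks each,
order randomized).  Sham trials carry "virtual" pulse times so every
preprocessing step can be applied identically to both stimulation types.

## Oscillator model

A simulated participant is an `OscillatorModel`:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `iaf` | intrinsic alpha frequency, Hz | 10.0 (cohorts: N(10, 1) truncated to 8–12) | typical adult occipital alpha and its inter-individual spread |
| `alpha_amp` | source oscillation amplitude, µV | 10 | prominent occipital alpha at rest |
| `reset_strength` (κ) | fraction of wrapped phase distance to `reset_phase` removed per active pulse, ∈ [0, 1] | 0.8 | strong but partial per-pulse reset; κ = 0 disables entrainment, κ = 1 is a hard reset |
| `reset_phase` | preferred phase, rad | 0 | arbitrary reference; only phase differences matter |
| `noise_exponent` | 1/f^α slope of background noise | 1.0 | canonical EEG background |
| `noise_amp` | background RMS per channel, µV | 5 | alpha SNR ≈ 2, a clearly visible but not dominant rhythm |
| `artifact_amp`, `artifact_duration` | pulse spike artifact, µV / ms | 60 / 7 | spike artifacts last ~4–10 ms; amplitude far above EEG so cleaning is consequential |
| `phase_dependent_reset` | modulation depth of κ by the pre-burst phase | 0 | off unless a phase-dependence study is simulated |

The phase φ(t) advances at 2π·iaf between pulses.  At each **active**
pulse, φ jumps by κ·wrap(reset_phase − φ), with wrap(·) ∈ (−π, π].
Partial resets therefore accumulate: after p pulses the residual spread
of an initially uniform phase distribution is (1−κ)^p of a cycle, which
is the minimal dynamical account of progressive phase alignment over a
burst.  The initial phase is uniform per trial; the phase advance is
otherwise deterministic (no phase diffusion), so alignment persists
after the burst — the model is intentionally the simplest one exhibiting
entrainment that outlasts the driver.  With `phase_dependent_reset` = d,
the per-trial efficacy is scaled by (1 + d·cos(φ₋₂₀₀ − reset_phase))/(1 + d),
where φ₋₂₀₀ is the phase 200 ms before the first pulse; this generates
data in which entrainment depends on the pre-burst alpha phase, the
structure the phase-bin analysis is designed to detect.

The source (oscillation + artifact) is projected to the scalp through a
fixed gain map: Gaussian falloff (σ = 5 cm) from a virtual source at the
midpoint of O2/PO4, normalized to peak 1.  Background noise is
independent per channel.  The artifact is a damped 250 Hz cosine ring
(decay constant = duration/3) with ±20 % seeded amplitude variability.

## Preprocessing conventions

- **Artifact interpolation**: every sample in the *closed* interval
  [t_pulse − 1 ms, t_pulse + 13 ms] (36 samples at 2500 Hz) is replaced
  by monotone shape-preserving piecewise-cubic Hermite interpolation
  (scipy's PCHIP, the Fritsch–Carlson scheme) anchored on all clean
  samples; PCHIP slopes are local, so this equals interpolating each
  window from its neighbors.  All other samples are bit-identical to the
  input, which the tests assert exactly.
- **Downsampling** 2500 → 100 Hz: 8th-order zero-phase Butterworth
  low-pass at 0.4 × target rate (40 Hz) before decimation.  Consequence:
  content above ~40 Hz is attenuated by design; wavelet analysis near
  the 50 Hz Nyquist of the analysis rate is not meaningful.
- **Epoching**: half-open [−300, 900) ms windows re-referenced to the
  pre-cue (120 samples at 100 Hz, sample 30 at t = 0).  Out-of-range
  cues are skipped with a warning.  No re-referencing of channels
  anywhere.

## Spectral conventions

- Morlet kernels `exp(−t²/2σ_t²)·exp(2πift)` with σ_t = c/(2πf),
  truncated at ±4σ_t, mean-subtracted (DC-blind), and normalized to
  **unit gain**: a unit sinusoid at the center frequency yields
  amplitude 1.0, so amplitude maps read in µV.
- Closed-form resolution: FWHM_time = c√(2 ln 2)/(πf), FWHM_freq =
  2√(2 ln 2)·f/c; at f = 10, c = 5 these are 0.19 s and 4.71 Hz, and the
  implemented kernel reproduces them to measurement precision.
- **Edge handling**: no padding; coefficients within 2.5 envelope SDs of
  an epoch edge are flagged invalid and excluded from statistics.  At
  10 Hz/100 Hz this is a 200 ms margin, the largest margin that keeps
  both the pre-burst phase read-out (−95 ms, i.e. 205 ms from the epoch
  start) and the late analysis windows usable; beyond 2.5σ the envelope
  weight falling outside the epoch is under ~4 % of peak.  Residual
  truncation bias at the margin is common to all trials of a
  participant and cancels in paired contrasts.
- Phase convention: for cos(2πf(t − t₀)) the coefficient phase at time
  t is +2πf(t − t₀), wrapped to [−π, π).  The pre-burst phase is read at
  the sample nearest −95 ms (−100 ms on the t=0-aligned 10 ms grid).
- IAF: Welch periodogram (2 s Hann segments, 50 % overlap → 0.5 Hz
  resolution), argmax restricted to 7–13 Hz.  If the band argmax sits on
  a band edge, or the dominant rhythm above 2 Hz lies outside the band,
  the result is returned with a "no clear alpha peak" warning.

## Statistical conventions

- **Planned window contrasts**: per-participant means of ITPC / evoked
  amplitude at 10 Hz over the O2/PO4 average and the half-open window
  samples, compared by paired t-tests.  The seven windows are planned a
  priori, so no correction across windows.  Tail: two-tailed (the more
  conservative choice; the topographic cluster tests are one-tailed as
  is conventional for directional entrainment predictions).
- **Cluster permutation**: channel-wise paired t, threshold at the
  cluster-forming quantile (one-tailed 0.05), connected components under
  the sensor-adjacency graph (neighbors = scalp distance < 1.3 × median
  nearest-neighbor distance on the idealized 10–20 layout), cluster mass
  = summed t, null by sign-flipping participant difference maps, p =
  (1 + #{null maxima ≥ mass})/(n_perm + 1).  Agrees with MNE's
  single-sample cluster test to machine precision on the t-maps and
  exactly on cluster membership (asserted in the tests).
- **Phase bins**: six equal circular bins starting at −π (origin is a
  parameter).  Bin-wise ITPC is computed per participant per time
  sample over a *closed* 205–705 ms window snapped down to the sample
  grid (→ 51 samples at 100 Hz: 200…700 ms); this closed convention is
  used for this analysis only.  Cohort summary: bin means pool
  participants × time samples; the repeated-measures ANOVA and the sine
  regression run on per-participant time-averaged tables; participants
  with an under-filled bin (< 2 trials) are excluded pairwise.
- **Sine regression** y = a·sin(f·x·π/3 + ϕ) + c over bin number
  x = 1…6: nonlinear least squares with multi-start over
  ϕ ∈ {0, π/2, π, 3π/2} and f ∈ {0.5, 1, 2}, canonicalized to a ≥ 0,
  ϕ ∈ [0, 2π).  f is bounded to [0.5, 3] cycles-per-six-bins: below half
  a cycle the model degenerates into an arbitrarily large-amplitude
  polynomial trend and stops being interpretable as cyclic modulation.
  Flat inputs (or fits with amplitude below 1e−10) return the a = 0
  flat solution.
- **RM-ANOVA**: classical one-way within-subject decomposition,
  F(b−1, (b−1)(n−1)) — (5, 45) for 6 bins × 10 participants.  No
  sphericity correction (not needed for the synthetic checks; real data
  may warrant Greenhouse–Geisser).
- **Psychophysics**: d′ and criterion with the log-linear correction
  (add 0.5 per cell) applied only when a rate is 0 or 1, toggleable.
  Naka–Rushton fitting runs in log-contrast space (the function is a
  logistic in log c), multi-start over exponents {1, 2, 3}.

## Reproducibility

Every simulation entry point takes an integer seed; one global seed is
fanned out to per-participant and per-trial children via
`numpy.random.SeedSequence` (documented in `pipeline.spawn_seeds`; all
derived seeds < 2³¹).  Identical (config, seed) pairs produce
byte-identical result tables, which the test suite asserts.

## Problem sizes used by the checks

The cohort-level checks simulate 10 participants × 128 trials per
rhythmicity condition (the full blocked design, active trials only) on
the reduced 8-channel occipito-parietal montage, which contains the
O2/PO4 channels of interest; the full 63-channel montage is used
wherever topography matters (gain map, adjacency, cluster tests).  The
cluster-test calibration uses 500 null repetitions of 10 × 63 Gaussian
topographies at 1000 permutations.  These sizes make the statistical
assertions stable while keeping a full test run in the low minutes.

## What the synthetic tests do and do not show

The generator reproduces the *structure* of the experiment — timing,
blocking, artifact placement, phase-reset dynamics, 1/f background,
inter-individual IAF spread — so passing tests demonstrate that the
analysis chain is correct: it recovers known entrainment when present
(κ > 0), stays silent when absent (κ = 0, type-I control verified at
the whole-pipeline level), and its statistics are calibrated.  The
generator does **not** model volume conduction beyond a fixed gain map,
auditory/somatosensory co-stimulation (sham is signal-identical to
no-stimulation by design, keeping it a clean negative control), ocular
or muscular artifacts, non-stationary alpha power, or phase diffusion.
Group-level effect sizes measured on synthetic cohorts therefore do not
transfer to real recordings; only the qualitative pattern does.

One structural consequence of the strong-reset regime is worth noting:
with per-pulse κ = 0.8 a *single* pulse already aligns phases almost
fully (residual spread 0.2 of a cycle, mean resultant ≈ 0.94).  Because
the arrhythmic condition jitters pulse 2 by ±30 ms, about half of its
pulse-2 events fall inside window W1 [105, 205) ms, and the 190 ms
wavelet FWHM spreads the large post-pulse-2 contrast across the 205 ms
boundary; the rhythmic-vs-arrhythmic contrast in W1 is then reliably
significant in this regime, unlike W0.  In the weak-reset regime
(κ ≲ 0.3) alignment builds gradually over the burst and W1 behaves like
W0.  Analyses of real data that find no W1 effect are thus informative
about the per-pulse reset strength.

## Known limitations

- The sine-regression frequency bound excludes sub-half-cycle trends by
  design; genuinely monotone bin patterns will be fit by f = 0.5 humps.
- The pre-burst phase is read 2.5–2.6 envelope SDs from the epoch edge;
  a small common truncation bias is unavoidable with −300 ms epochs and
  5-cycle wavelets.
- `estimate_iaf` assumes a unimodal alpha peak; split peaks return the
  larger mode.
- The BrainVision writer covers only the minimal IEEE-float multiplexed
  layout needed for fixtures and round-trip checks.
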