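"""Statistical battery for the entrainment analysis.

* planned paired t-contrasts of the phase-locked signatures in seven
  a-priori 100 ms windows W0-W6 spanning before, during, and after the
  four-pulse burst (no multiple-comparison correction across planned
  windows);
* topographic inference corrected by cluster-based permutation tests
  (channel-wise paired t, neighborhood clustering, sign-flipping null);
* pre-burst alpha-phase dependence: trials sorted into six equidistant
  phase bins, bin-wise ITPC summarized by a one-way repeated-measures
  ANOVA and a sine regression ``y = a*sin(f*x*pi/3 + phi) + c`` over bin
  number x = 1..6;
* across-participant Pearson correlation between individual alpha
  frequency (IAF) and entrained ITPC, with the |IAF - 10 Hz| variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from .spectral import TFMap

#: Planned 100 ms analysis windows, ms, half-open [start, end).
#: W0 precedes the first pulse; W1-W3 are the inter-pulse cycles;
#: W4-W6 are the first three cycles after the last pulse.
WINDOWS: dict[str, tuple[float, float]] = {
    "W0": (5.0, 105.0),
    "W1": (105.0, 205.0),
    "W2": (205.0, 305.0),
    "W3": (305.0, 405.0),
    "W4": (405.0, 505.0),
    "W5": (505.0, 605.0),
    "W6": (605.0, 705.0),
}


# ---------------------------------------------------------------- contrasts


def window_contrast(
    metric_a: np.ndarray, metric_b: np.ndarray
) -> tuple[float, float]:
    """Paired two-tailed t-test across participants for one planned window.

    ``metric_a``/``metric_b`` are per-participant scalars (e.g. ITPC at
    10 Hz averaged over O2/PO4 and the window samples, one value per
    participant and condition).  Returns (t, p).
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("metrics must be equal-length per-participant vectors")
    if a.size < 3:
        raise ValueError("paired contrast needs at least 3 participants")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


# ------------------------------------------------- cluster permutation test


@dataclass
class ClusterResult:
    """Outcome of a topographic cluster permutation test.

    ``clusters`` holds channel-index arrays (connected components under
    the adjacency graph), ``masses`` the summed member t-values, and
    ``p_values`` the permutation p of each cluster,
    ``(1 + #{null maxima >= mass}) / (n_perm + 1)``.
    """

    clusters: list[np.ndarray]
    masses: np.ndarray
    p_values: np.ndarray
    t_obs: np.ndarray
    threshold: float
    null_max: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[np.ndarray]:
        return [c for c, p in zip(self.clusters, self.p_values) if p <= alpha]

    @property
    def any_significant(self) -> bool:
        return bool(len(self.significant()))


def _neighbor_lists(adjacency: np.ndarray) -> list[np.ndarray]:
    adj = np.asarray(adjacency, bool)
    if adj.shape[0] != adj.shape[1] or not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be a symmetric square boolean matrix")
    return [np.flatnonzero(row) for row in adj]


def _clusters_from_mask(
    mask: np.ndarray, neighbors: list[np.ndarray]
) -> list[np.ndarray]:
    """Connected components of the suprathreshold channel set (DFS)."""
    seen = np.zeros(mask.size, bool)
    out = []
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neighbors[u]:
                if mask[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        out.append(np.array(sorted(comp)))
    return out


def _signed_max_mass(
    t_map: np.ndarray, thr: float, neighbors: list[np.ndarray], tail: str
) -> float:
    """Largest cluster mass (absolute value for two-tailed) in one map."""
    best = 0.0
    masks = [t_map > thr] if tail == "one" else [t_map > thr, t_map < -thr]
    for mask in masks:
        if not mask.any():
            continue
        for comp in _clusters_from_mask(mask, neighbors):
            best = max(best, abs(float(t_map[comp].sum())))
    return best


def _paired_t_maps(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized per-channel paired t for every sign-flip row.

    ``diffs`` is (n_participants, n_channels); ``signs`` is (n_perm,
    n_participants) of +/-1.  Sign flips leave the per-element squares
    unchanged, so only the means need recomputing.
    """
    n = diffs.shape[0]
    means = signs @ diffs / n
    sq = (diffs**2).sum(axis=0)
    var = (sq / n - means**2) * (n / (n - 1))
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def cluster_permutation(
    topo_a: np.ndarray,
    topo_b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    tail: str = "one",
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster-based permutation test between two paired topographies.

    Per-channel paired t-values are thresholded at the ``cluster_alpha``
    critical t (one- or two-tailed); suprathreshold channels are grouped
    into adjacency-connected clusters scored by their summed t (cluster
    mass); the null distribution of the maximal mass is built by
    sign-flipping the participant difference maps ``n_perm`` times.  The
    defaults (1000 permutations, one-tailed, alpha = cluster alpha =
    0.05) match the planned topographic analysis; ``alpha`` is only a
    convenience threshold for :meth:`ClusterResult.significant`.
    """
    a = np.asarray(topo_a, float)
    b = np.asarray(topo_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("topographies must be (n_participants, n_channels)")
    n, n_ch = a.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency shape must match the channel count")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    neighbors = _neighbor_lists(adjacency)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    diffs = a - b
    q = cluster_alpha if tail == "one" else cluster_alpha / 2.0
    thr = float(sps.t.ppf(1.0 - q, n - 1))

    t_obs = _paired_t_maps(diffs, np.ones((1, n)))[0]
    obs_masks = [t_obs > thr] if tail == "one" else [t_obs > thr, t_obs < -thr]
    clusters: list[np.ndarray] = []
    for mask in obs_masks:
        clusters.extend(_clusters_from_mask(mask, neighbors))
    masses = np.array([t_obs[c].sum() for c in clusters])

    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    t_null = _paired_t_maps(diffs, signs)
    null_max = np.array(
        [_signed_max_mass(t_null[i], thr, neighbors, tail) for i in range(n_perm)]
    )
    p_values = np.array(
        [
            (1.0 + np.sum(null_max >= abs(m))) / (n_perm + 1.0)
            for m in masses
        ]
    )
    return ClusterResult(clusters, masses, p_values, t_obs, thr, null_max)


# ------------------------------------------------------- phase-bin analysis


def phase_bins(n_bins: int = 6, origin: float = -np.pi) -> np.ndarray:
    """Equidistant circular bin edges starting at ``origin`` (length n_bins+1)."""
    return origin + np.arange(n_bins + 1) * (2.0 * np.pi / n_bins)


def assign_phase_bins(
    phases: np.ndarray, n_bins: int = 6, origin: float = -np.pi
) -> np.ndarray:
    """Bin index in [0, n_bins) for each phase; bins partition the circle."""
    rel = np.mod(np.asarray(phases, float) - origin, 2.0 * np.pi)
    idx = np.floor(rel / (2.0 * np.pi / n_bins)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _inclusive_window_slice(
    times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Closed-interval sample selection snapped down to the grid.

    Index range ``[floor(start), floor(end)]`` on the sample grid; with
    the default 100 Hz axis this maps the 500 ms post-second-pulse span
    onto 51 samples.
    """
    dt = float(times[1] - times[0])
    i0 = int(np.floor((window[0] - times[0]) / dt + 1e-9))
    i1 = int(np.floor((window[1] - times[0]) / dt + 1e-9))
    if i0 < 0 or i1 >= times.size:
        raise ValueError("window extends beyond the epoch time axis")
    return np.arange(i0, i1 + 1)


def phase_bin_itpc(
    trial_phases: np.ndarray,
    trial_tf: TFMap,
    window: tuple[float, float] = (205.0, 705.0),
    freq: float = 10.0,
    channels: tuple[str, ...] = ("O2", "PO4"),
    n_bins: int = 6,
    origin: float = -np.pi,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin-wise ITPC time courses for one participant.

    Trials are partitioned into ``n_bins`` equal circular bins of their
    pre-burst phase; within each bin the ITPC at ``freq`` is computed per
    channel and time sample over the (closed) analysis window, then
    averaged over ``channels``.  Returns ``(itpc_bins, times, counts)``
    where ``itpc_bins`` is (n_bins, n_times); bins with fewer than two
    trials are flagged missing (NaN) for pairwise exclusion upstream.
    """
    phases = np.asarray(trial_phases, float)
    if trial_tf.data.ndim != 4 or phases.size != trial_tf.data.shape[0]:
        raise ValueError("need one pre-burst phase per trial in the TFMap")
    fi = trial_tf.freq_index(freq)
    ti = _inclusive_window_slice(trial_tf.times, window)
    ch_idx = [trial_tf.ch_names.index(c) for c in channels]
    coefs = trial_tf.data[:, ch_idx, fi, :][:, :, ti]  # trials x ch x times
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = coefs / np.abs(coefs)
    phasors[~np.isfinite(phasors)] = 0.0

    bins = assign_phase_bins(phases, n_bins, origin)
    counts = np.bincount(bins, minlength=n_bins)
    out = np.full((n_bins, ti.size), np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.sum() >= 2:
            out[b] = np.abs(phasors[sel].mean(axis=0)).mean(axis=0)
    return out, trial_tf.times[ti], counts


@dataclass
class SineFit:
    """Canonical sine-regression solution ``y = a*sin(f*x*pi/3 + phi) + c``.

    Canonical form: ``a >= 0`` and ``phi`` in [0, 2pi).  ``flat`` marks a
    degenerate fit (amplitude below tolerance); in that case a = 0 and c
    is the mean of the input.
    """

    a: float
    f: float
    phi: float
    c: float
    sse: float
    r2: float
    flat: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return self.a * np.sin(self.f * x * np.pi / 3.0 + self.phi) + self.c


def _sine_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, f, phi, c = params
    return a * np.sin(f * x * np.pi / 3.0 + phi) + c


def sine_regression(
    bin_means: np.ndarray, amplitude_tol: float = 1e-10
) -> SineFit:
    """Nonlinear least-squares sine fit over bin number x = 1..n_bins.

    Multi-start over phase offsets {0, pi/2, pi, 3pi/2} and frequencies
    {0.5, 1, 2} cycles-per-six-bins; the best-SSE solution is returned in
    canonical form (a >= 0, phi in [0, 2pi)).  A flat input, or a best
    fit whose amplitude is below tolerance, returns the a = 0 flat
    solution with c at the mean.
    """
    y = np.asarray(bin_means, float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("need a 1-D vector of at least 4 bin means")
    x = np.arange(1.0, y.size + 1.0)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < amplitude_tol**2:
        return SineFit(0.0, 1.0, 0.0, float(y.mean()), 0.0, 0.0, flat=True)

    a0 = max((y.max() - y.min()) / 2.0, 1e-6)
    best = None
    for f0 in (0.5, 1.0, 2.0):
        for phi0 in (0.0, np.pi / 2.0, np.pi, 1.5 * np.pi):
            res = optimize.least_squares(
                lambda p: _sine_model(p, x) - y,
                x0=[a0, f0, phi0, float(y.mean())],
                # f below 0.5 cycles across the bins degenerates into a
                # huge-amplitude polynomial trend; exclude it so the fit
                # stays interpretable as cyclic modulation
                bounds=([0.0, 0.5, -np.inf, -np.inf], [np.inf, 3.0, np.inf, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            sse = float(np.sum(res.fun**2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, res.x)
    sse, (a, f, phi, c) = best
    if a < 0:  # defensive; bounds already keep a >= 0
        a, phi = -a, phi + np.pi
    phi = float(np.mod(phi, 2.0 * np.pi))
    if phi >= 2.0 * np.pi - 1e-9:  # snap float wrap-around to the canonical 0
        phi -= 2.0 * np.pi
    if a < amplitude_tol:
        return SineFit(0.0, 1.0, 0.0, float(y.mean()), sse, 0.0, flat=True)
    r2 = 1.0 - sse / sst
    return SineFit(float(a), float(f), phi, float(c), sse, float(r2))


def rm_anova_bins(table: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA over phase bins.

    ``table`` is (n_participants, n_bins) of bin-mean ITPC values with no
    missing cells.  Returns ``(F, (df_bins, df_error), p)`` with the
    standard degrees of freedom (n_bins - 1, (n_bins - 1)(n - 1)).
    """
    x = np.asarray(table, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("table must be (n_participants >= 2, n_bins >= 2)")
    if np.isnan(x).any():
        raise ValueError("missing cells; exclude participants upstream")
    n, b = x.shape
    grand = x.mean()
    ss_bins = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = b * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_bins - ss_subj
    df1, df2 = b - 1, (b - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        return 0.0, (df1, df2), 1.0
    f_stat = (ss_bins / df1) / ms_err
    p = float(sps.f.sf(f_stat, df1, df2))
    return float(f_stat), (df1, df2), p


# -------------------------------------------------------- IAF correlation


def correlate_iaf_itpc(
    iaf: np.ndarray, itpc_values: np.ndarray, entrain_freq: float = 10.0
) -> dict[str, tuple[float, float]]:
    """Pearson correlations of entrained ITPC with IAF and |IAF - 10 Hz|.

    ``itpc_values`` are per-participant means of the entrained ITPC
    (10 Hz, stimulated channels, W2-W6).  Returns ``{"iaf": (r, p),
    "abs_iaf_deviation": (r, p)}`` with two-tailed p-values.
    """
    x = np.asarray(iaf, float)
    y = np.asarray(itpc_values, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need matched per-participant vectors, n >= 3")
    out = {}
    for name, pred in (("iaf", x), ("abs_iaf_deviation", np.abs(x - entrain_freq))):
        if np.std(pred) == 0.0 or np.std(y) == 0.0:
            raise ValueError(f"zero variance makes the {name} correlation undefined")
        r, p = sps.pearsonr(pred, y)
        out[name] = (float(r), float(p))
    return out
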