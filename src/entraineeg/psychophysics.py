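"""Signal-detection measures and contrast-response fitting.

The behavioral task is a two-alternative tilt discrimination (clockwise
vs counterclockwise Gabor); treating "clockwise" as the signal class,
sensitivity and bias follow standard signal detection theory:
``d' = z(H) - z(FA)`` and criterion ``c = -(z(H) + z(FA)) / 2``.
Sensitivity as a function of Gabor contrast is summarized by the
Naka-Rushton saturating response ``d'(c) = dmax * c**n / (c**n + c50**n)``
whose half-of-max point defines the c50 contrast; the experimental
contrast is titrated on the fitted curve (by c50 or by a criterion
sensitivity level such as d' = 1.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm


def naka_rushton(
    contrast: float | np.ndarray, dmax: float, c50: float, exponent: float
) -> float | np.ndarray:
    """Saturating contrast-response function ``dmax * c**n / (c**n + c50**n)``."""
    c = np.asarray(contrast, float)
    cn = c**exponent
    out = dmax * cn / (cn + c50**exponent)
    return float(out) if np.isscalar(contrast) else out


def dprime_criterion(
    hits: int, misses: int, fas: int, crs: int, correction: bool = True
) -> tuple[float, float]:
    """Sensitivity d' and criterion c from a 2x2 response count table.

    When any rate is exactly 0 or 1 and ``correction`` is enabled, the
    log-linear rule is applied: 0.5 is added to every cell (so 1 to each
    denominator) before computing rates, keeping the z-transform finite.
    """
    for name, v in (("hits", hits), ("misses", misses), ("fas", fas), ("crs", crs)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal == 0 or n_noise == 0:
        raise ValueError("both signal and noise classes need at least one trial")
    h = hits / n_signal
    fa = fas / n_noise
    if correction and (h in (0.0, 1.0) or fa in (0.0, 1.0)):
        h = (hits + 0.5) / (n_signal + 1.0)
        fa = (fas + 0.5) / (n_noise + 1.0)
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    return float(zh - zfa), float(-(zh + zfa) / 2.0)


def response_table_counts(
    table: pd.DataFrame, signal_class: str = "cw"
) -> tuple[int, int, int, int]:
    """(hits, misses, fas, crs) from a per-trial signal/response table."""
    sig = table["signal"] == signal_class
    resp = table["response"] == signal_class
    return (
        int((sig & resp).sum()),
        int((sig & ~resp).sum()),
        int((~sig & resp).sum()),
        int((~sig & ~resp).sum()),
    )


@dataclass
class NakaRushtonFit:
    """Fitted contrast-response parameters.

    By construction the fitted curve evaluated at ``c50`` equals
    ``dmax / 2`` (the half-of-max definition of c50).
    """

    dmax: float
    c50: float
    exponent: float
    sse: float
    converged: bool = True

    def predict(self, contrast: float | np.ndarray) -> float | np.ndarray:
        return naka_rushton(contrast, self.dmax, self.c50, self.exponent)

    def contrast_at(self, dprime: float) -> float:
        """Invert the fitted curve: contrast attaining ``dprime``.

        Used to titrate the experimental contrast to a criterion
        sensitivity (e.g. d' = 1.2).
        """
        if not 0.0 < dprime < self.dmax:
            raise ValueError("dprime must lie strictly between 0 and dmax")
        ratio = dprime / (self.dmax - dprime)
        return float(self.c50 * ratio ** (1.0 / self.exponent))


def fit_naka_rushton(
    contrasts: np.ndarray, dprimes: np.ndarray
) -> NakaRushtonFit:
    """Least-squares Naka-Rushton fit of d' against contrast.

    Fitting runs in log-contrast space for conditioning, with
    multi-start over exponents {1, 2, 3}.  A fit that fails to converge
    from every start is returned with ``converged=False`` and the least
    bad parameters found.
    """
    c = np.asarray(contrasts, float)
    d = np.asarray(dprimes, float)
    if c.shape != d.shape or c.ndim != 1:
        raise ValueError("contrasts and dprimes must be matched 1-D vectors")
    if c.size < 4:
        raise ValueError("need at least 4 contrast levels")
    if np.any(c <= 0.0) or np.any(c > 1.0):
        raise ValueError("contrasts must lie in (0, 1]")
    log_c = np.log(c)

    def model(params: np.ndarray) -> np.ndarray:
        dmax, log_c50, n = params
        return dmax / (1.0 + np.exp(-n * (log_c - log_c50)))

    dmax0 = max(float(d.max()), 0.1)
    c50_0 = float(np.median(c))
    best, ok = None, False
    for n0 in (1.0, 2.0, 3.0):
        res = optimize.least_squares(
            lambda p: model(p) - d,
            x0=[dmax0, np.log(c50_0), n0],
            bounds=([1e-6, np.log(1e-4), 0.2], [np.inf, 0.0, 10.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, res.x)
            ok = res.success
    sse, (dmax, log_c50, n) = best
    return NakaRushtonFit(float(dmax), float(np.exp(log_c50)), float(n), sse, ok)
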