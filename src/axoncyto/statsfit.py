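"""Lognormal population statistics for axon morphometry.

Axonal cross-sectional areas, best-fit diameters and tortuosities are
strongly right-skewed and are conventionally summarised by a lognormal
distribution with log-scale parameters (μ, σ):

    mode  v0 = exp(μ − σ²)
    median x̃ = exp(μ)
    arithmetic mean  = exp(μ + σ²/2)
    arithmetic SD    = mean · sqrt(exp(σ²) − 1)

The module fits by closed-form maximum likelihood on ln(x), inverts
(mode, median) pairs back to (μ, σ) so that tract parameter sets can be
built from published summary values, runs the moment-agreement consistency
check (fit-implied arithmetic moments vs the sample's own), and prepares
Q-Q data of ln(x) against the standard normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "LognormalFit",
    "QQData",
    "fit_lognormal",
    "moment_consistency",
    "mode_median_to_params",
    "qq_lognormal",
    "density_histogram",
]


@dataclass(frozen=True)
class LognormalFit:
    """A fitted lognormal and its derived summary quantities."""

    mu: float
    sigma: float
    n: int
    mode: float
    median: float
    arith_mean: float
    arith_sd: float


@dataclass(frozen=True)
class QQData:
    """Sorted ln-sample quantiles vs standard-normal plotting positions."""

    sample_quantiles: np.ndarray
    theoretical_quantiles: np.ndarray
    slope: float
    intercept: float


def _validate_positive(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size and not np.all(x > 0):
        raise ValueError("all samples must be strictly positive")
    return x


def fit_lognormal(samples) -> LognormalFit:
    """Closed-form MLE of a lognormal: μ = mean(ln x), σ² = mean((ln x − μ)²).

    The divisor-n (biased) variance is the maximum-likelihood estimate.
    Requires n ≥ 10 and a non-degenerate sample (σ must be positive for the
    mode < median < mean ordering to hold).
    """
    x = _validate_positive(samples)
    if x.size < 10:
        raise ValueError(f"need at least 10 samples, got {x.size}")
    lx = np.log(x)
    mu = float(lx.mean())
    sigma = float(np.sqrt(np.mean((lx - mu) ** 2)))
    if sigma < 1e-12:
        raise ValueError("degenerate sample: sigma must be > 0")
    mean = math.exp(mu + sigma**2 / 2)
    return LognormalFit(
        mu=mu,
        sigma=sigma,
        n=int(x.size),
        mode=math.exp(mu - sigma**2),
        median=math.exp(mu),
        arith_mean=mean,
        arith_sd=mean * math.sqrt(math.expm1(sigma**2)),
    )


def moment_consistency(
    samples, fit: LognormalFit, tol: float = 0.10
) -> tuple[bool, float, float]:
    """Compare fit-implied arithmetic moments with the sample's own.

    Agreement of exp(μ + σ²/2) and its SD with the plain sample mean and SD
    is the working criterion that the lognormal is an adequate description
    of the data.  Returns ``(passed, rel_err_mean, rel_err_sd)`` with the
    relative errors taken against the direct sample moments.
    """
    x = _validate_positive(samples)
    m, s = float(x.mean()), float(x.std(ddof=1))
    err_mean = abs(fit.arith_mean - m) / m
    err_sd = abs(fit.arith_sd - s) / s if s > 0 else float("inf")
    return (err_mean <= tol and err_sd <= tol), err_mean, err_sd


def mode_median_to_params(mode: float, median: float) -> tuple[float, float]:
    """Invert (mode, median) to the log-scale parameters (μ, σ).

    μ = ln(median), σ = sqrt(ln(median/mode)); requires 0 < mode < median,
    which any lognormal with σ > 0 satisfies.
    """
    if not 0 < mode < median:
        raise ValueError("require 0 < mode < median for a lognormal")
    return math.log(median), math.sqrt(math.log(median / mode))


def qq_lognormal(samples) -> QQData:
    """Q-Q data of ln(samples) against the standard normal.

    Plotting positions (i − 0.5)/n; the reference line uses the sample mean
    and SD of ln(x), so lognormal data fall on it up to sampling noise.
    """
    x = _validate_positive(samples)
    if x.size < 10:
        raise ValueError(f"need at least 10 samples, got {x.size}")
    lx = np.sort(np.log(x))
    n = lx.size
    theo = _st.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return QQData(
        sample_quantiles=lx,
        theoretical_quantiles=theo,
        slope=float(lx.std(ddof=0)),
        intercept=float(lx.mean()),
    )


def density_histogram(samples, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram normalised to a probability density (Σ density·width = 1)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(samples, dtype=float).ravel()
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    density, edges = np.histogram(x, bins=edges, density=True)
    return edges, density
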