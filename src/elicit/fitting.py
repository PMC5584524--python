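"""Fit a smooth beta distribution to an elicited or pooled histogram.

Elicited histograms for bounded proportions are conventionally smoothed
with a beta distribution before entering a decision model.  Two fitters are
provided: a closed-form method-of-moments fit, and the default least-squares
fit that matches the beta's bin masses (CDF increments over the histogram's
edges) to the histogram's probabilities.  The beta lives on the full
normalized [0, 1] scale — mass outside the expert's stated [L, H] support is
permitted in the smooth fit and shows up in the goodness-of-fit discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .hybrid import HistogramDistribution, histogram_moments
from .quantities import EncodingError


class FitError(RuntimeError):
    """Raised when no valid beta fit exists or the optimizer fails."""

    def __init__(self, message: str, fallback: "FittedBeta | None" = None):
        super().__init__(message)
        self.fallback = fallback


@dataclass(frozen=True)
class FittedBeta:
    """A fitted beta distribution with its goodness of fit.

    ``gof`` is the sum of squared differences between the beta's bin masses
    and the histogram probabilities over the four bins; it is zero iff the
    beta reproduces every bin mass exactly.
    """

    alpha: float
    beta: float
    support: tuple[float, float] = (0.0, 1.0)
    method: str = "least_squares"
    gof: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise EncodingError(
                f"beta parameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        a, b = self.alpha, self.beta
        return a * b / ((a + b) ** 2 * (a + b + 1))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def distribution(self):
        """The fitted distribution as a frozen ``scipy.stats.beta``."""
        lo, hi = self.support
        return stats.beta(self.alpha, self.beta, loc=lo, scale=hi - lo)


def _bin_gof(alpha: float, beta: float, edges: np.ndarray, probs: np.ndarray) -> float:
    masses = np.diff(stats.beta.cdf(edges, alpha, beta))
    return float(np.sum((masses - probs) ** 2))


def beta_bin_masses(alpha: float, beta: float, edges) -> np.ndarray:
    """Beta(alpha, beta) probability mass in each bin of ``edges``."""
    return np.diff(stats.beta.cdf(np.asarray(edges, dtype=float), alpha, beta))


def moments_to_beta(mean: float, variance: float) -> tuple[float, float]:
    """Solve (alpha, beta) from a mean and variance on [0, 1].

    Requires 0 < variance < mean * (1 - mean); outside that region no beta
    has those moments.
    """
    m, v = float(mean), float(variance)
    if not 0.0 < m < 1.0:
        raise FitError(f"mean must lie strictly inside (0, 1), got {m:g}")
    if v <= 0.0:
        raise FitError(f"degenerate distribution: variance {v:g} is not positive")
    bound = m * (1.0 - m)
    if v >= bound:
        raise FitError(
            f"no valid beta: variance {v:g} >= mean*(1-mean) = {bound:g}"
        )
    nu = bound / v - 1.0  # alpha + beta
    return m * nu, (1.0 - m) * nu


def fit_beta_moments(h: HistogramDistribution) -> FittedBeta:
    """Method-of-moments beta fit to a histogram on [0, 1]."""
    _check_unit_support(h)
    mean, var = histogram_moments(h)
    alpha, beta = moments_to_beta(mean, var)
    gof = _bin_gof(alpha, beta, h.edges, h.probs)
    return FittedBeta(alpha=alpha, beta=beta, method="moments", gof=gof)


def fit_beta_bins(
    edges,
    probs,
    *,
    start: tuple[float, float] | None = None,
    tol: float = 1e-10,
) -> FittedBeta:
    """Least-squares beta fit to raw bin masses over arbitrary edges.

    Minimizes ``sum_i (BetaCDF(e_{i+1}) - BetaCDF(e_i) - probs_i)^2``.  The
    ``probs`` need not sum to one: this low-level entry point also serves
    recovery tests against exact (untruncated) beta bin masses.  Parameters
    are optimized on the log scale to keep them positive.
    """
    edges = np.asarray(edges, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if edges.ndim != 1 or len(edges) != len(probs) + 1:
        raise EncodingError("need len(edges) == len(probs) + 1")
    if not np.all(np.diff(edges) > 0):
        raise EncodingError(f"edges must be strictly increasing: {edges}")

    if start is None:
        start = (2.0, 2.0)

    def residuals(theta):
        a, b = np.exp(theta)
        return np.diff(stats.beta.cdf(edges, a, b)) - probs

    x0 = np.log(np.asarray(start, dtype=float))
    try:
        res = optimize.least_squares(
            residuals, x0, method="lm", ftol=tol, xtol=1e-14, gtol=tol, max_nfev=5000
        )
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"optimizer failed: {exc}") from exc
    alpha, beta = np.exp(res.x)
    gof = float(2.0 * res.cost)  # least_squares cost is half the sum of squares
    return FittedBeta(alpha=float(alpha), beta=float(beta), method="least_squares", gof=gof)


def fit_beta_ls(h: HistogramDistribution) -> FittedBeta:
    """Default beta fit: least squares on bin masses, moment fit as start.

    The optimizer is started at the method-of-moments fit (falling back to
    Beta(2, 2) when the moments admit no beta), so its discrepancy can never
    exceed the moment fit's.  On optimizer failure a :class:`FitError` is
    raised carrying the moment fit as a fallback suggestion.
    """
    _check_unit_support(h)
    start_fit = None
    try:
        start_fit = fit_beta_moments(h)
        start = (start_fit.alpha, start_fit.beta)
    except FitError:
        start = (2.0, 2.0)
    try:
        fitted = fit_beta_bins(h.edges, h.probs, start=start)
    except FitError as exc:
        raise FitError(str(exc), fallback=start_fit) from exc
    if start_fit is not None and fitted.gof > start_fit.gof:
        # keep the better of the two; the optimizer cannot be allowed to
        # return a worse point than its own starting value
        return FittedBeta(
            alpha=start_fit.alpha,
            beta=start_fit.beta,
            method="least_squares",
            gof=start_fit.gof,
        )
    return fitted


def fit_beta(h: HistogramDistribution, method: str = "least_squares", family: str = "beta") -> FittedBeta:
    """Family-dispatching fitter front end (only the beta family is implemented)."""
    if family != "beta":
        raise NotImplementedError(f"only the beta family is implemented, got {family!r}")
    if method == "least_squares":
        return fit_beta_ls(h)
    if method == "moments":
        return fit_beta_moments(h)
    raise ValueError(f"unknown method {method!r}")


def _check_unit_support(h: HistogramDistribution) -> None:
    lo, hi = h.support
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        raise EncodingError(
            f"histogram support [{lo:g}, {hi:g}] must lie within [0, 1]; "
            "normalize the quantity scale first"
        )
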