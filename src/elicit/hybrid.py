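"""Hybrid-method ("four complementary intervals") encoding.

The expert states a lower plausible limit L, a mode M and an upper plausible
limit H for a bounded quantity, then allocates probability to the four
intervals obtained by halving [L, M] and [M, H].  This module turns those
answers into a piecewise-constant (histogram) probability density and
computes its exact moments.  Outside [L, H] the density is zero: the stated
plausible limits are hard support bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quantities import EncodingError, QuantityDefinition

#: tolerance on probability normalization after conversion to fractions
PROB_TOL = 1e-9


@dataclass(frozen=True)
class HybridSummaries:
    """One expert's raw hybrid-method answer.

    ``L``, ``M``, ``H`` are on the quantity scale; ``p`` holds the four
    interval probabilities as fractions in [0, 1] summing to one.
    Use :func:`probabilities_from_percent` to convert typed percentages.
    """

    L: float
    M: float
    H: float
    p: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not self.L < self.M:
            raise EncodingError(f"L < M violated: L={self.L}, M={self.M}")
        if not self.M < self.H:
            raise EncodingError(f"M < H violated: M={self.M}, H={self.H}")
        p = tuple(float(x) for x in self.p)
        if len(p) != 4:
            raise EncodingError(f"expected 4 interval probabilities, got {len(p)}")
        if any(x < 0 for x in p):
            raise EncodingError(f"negative interval probability in {p}")
        if abs(sum(p) - 1.0) > PROB_TOL:
            raise EncodingError(
                f"interval probabilities must sum to 1, got {sum(p):.12g}"
            )
        object.__setattr__(self, "p", p)

    @property
    def range(self) -> float:
        """The stated plausible range H - L."""
        return self.H - self.L

    def normalized(self, quantity: QuantityDefinition) -> "HybridSummaries":
        """Return the same answer mapped onto the unit interval."""
        return HybridSummaries(
            L=quantity.to_normalized(self.L),
            M=quantity.to_normalized(self.M),
            H=quantity.to_normalized(self.H),
            p=self.p,
        )


def probabilities_from_percent(percents, *, integers_exact: bool = True):
    """Convert four typed percentages to fractions summing to 1.

    Experts type whole (or occasionally decimal) percentages.  Integer input
    must sum to exactly 100; decimal input is accepted to within 1e-6.
    """
    vals = [float(v) for v in percents]
    if len(vals) != 4:
        raise EncodingError(f"expected 4 percentages, got {len(vals)}")
    total = sum(vals)
    all_int = all(float(v).is_integer() for v in vals)
    tol = 0.0 if (all_int and integers_exact) else 1e-6
    if abs(total - 100.0) > tol:
        raise EncodingError(f"percentages must sum to 100, got {total:.8g}")
    frac = [v / total for v in vals]  # renormalise away decimal round-off
    return tuple(frac)


def bin_edges(L: float, M: float, H: float) -> np.ndarray:
    """The five bin edges of the hybrid method: [L, M] and [M, H] each halved."""
    if not L < M:
        raise EncodingError(f"L < M violated: L={L}, M={M}")
    if not M < H:
        raise EncodingError(f"M < H violated: M={M}, H={H}")
    return np.array([L, (L + M) / 2.0, M, (M + H) / 2.0, H], dtype=float)


@dataclass(frozen=True)
class HistogramDistribution:
    """Piecewise-constant density over the four hybrid bins.

    ``densities[i] * widths[i] == probs[i]`` by construction and the density
    integrates to one over ``[edges[0], edges[4]]``; it is zero outside.
    """

    edges: np.ndarray
    probs: np.ndarray
    scale: QuantityDefinition | None = None
    #: the expert's stated mode M, when built from hybrid summaries
    stated_mode: float | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if edges.shape != (5,) or probs.shape != (4,):
            raise EncodingError(
                f"need 5 edges and 4 probabilities, got {edges.shape}, {probs.shape}"
            )
        if not np.all(np.diff(edges) > 0):
            raise EncodingError(f"edges must be strictly increasing: {edges}")
        if np.any(probs < 0):
            raise EncodingError(f"negative bin probability in {probs}")
        if abs(probs.sum() - 1.0) > PROB_TOL:
            raise EncodingError(f"bin probabilities must sum to 1, got {probs.sum():.12g}")
        edges.setflags(write=False)
        probs.setflags(write=False)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "probs", probs)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def densities(self) -> np.ndarray:
        return self.probs / self.widths

    @property
    def support(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])

    def pdf(self, x) -> np.ndarray:
        """Evaluate the piecewise-constant density (zero outside [L, H]).

        At interior bin edges the value of the upper bin is used; the two
        support endpoints belong to the outermost bins.
        """
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.edges, x, side="right") - 1
        idx = np.clip(idx, 0, 3)
        out = self.densities[idx]
        return np.where((x >= self.edges[0]) & (x <= self.edges[-1]), out, 0.0)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.probs)])
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1, 0, 3)
        within = cum[idx] + self.densities[idx] * (x - self.edges[idx])
        out = np.where(x <= self.edges[0], 0.0, np.where(x >= self.edges[-1], 1.0, within))
        return out


def build_histogram(
    summaries: HybridSummaries, quantity: QuantityDefinition | None = None
) -> HistogramDistribution:
    """Encode a hybrid answer as a normalized histogram on the unit interval.

    If ``quantity`` is given, L/M/H (stated on the quantity scale) are mapped
    onto [0, 1] first so that fitting and pooling share a single code path.
    """
    s = summaries if quantity is None else summaries.normalized(quantity)
    if quantity is not None:
        if s.L < -PROB_TOL or s.H > 1.0 + PROB_TOL:
            raise EncodingError(
                f"summaries outside quantity scale: L={summaries.L}, H={summaries.H}, "
                f"scale [{quantity.scale_min}, {quantity.scale_max}]"
            )
    edges = bin_edges(s.L, s.M, s.H)
    return HistogramDistribution(
        edges=edges, probs=np.asarray(s.p), scale=quantity, stated_mode=s.M
    )


def histogram_moments(h: HistogramDistribution) -> tuple[float, float]:
    """Exact (mean, variance) of the piecewise-uniform density.

    Each bin contributes its uniform moments: a bin of midpoint ``c`` and
    width ``w`` has E[X] = c and E[X^2] = c^2 + w^2/12.
    """
    w = h.widths
    mid = (h.edges[:-1] + h.edges[1:]) / 2.0
    mean = float(np.sum(h.probs * mid))
    second = float(np.sum(h.probs * (mid**2 + w**2 / 12.0)))
    return mean, second - mean**2


def histogram_mode(h: HistogramDistribution) -> float:
    """The mode of the histogram.

    A histogram built from hybrid summaries reports the expert's stated M
    (it carries it as ``stated_mode``): M is where the expert placed the
    peak of their belief, and elicitation summaries report that statement,
    not a bin midpoint.  For an arbitrary histogram the midpoint of the
    highest-density bin is returned, ties broken toward the lowest bin
    (``argmax`` takes the first maximum).
    """
    if h.stated_mode is not None:
        return float(h.stated_mode)
    top = int(np.argmax(h.densities))
    return float((h.edges[top] + h.edges[top + 1]) / 2.0)
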