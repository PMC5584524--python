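"""Linear opinion pooling and panel/arm reporting.

Individual experts' histograms are combined by (weighted) arithmetic
averaging of their densities — the linear opinion pool.  Because each
expert's histogram has its own bin edges, members are averaged on a common
uniform grid over the normalized scale for plotting and export; pooled
moments, however, are computed from the exact mixture identities
(mixture mean = sum of weighted member means, and likewise for the second
moment), which are exact for piecewise-uniform members and do not inherit
grid-resolution error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hybrid import (
    HistogramDistribution,
    HybridSummaries,
    build_histogram,
    histogram_moments,
)
from .quantities import QuantityDefinition
from .validation import validate

#: number of grid points for the pooled density (export/plot resolution)
GRID_POINTS = 513


class PoolingError(ValueError):
    """Raised on empty panels, mismatched quantities or bad weights."""


@dataclass(frozen=True)
class PooledDistribution:
    """A linear opinion pool of expert histograms.

    ``grid``/``density`` tabulate the pooled density on the normalized
    scale (trapezoid-renormalized to integrate to one); ``mean`` and
    ``variance`` come from the exact mixture identities over the members.
    """

    grid: np.ndarray
    density: np.ndarray
    weights: np.ndarray
    source_ids: tuple
    mean: float
    variance: float
    members: tuple[HistogramDistribution, ...] = field(repr=False, default=())

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def pdf(self, x) -> np.ndarray:
        """Exact pooled density (weighted member mixture), not the grid tabulation."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, h in zip(self.weights, self.members):
            out = out + w * h.pdf(x)
        return out


def pool_linear(
    histograms: list[HistogramDistribution],
    weights=None,
    source_ids=None,
    n_grid: int = GRID_POINTS,
) -> PooledDistribution:
    """Arithmetically average expert histograms into one distribution.

    Weights default to equal; they are normalized to sum to one.  All
    members must be on the same quantity (same normalized scale).
    """
    if not histograms:
        raise PoolingError("cannot pool an empty panel")
    scales = {
        (h.scale.name, h.scale.scale_min, h.scale.scale_max)
        for h in histograms
        if h.scale is not None
    }
    if len(scales) > 1:
        raise PoolingError(f"histograms refer to different quantities: {sorted(scales)}")

    n = len(histograms)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise PoolingError(f"need {n} weights, got shape {w.shape}")
        if np.any(w < 0) or w.sum() <= 0:
            raise PoolingError("weights must be non-negative and not all zero")
    if source_ids is None:
        source_ids = tuple(range(n))

    # canonical member order so the pool is bit-for-bit invariant to how
    # the panel happened to be listed (float addition is order-sensitive)
    def _key(item):
        _, _, h = item
        return (h.edges.tobytes(), h.probs.tobytes())

    ordered = sorted(zip(w, source_ids, histograms), key=_key)
    w = np.array([wi for wi, _, _ in ordered])
    source_ids = tuple(sid for _, sid, _ in ordered)
    histograms = [h for _, _, h in ordered]
    w = w / w.sum()  # normalized after ordering so the sum is canonical too

    lo = min(h.edges[0] for h in histograms)
    hi = max(h.edges[-1] for h in histograms)
    lo, hi = min(lo, 0.0), max(hi, 1.0)  # full normalized scale
    grid = np.linspace(lo, hi, n_grid)
    density = np.zeros_like(grid)
    for wi, h in zip(w, histograms):
        density += wi * h.pdf(grid)
    integral = np.trapezoid(density, grid)
    if integral <= 0:
        raise PoolingError("pooled density integrates to zero")
    density = density / integral

    moments = [histogram_moments(h) for h in histograms]
    means = np.array([m for m, _ in moments])
    seconds = np.array([v + m**2 for m, v in moments])
    mean = float(np.sum(w * means))
    variance = float(np.sum(w * seconds) - mean**2)

    return PooledDistribution(
        grid=grid,
        density=density,
        weights=w,
        source_ids=source_ids,
        mean=mean,
        variance=variance,
        members=tuple(histograms),
    )


@dataclass(frozen=True)
class PanelSummary:
    """Descriptive summaries of one panel (one study arm)."""

    n_experts: int
    mean_of_modes: float
    min_mode: float
    max_mode: float
    mean_range: float
    pooled_mean: float
    pooled_sd: float
    quantity_name: str = ""

    def to_json(self) -> dict:
        return {
            "n_experts": self.n_experts,
            "mean_of_modes": self.mean_of_modes,
            "min_mode": self.min_mode,
            "max_mode": self.max_mode,
            "mean_range": self.mean_range,
            "pooled_mean": self.pooled_mean,
            "pooled_sd": self.pooled_sd,
            "quantity_name": self.quantity_name,
        }


def summarize_panel(
    panel: list[HybridSummaries], quantity: QuantityDefinition
) -> PanelSummary:
    """Summaries of a panel on the normalized scale.

    Every member must pass the consistency rules with no errors (warnings
    are the expert's to confirm during the session, not the panel's).
    Modes and ranges are reported on the normalized [0, 1] scale, matching
    how pooled proportions are conventionally reported.
    """
    if not panel:
        raise PoolingError("cannot summarize an empty panel")
    for i, s in enumerate(panel):
        report = validate(s.L, s.M, s.H, s.p, quantity)
        if not report.overall_valid:
            raise PoolingError(
                f"panel member {i} fails validation: {sorted(report.failed_errors)}"
            )
    norm = [s.normalized(quantity) for s in panel]
    # sorted before averaging: summaries are order-invariant bit-for-bit
    modes = np.sort([s.M for s in norm])
    ranges = np.sort([s.H - s.L for s in norm])
    pooled = pool_linear([build_histogram(s, quantity) for s in panel])
    return PanelSummary(
        n_experts=len(panel),
        mean_of_modes=float(modes.mean()),
        min_mode=float(modes.min()),
        max_mode=float(modes.max()),
        mean_range=float(ranges.mean()),
        pooled_mean=pooled.mean,
        pooled_sd=pooled.sd,
        quantity_name=quantity.name,
    )


def completion_rates(flow: dict[str, tuple[int, int]]) -> dict[str, float]:
    """Per-arm completion rate, in percent, from (randomised, completed) counts."""
    rates = {}
    for arm, (randomised, completed) in flow.items():
        if randomised < 1:
            raise PoolingError(f"arm {arm!r}: rate undefined for randomised={randomised}")
        if not 0 <= completed <= randomised:
            raise PoolingError(
                f"arm {arm!r}: completed={completed} outside [0, randomised={randomised}]"
            )
        rates[arm] = 100.0 * completed / randomised
    return rates


@dataclass(frozen=True)
class ArmContrast:
    """Difference table between two arms' panel summaries (A minus B)."""

    diff_mean_of_modes: float
    diff_mean_range: float
    diff_pooled_mean: float
    diff_pooled_sd: float
    smaller_sd_arm: str  # "A", "B" or "tie"

    def to_json(self) -> dict:
        return {
            "diff_mean_of_modes": self.diff_mean_of_modes,
            "diff_mean_range": self.diff_mean_range,
            "diff_pooled_mean": self.diff_pooled_mean,
            "diff_pooled_sd": self.diff_pooled_sd,
            "smaller_sd_arm": self.smaller_sd_arm,
        }


def compare_arms(summary_a: PanelSummary, summary_b: PanelSummary) -> ArmContrast:
    """Tabulate A-minus-B differences and flag the more certain (smaller-sd) arm."""
    if (
        summary_a.quantity_name
        and summary_b.quantity_name
        and summary_a.quantity_name != summary_b.quantity_name
    ):
        raise PoolingError(
            f"cannot compare arms on different quantities: "
            f"{summary_a.quantity_name!r} vs {summary_b.quantity_name!r}"
        )
    if summary_a.pooled_sd < summary_b.pooled_sd:
        smaller = "A"
    elif summary_b.pooled_sd < summary_a.pooled_sd:
        smaller = "B"
    else:
        smaller = "tie"
    return ArmContrast(
        diff_mean_of_modes=summary_a.mean_of_modes - summary_b.mean_of_modes,
        diff_mean_range=summary_a.mean_range - summary_b.mean_range,
        diff_pooled_mean=summary_a.pooled_mean - summary_b.pooled_mean,
        diff_pooled_sd=summary_a.pooled_sd - summary_b.pooled_sd,
        smaller_sd_arm=smaller,
    )
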