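"""Model/results surface over a panel of elicited summaries.

``ElicitationPanel`` plays the role of a model object built from data (a
panel of hybrid answers plus the quantity they concern); ``fit()`` encodes
every expert, fits per-expert betas, pools the panel by linear opinion
pooling, fits a beta to the pooled distribution and returns a
``PanelResults`` carrying estimates, spreads, diagnostics and a
``summary()`` table — the workflow a decision modeller runs between
receiving completed questionnaires and plugging a prior into an HTA model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitError, FittedBeta, fit_beta, moments_to_beta
from .hybrid import (
    HybridSummaries,
    build_histogram,
    histogram_mode,
    probabilities_from_percent,
)
from .pooling import PanelSummary, PooledDistribution, pool_linear, summarize_panel
from .quantities import QuantityDefinition
from .validation import validate


class ElicitationPanel:
    """A panel of experts' hybrid answers about one quantity.

    Parameters
    ----------
    panel : list of HybridSummaries
        One entry per expert, on the quantity scale.
    quantity : QuantityDefinition
        The elicited quantity (bounded scale).
    expert_ids : sequence, optional
        Identifiers used in reports; defaults to 1..n.
    """

    def __init__(self, panel, quantity: QuantityDefinition, expert_ids=None):
        if not panel:
            raise ValueError("panel must contain at least one expert")
        self.panel = list(panel)
        self.quantity = quantity
        self.expert_ids = (
            list(expert_ids) if expert_ids is not None else list(range(1, len(panel) + 1))
        )
        if len(self.expert_ids) != len(self.panel):
            raise ValueError("expert_ids length must match the panel")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, quantity: QuantityDefinition
    ) -> "ElicitationPanel":
        """Build from a panel frame with columns expert_id, L, M, H, p1..p4 (%)."""
        panel, ids = [], []
        for _, row in df.iterrows():
            p = probabilities_from_percent([row[f"p{i + 1}"] for i in range(4)])
            panel.append(HybridSummaries(L=float(row.L), M=float(row.M), H=float(row.H), p=p))
            ids.append(row.get("expert_id", len(ids) + 1))
        return cls(panel, quantity, expert_ids=ids)

    def validate(self):
        """Consistency reports for every expert (keyed by expert id)."""
        return {
            eid: validate(s.L, s.M, s.H, s.p, self.quantity)
            for eid, s in zip(self.expert_ids, self.panel)
        }

    def fit(self, method: str = "least_squares", weights=None) -> "PanelResults":
        """Encode, fit and pool the panel."""
        histograms = [build_histogram(s, self.quantity) for s in self.panel]
        expert_fits = []
        for h in histograms:
            try:
                expert_fits.append(fit_beta(h, method=method))
            except FitError as exc:
                expert_fits.append(exc.fallback)
        pooled = pool_linear(histograms, weights=weights, source_ids=tuple(self.expert_ids))
        summary = summarize_panel(self.panel, self.quantity)
        try:
            a, b = moments_to_beta(pooled.mean, pooled.variance)
            pooled_fit = FittedBeta(alpha=a, beta=b, method="moments", gof=float("nan"))
        except FitError:
            pooled_fit = None
        return PanelResults(
            model=self,
            histograms=histograms,
            expert_fits=expert_fits,
            pooled=pooled,
            panel_summary=summary,
            pooled_fit=pooled_fit,
            method=method,
        )


@dataclass
class PanelResults:
    """Fitted panel: per-expert betas, the linear pool and its summaries."""

    model: ElicitationPanel
    histograms: list
    expert_fits: list
    pooled: PooledDistribution
    panel_summary: PanelSummary
    pooled_fit: FittedBeta | None
    method: str

    @property
    def pooled_mean(self) -> float:
        return self.pooled.mean

    @property
    def pooled_sd(self) -> float:
        return self.pooled.sd

    def expert_table(self) -> pd.DataFrame:
        """Per-expert normalized summaries and fitted beta parameters."""
        rows = []
        q = self.model.quantity
        for eid, s, h, f in zip(
            self.model.expert_ids, self.model.panel, self.histograms, self.expert_fits
        ):
            n = s.normalized(q)
            rows.append(
                {
                    "expert_id": eid,
                    "L": n.L,
                    "mode": histogram_mode(h),
                    "H": n.H,
                    "range": n.H - n.L,
                    "alpha": np.nan if f is None else f.alpha,
                    "beta": np.nan if f is None else f.beta,
                    "gof": np.nan if f is None else f.gof,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """A readable report of the panel fit."""
        s = self.panel_summary
        lines = [
            "Elicitation panel results",
            "=" * 60,
            f"Quantity:            {self.model.quantity.name}",
            f"Experts:             {s.n_experts}",
            f"Fitting method:      {self.method}",
            "-" * 60,
            f"Mean of modes:       {s.mean_of_modes:.3f}  "
            f"(min {s.min_mode:.3f}, max {s.max_mode:.3f})",
            f"Mean range (H-L):    {s.mean_range:.3f}",
            f"Pooled mean:         {s.pooled_mean:.3f}",
            f"Pooled sd:           {s.pooled_sd:.3f}",
        ]
        if self.pooled_fit is not None:
            lines.append(
                f"Pooled beta fit:     alpha={self.pooled_fit.alpha:.3f}, "
                f"beta={self.pooled_fit.beta:.3f}"
            )
        lines.append("-" * 60)
        tbl = self.expert_table()
        with pd.option_context("display.float_format", "{:.3f}".format):
            lines.append(tbl.to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot member densities, the pooled density and the pooled beta fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.pooled.grid
        for h in self.histograms:
            ax.plot(x, h.pdf(x), color="0.7", lw=0.8)
        ax.plot(x, self.pooled.density, color="C0", lw=2, label="linear pool")
        if self.pooled_fit is not None:
            ax.plot(
                x,
                self.pooled_fit.distribution().pdf(x),
                color="C1",
                lw=2,
                ls="--",
                label=f"Beta({self.pooled_fit.alpha:.2f}, {self.pooled_fit.beta:.2f})",
            )
        ax.set_xlabel(f"{self.model.quantity.name} (normalized)")
        ax.set_ylabel("density")
        ax.legend()
        return ax
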