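"""Synthetic expert panels with known ground-truth beliefs.

Each simulated expert holds a true belief that is a beta distribution; the
panel shares a common "truth" whose mean is jittered between experts
(variance held fixed).  The expert answers the hybrid questionnaire the way
a careful human would: L and H are tail quantiles of their true belief, M is
its true mode, and the four interval probabilities are the true bin masses
renormalized to the stated [L, H] support — optionally rounded to whole
percentages (largest-remainder repair so they always sum to exactly 100%),
which is the granularity people actually type.

Defaults reflect a small primary-care panel asked for the proportion of
patients who would change their drinking after advice: a truth centred near
0.38 with sd about 0.18, panels of around 8-10 experts, and moderate
between-expert disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .hybrid import HybridSummaries, bin_edges
from .quantities import QuantityDefinition


class SimulationError(RuntimeError):
    """Raised when no feasible expert can be drawn."""


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of a simulated panel.

    Parameters
    ----------
    n_experts : int
        Panel size.
    truth_alpha, truth_beta : float
        The panel-level true belief, a Beta(alpha, beta) on [0, 1].
    between_expert_sd : float
        Standard deviation of the jitter applied to the truth's mean on the
        [0, 1] scale; each expert's belief keeps the truth's variance.
    tail_prob : float
        Quantile level used for the stated limits: L at ``tail_prob``,
        H at ``1 - tail_prob``.  Default 1%.
    percent_rounding : bool
        Round interval probabilities to integer percent with
        largest-remainder repair (sums to exactly 100).
    seed : int
        Base seed; every expert is deterministic given (seed, index).
    """

    n_experts: int = 8
    truth_alpha: float = 2.4
    truth_beta: float = 3.9
    between_expert_sd: float = 0.10
    tail_prob: float = 0.01
    percent_rounding: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise SimulationError("n_experts must be >= 1")
        if not (self.truth_alpha > 0 and self.truth_beta > 0):
            raise SimulationError("truth parameters must be positive")
        if self.between_expert_sd < 0:
            raise SimulationError("between_expert_sd must be non-negative")
        if not 0 < self.tail_prob < 0.5:
            raise SimulationError("tail_prob must lie in (0, 0.5)")


def round_to_integer_percent(fractions) -> tuple[int, ...]:
    """Round fractions to integer percentages summing to exactly 100.

    Largest-remainder (Hamilton) apportionment: floor everything, then give
    the leftover percentage points to the largest remainders; ties go to the
    lowest bin index for determinism.
    """
    f = np.asarray(fractions, dtype=float) * 100.0
    floors = np.floor(f).astype(int)
    remainder = f - floors
    missing = int(round(100 - floors.sum()))
    # stable argsort descending on remainder; ties resolved by index order
    order = np.argsort(-remainder, kind="stable")
    out = floors.copy()
    for i in order[:missing]:
        out[i] += 1
    return tuple(int(v) for v in out)


def _jittered_belief(spec: SimulationSpec, rng: np.random.Generator):
    """Draw one expert's true beta by jittering the truth's mean.

    The truth's variance is preserved by re-solving (alpha, beta) from the
    jittered mean; draws are rejected (up to 100 times) when the jittered
    moments admit no beta distribution.
    """
    a0, b0 = spec.truth_alpha, spec.truth_beta
    m0 = a0 / (a0 + b0)
    v0 = a0 * b0 / ((a0 + b0) ** 2 * (a0 + b0 + 1.0))
    if spec.between_expert_sd == 0:
        return a0, b0
    for _ in range(100):
        m = m0 + rng.normal(0.0, spec.between_expert_sd)
        if not 0.0 < m < 1.0:
            continue
        if v0 >= m * (1.0 - m):
            continue
        nu = m * (1.0 - m) / v0 - 1.0
        return m * nu, (1.0 - m) * nu
    raise SimulationError(
        "could not draw feasible jittered moments in 100 attempts; "
        "reduce between_expert_sd or the truth's variance"
    )


def simulate_expert(spec: SimulationSpec, index: int) -> HybridSummaries:
    """One simulated expert's hybrid answer, deterministic given (seed, index)."""
    rng = np.random.default_rng([spec.seed, index])
    a, b = _jittered_belief(spec, rng)
    belief = stats.beta(a, b)

    L = float(belief.ppf(spec.tail_prob))
    H = float(belief.ppf(1.0 - spec.tail_prob))
    if a > 1.0 and b > 1.0:
        M = float((a - 1.0) / (a + b - 2.0))
    else:
        # U-shaped or J-shaped beliefs have no interior mode; the mean is
        # the expert's stated best guess instead
        M = float(belief.mean())
    if not L < M < H:  # pragma: no cover - only for extreme tail_prob
        M = (L + H) / 2.0

    edges = bin_edges(L, M, H)
    masses = np.diff(belief.cdf(edges))
    p = masses / masses.sum()  # renormalize to the stated [L, H] support
    if spec.percent_rounding:
        pct = round_to_integer_percent(p)
        p = tuple(v / 100.0 for v in pct)
    else:
        p = tuple(float(v) for v in p)
    return HybridSummaries(L=L, M=M, H=H, p=p)


def simulate_panel(spec: SimulationSpec) -> list[HybridSummaries]:
    """The full panel of ``spec.n_experts`` simulated answers."""
    return [simulate_expert(spec, i) for i in range(spec.n_experts)]


def unit_quantity(name: str = "proportion") -> QuantityDefinition:
    """A [0, 1] proportion quantity, the scale simulated panels live on."""
    return QuantityDefinition(name=name, scale_min=0.0, scale_max=1.0)


def simulate_two_arm_study(
    spec_a: SimulationSpec,
    spec_b: SimulationSpec,
    completion_prob_b: float,
):
    """Emulate a two-arm elicitation study with incomplete follow-up in arm B.

    Arm A (facilitated) completes fully; each arm-B (distance) expert
    completes independently with probability ``completion_prob_b``.

    Returns
    -------
    (panel_a, panel_b, flow) where ``flow`` maps arm name to
    (randomised, completed) counts, ready for :func:`completion_rates`.
    """
    if not 0.0 <= completion_prob_b <= 1.0:
        raise SimulationError("completion_prob_b must lie in [0, 1]")
    panel_a = simulate_panel(spec_a)
    full_b = simulate_panel(spec_b)
    rng = np.random.default_rng([spec_b.seed, 2**20])  # completion draws
    completed_mask = rng.random(len(full_b)) < completion_prob_b
    panel_b = [s for s, done in zip(full_b, completed_mask) if done]
    flow = {
        "A": (len(panel_a), len(panel_a)),
        "B": (len(full_b), len(panel_b)),
    }
    return panel_a, panel_b, flow
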