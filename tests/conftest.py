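import numpy as np
import pytest

from elicit import HybridSummaries, QuantityDefinition, unit_quantity


@pytest.fixture
def unit_q() -> QuantityDefinition:
    return unit_quantity("proportion")


@pytest.fixture
def count_q() -> QuantityDefinition:
    return QuantityDefinition(
        name="count100",
        scale_min=0,
        scale_max=100,
        display_mode="count_out_of_n",
        n_total=100,
    )


def random_summaries(rng: np.random.Generator, lo=0.0, hi=1.0) -> HybridSummaries:
    """A random valid hybrid answer on [lo, hi]."""
    pts = np.sort(rng.uniform(lo, hi, size=3))
    while pts[0] >= pts[1] or pts[1] >= pts[2]:  # pragma: no cover
        pts = np.sort(rng.uniform(lo, hi, size=3))
    p = rng.dirichlet(np.ones(4))
    p = p / p.sum()
    return HybridSummaries(L=pts[0], M=pts[1], H=pts[2], p=tuple(p))


def quadrature_moments(h, n: int = 10_001):
    """Brute-force moments of a histogram density by fine quadrature.

    Integrates bin by bin so the discontinuities at bin edges never fall
    inside a quadrature panel.
    """
    mean = 0.0
    second = 0.0
    total = 0.0
    for i in range(4):
        x = np.linspace(h.edges[i], h.edges[i + 1], n)
        d = np.full_like(x, h.densities[i])
        total += np.trapezoid(d, x)
        mean += np.trapezoid(x * d, x)
        second += np.trapezoid(x**2 * d, x)
    return total, mean, second
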