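"""Linear opinion pooling, panel summaries, completion rates, arm contrast."""

import numpy as np
import pytest

from elicit import (
    HybridSummaries,
    PoolingError,
    build_histogram,
    compare_arms,
    completion_rates,
    histogram_moments,
    pool_linear,
    summarize_panel,
)

from conftest import random_summaries


def mixture_quadrature_moments(histograms, weights, n=200_001):
    """Oracle: fine quadrature of the exact weighted mixture density."""
    x = np.linspace(0.0, 1.0, n)
    fx = np.zeros_like(x)
    for w, h in zip(weights, histograms):
        fx += w * h.pdf(x)
    total = np.trapezoid(fx, x)
    mean = np.trapezoid(x * fx, x)
    second = np.trapezoid(x**2 * fx, x)
    return total, mean, second


class TestPoolLinear:
    def test_identical_members_pool_to_themselves(self, unit_q):
        s = HybridSummaries(0.2, 0.4, 0.8, (0.1, 0.4, 0.35, 0.15))
        h = build_histogram(s, unit_q)
        pooled = pool_linear([h, h])
        np.testing.assert_allclose(pooled.density, h.pdf(pooled.grid) /
                                   np.trapezoid(h.pdf(pooled.grid), pooled.grid))
        mean, var = histogram_moments(h)
        assert pooled.mean == pytest.approx(mean, abs=1e-12)
        assert pooled.variance == pytest.approx(var, abs=1e-12)

    def test_equal_weight_mean_is_average_of_member_means(self, unit_q):
        s1 = HybridSummaries(0.1, 0.3, 0.5, (0.1, 0.4, 0.4, 0.1))
        s2 = HybridSummaries(0.4, 0.6, 0.9, (0.2, 0.3, 0.3, 0.2))
        h1, h2 = build_histogram(s1, unit_q), build_histogram(s2, unit_q)
        pooled = pool_linear([h1, h2])
        m1, _ = histogram_moments(h1)
        m2, _ = histogram_moments(h2)
        assert pooled.mean == pytest.approx((m1 + m2) / 2, abs=1e-6)

    def test_pooled_grid_density_integrates_to_one(self, unit_q):
        rng = np.random.default_rng(3)
        hists = [build_histogram(random_summaries(rng), unit_q) for _ in range(8)]
        pooled = pool_linear(hists)
        assert np.trapezoid(pooled.density, pooled.grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(pooled.density >= 0)

    def test_mixture_moment_identities(self, unit_q):
        """Pooled mean and second moment equal the weighted member moments."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            k = rng.integers(1, 9)
            hists = [build_histogram(random_summaries(rng), unit_q) for _ in range(k)]
            w = rng.uniform(0.1, 1.0, size=k)
            pooled = pool_linear(hists, weights=w)
            w = w / w.sum()
            moments = [histogram_moments(h) for h in hists]
            mean = sum(wi * m for wi, (m, _) in zip(w, moments))
            second = sum(wi * (v + m**2) for wi, (m, v) in zip(w, moments))
            assert pooled.mean == pytest.approx(mean, abs=1e-6)
            assert pooled.variance + pooled.mean**2 == pytest.approx(second, abs=1e-6)

    def test_moments_match_mixture_quadrature(self, unit_q):
        rng = np.random.default_rng(23)
        hists = [build_histogram(random_summaries(rng), unit_q) for _ in range(6)]
        w = np.full(6, 1 / 6)
        pooled = pool_linear(hists)
        total, q_mean, q_second = mixture_quadrature_moments(hists, w)
        assert total == pytest.approx(1.0, abs=1e-4)
        assert pooled.mean == pytest.approx(q_mean, abs=1e-4)
        assert pooled.sd == pytest.approx(np.sqrt(q_second - q_mean**2), abs=1e-4)

    def test_permutation_invariance_bit_exact(self, unit_q):
        rng = np.random.default_rng(29)
        summaries = [random_summaries(rng) for _ in range(7)]
        hists = [build_histogram(s, unit_q) for s in summaries]
        a = pool_linear(hists)
        order = rng.permutation(7)
        b = pool_linear([hists[i] for i in order])
        assert np.array_equal(a.density, b.density)
        assert a.mean == b.mean and a.variance == b.variance
        sa = summarize_panel(summaries, unit_q)
        sb = summarize_panel([summaries[i] for i in order], unit_q)
        assert sa == sb

    def test_empty_panel_and_bad_weights_rejected(self, unit_q):
        with pytest.raises(PoolingError, match="empty"):
            pool_linear([])
        h = build_histogram(HybridSummaries(0.2, 0.4, 0.8, (0.25,) * 4), unit_q)
        with pytest.raises(PoolingError, match="weights"):
            pool_linear([h, h], weights=[0.0, 0.0])
        with pytest.raises(PoolingError, match="weights"):
            pool_linear([h], weights=[-1.0])

    def test_mismatched_quantities_rejected(self, unit_q, count_q):
        h1 = build_histogram(HybridSummaries(0.2, 0.4, 0.8, (0.25,) * 4), unit_q)
        h2 = build_histogram(HybridSummaries(20, 40, 80, (0.25,) * 4), count_q)
        with pytest.raises(PoolingError, match="different quantities"):
            pool_linear([h1, h2])


class TestSummarizePanel:
    def test_mode_arithmetic(self, unit_q):
        panel = [
            HybridSummaries(0.1, 0.2, 0.5, (0.1, 0.4, 0.4, 0.1)),
            HybridSummaries(0.2, 0.4, 0.6, (0.1, 0.4, 0.4, 0.1)),
            HybridSummaries(0.3, 0.6, 0.9, (0.1, 0.4, 0.4, 0.1)),
        ]
        s = summarize_panel(panel, unit_q)
        assert s.mean_of_modes == pytest.approx(0.4)
        assert s.min_mode == pytest.approx(0.2)
        assert s.max_mode == pytest.approx(0.6)
        assert s.mean_range == pytest.approx((0.4 + 0.4 + 0.6) / 3)
        assert s.min_mode <= s.mean_of_modes <= s.max_mode

    def test_single_expert_reduces_to_histogram_moments(self, unit_q):
        s0 = HybridSummaries(0.2, 0.4, 0.8, (0.1, 0.4, 0.35, 0.15))
        s = summarize_panel([s0], unit_q)
        mean, var = histogram_moments(build_histogram(s0, unit_q))
        assert s.pooled_mean == pytest.approx(mean, abs=1e-12)
        assert s.pooled_sd == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_pooled_sd_matches_mixture_quadrature(self, unit_q):
        rng = np.random.default_rng(101)
        panel = [random_summaries(rng) for _ in range(20)]
        s = summarize_panel(panel, unit_q)
        hists = [build_histogram(x, unit_q) for x in panel]
        _, q_mean, q_second = mixture_quadrature_moments(hists, np.full(20, 0.05))
        assert s.pooled_sd == pytest.approx(np.sqrt(q_second - q_mean**2), abs=1e-4)

    def test_invalid_member_rejected(self, unit_q):
        # stated limits outside the quantity scale: an ORDERING error
        panel = [HybridSummaries(-0.5, 0.4, 0.8, (0.25,) * 4)]
        with pytest.raises(PoolingError, match="fails validation"):
            summarize_panel(panel, unit_q)

    def test_empty_panel_rejected(self, unit_q):
        with pytest.raises(PoolingError, match="empty"):
            summarize_panel([], unit_q)


class TestCompletionRates:
    def test_study_flow_worked_example(self):
        rates = completion_rates({"face_to_face": (8, 8), "email": (10, 7)})
        assert rates["face_to_face"] == 100.0
        assert rates["email"] == 70.0

    def test_zero_completion(self):
        assert completion_rates({"arm": (5, 0)})["arm"] == 0.0

    def test_degenerate_counts_rejected(self):
        with pytest.raises(PoolingError, match="undefined"):
            completion_rates({"arm": (0, 0)})
        with pytest.raises(PoolingError, match="outside"):
            completion_rates({"arm": (5, 6)})


class TestCompareArms:
    def test_identical_panels_contrast_to_zero(self, unit_q):
        panel = [HybridSummaries(0.2, 0.4, 0.8, (0.1, 0.4, 0.35, 0.15))]
        a = summarize_panel(panel, unit_q)
        c = compare_arms(a, a)
        assert c.diff_mean_of_modes == 0
        assert c.diff_mean_range == 0
        assert c.diff_pooled_mean == 0
        assert c.diff_pooled_sd == 0
        assert c.smaller_sd_arm == "tie"

    def test_widened_arm_has_larger_range_and_sd(self, unit_q):
        """Widening every member's (H-L) symmetrically about M increases
        both the mean range and the pooled sd."""
        rng = np.random.default_rng(37)
        panel_a = []
        panel_b = []
        for _ in range(6):
            s = random_summaries(rng, lo=0.25, hi=0.75)
            panel_a.append(s)
            panel_b.append(
                HybridSummaries(L=s.L - 0.2, M=s.M, H=s.H + 0.2, p=s.p)
            )
        a = summarize_panel(panel_a, unit_q)
        b = summarize_panel(panel_b, unit_q)
        c = compare_arms(a, b)
        assert b.mean_range > a.mean_range
        assert b.pooled_sd > a.pooled_sd
        assert c.smaller_sd_arm == "A"
        assert c.diff_mean_range == pytest.approx(-0.4, abs=1e-9)

    def test_one_expert_arms_reduce_to_individual_difference(self, unit_q):
        s1 = HybridSummaries(0.1, 0.3, 0.5, (0.1, 0.4, 0.4, 0.1))
        s2 = HybridSummaries(0.4, 0.6, 0.9, (0.2, 0.3, 0.3, 0.2))
        a, b = summarize_panel([s1], unit_q), summarize_panel([s2], unit_q)
        c = compare_arms(a, b)
        m1, v1 = histogram_moments(build_histogram(s1, unit_q))
        m2, v2 = histogram_moments(build_histogram(s2, unit_q))
        assert c.diff_pooled_mean == pytest.approx(m1 - m2, abs=1e-12)
        assert c.diff_pooled_sd == pytest.approx(np.sqrt(v1) - np.sqrt(v2), abs=1e-12)
        assert c.diff_mean_of_modes == pytest.approx(0.3 - 0.6)

    def test_quantity_mismatch_rejected(self, unit_q, count_q):
        s = HybridSummaries(0.2, 0.4, 0.8, (0.1, 0.4, 0.35, 0.15))
        a = summarize_panel([s], unit_q)
        b = summarize_panel([HybridSummaries(20, 40, 80, s.p)], count_q)
        with pytest.raises(PoolingError, match="different quantities"):
            compare_arms(a, b)
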