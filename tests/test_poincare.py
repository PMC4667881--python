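"""Poincaré plot descriptors and the asymmetry partition.

The independent oracle rotates every (BT_n, BT_{n+1}) point by 45°:
the perpendicular coordinate's dispersion about the identity line gives
SD1, the along-line coordinate's sample standard deviation about the
centroid gives SD2.  The partition oracle accumulates the squared
contributions pair by pair.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermoloco as tl
from thermoloco.poincare import PoincareError

SQRT2 = math.sqrt(2.0)


def rotation_oracle(x, y):
    """Brute-force SD1/SD2 via explicit 45° rotation of each point."""
    perp = (x - y) / SQRT2  # signed distance to the identity line
    along = (x + y) / SQRT2
    n = x.size
    sd1 = math.sqrt(float(np.sum(perp**2)) / (n - 1))
    sd2 = math.sqrt(float(np.sum((along - along.mean()) ** 2)) / (n - 1))
    return sd1, sd2


def partition_oracle(x, y):
    """Pairwise accumulation of the decrease/increase partition."""
    n = x.size
    m = float(np.mean(np.concatenate([x, y])))
    s1d = s1i = s2d = s2i = 0.0
    for a, b in zip(x, y):
        delta = b - a
        d_sq = ((a + b - 2 * m) / SQRT2) ** 2
        if delta < 0:
            s1d += delta**2 / 2
            s2d += d_sq
        elif delta > 0:
            s1i += delta**2 / 2
            s2i += d_sq
        else:
            s2d += d_sq / 2
            s2i += d_sq / 2
    return (
        math.sqrt(s1d / (n - 1)),
        math.sqrt(s1i / (n - 1)),
        math.sqrt(s2d / (n - 1)),
        math.sqrt(s2i / (n - 1)),
    )


def random_series(seed, length=None):
    rng = np.random.default_rng(seed)
    if length is None:
        length = int(rng.integers(10, 721))
    return 37.0 + 0.3 * rng.standard_normal(length).cumsum() / math.sqrt(length)


class TestLaggedPairs:
    def test_three_samples_give_two_pairs(self):
        x, y = tl.lagged_pairs(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(x, [1.0, 2.0])
        np.testing.assert_array_equal(y, [2.0, 3.0])

    def test_720_samples_give_719_pairs(self):
        x, y = tl.lagged_pairs(np.full(720, 37.0))
        assert x.size == 719

    def test_pairs_spanning_missing_are_dropped(self):
        x, y = tl.lagged_pairs(np.array([37.0, np.nan, 37.2]))
        assert x.size == 0

    def test_too_short_series_raises(self):
        with pytest.raises(PoincareError):
            tl.lagged_pairs(np.array([37.0]))

    def test_lag_parameter(self):
        x, y = tl.lagged_pairs(np.arange(5.0), lag=2)
        np.testing.assert_array_equal(y - x, [2.0, 2.0, 2.0])


class TestSd1Sd2:
    def test_constant_series_is_zero(self):
        d = tl.poincare_descriptors(np.full(100, 37.0))
        assert d.sd1 == d.sd2 == d.sdnn == 0.0

    def test_alternating_series_closed_form(self):
        bt = np.tile([37.0, 36.0], 361)[:721]
        x, y = tl.lagged_pairs(bt)
        sd1, sd2, _ = tl.sd1_sd2(x, y)
        assert sd1 == pytest.approx(1.0 / SQRT2, abs=1e-3)
        assert sd2 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_rotation_oracle(self, seed):
        x, y = tl.lagged_pairs(random_series(seed))
        sd1, sd2, _ = tl.sd1_sd2(x, y)
        o1, o2 = rotation_oracle(x, y)
        assert sd1 == pytest.approx(o1, rel=1e-12)
        assert sd2 == pytest.approx(o2, rel=1e-12)

    def test_sdnn_matches_total_dispersion(self, rng):
        bt = random_series(7, 720)
        d = tl.poincare_descriptors(bt)
        x, y = tl.lagged_pairs(bt)
        m = np.mean(np.concatenate([x, y]))
        total = (np.sum((x - m) ** 2) + np.sum((y - m) ** 2)) / (x.size - 1)
        assert d.sd1**2 + d.sd2**2 == pytest.approx(total, rel=1e-12)
        assert d.sdnn**2 == pytest.approx((d.sd1**2 + d.sd2**2) / 2, rel=1e-12)


class TestAsymmetryPartition:
    def test_hand_computed_example(self):
        d = tl.poincare_descriptors(np.array([37.0, 37.1, 37.2, 36.9]))
        # increments +0.1, +0.1, −0.3 → decrease share 0.09/0.11
        assert d.c1d == pytest.approx(0.09 / 0.11, rel=1e-9)
        assert d.c1i == pytest.approx(0.02 / 0.11, rel=1e-9)

    def test_strictly_alternating_series_is_symmetric(self):
        # 721 samples → 720 increments, exactly 360 decreases and 360 increases
        d = tl.poincare_descriptors(np.tile([37.0, 36.0], 361)[:721])
        assert d.c1d == pytest.approx(0.5)
        assert d.c1i == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        x, y = tl.lagged_pairs(random_series(seed))
        got = tl.asymmetry_partition(x, y)[:4]
        expected = partition_oracle(x, y)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_contributions_are_missing(self):
        d = tl.poincare_descriptors(np.full(10, 37.0))
        assert math.isnan(d.c1d) and math.isnan(d.c2i)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, derandomize=True)
    def test_exact_decomposition_identities(self, seed):
        d = tl.poincare_descriptors(random_series(seed))
        assert d.sd1d**2 + d.sd1i**2 == pytest.approx(d.sd1**2, rel=1e-12)
        assert d.sd2d**2 + d.sd2i**2 == pytest.approx(d.sd2**2, rel=1e-12)
        if d.sd1 > 0 and d.sd2 > 0:
            assert d.c1d + d.c1i == pytest.approx(1.0, rel=1e-12)
            assert d.c2d + d.c2i == pytest.approx(1.0, rel=1e-12)

    def test_time_reversal_swaps_partition_and_preserves_sds(self):
        bt = random_series(42, 500)
        fwd = tl.poincare_descriptors(bt)
        rev = tl.poincare_descriptors(bt[::-1])
        assert rev.sd1 == pytest.approx(fwd.sd1, rel=1e-12)
        assert rev.sd2 == pytest.approx(fwd.sd2, rel=1e-12)
        assert rev.sd1d == pytest.approx(fwd.sd1i, rel=1e-12)
        assert rev.c1d == pytest.approx(fwd.c1i, rel=1e-12)
        assert rev.sd2d == pytest.approx(fwd.sd2i, rel=1e-12)

    def test_scale_equivariance_about_the_mean(self):
        bt = random_series(3, 400)
        base = tl.poincare_descriptors(bt)
        scaled = tl.poincare_descriptors(bt.mean() + 2.5 * (bt - bt.mean()))
        for name in ("sd1", "sd2", "sdnn", "sd1d", "sd1i", "sd2d", "sd2i"):
            assert getattr(scaled, name) == pytest.approx(2.5 * getattr(base, name), rel=1e-9)
        for name in ("c1d", "c1i", "c2d", "c2i"):
            assert getattr(scaled, name) == pytest.approx(getattr(base, name), rel=1e-9)


class TestClassification:
    def test_strict_inequalities(self):
        d = tl.poincare_descriptors(np.array([37.0, 37.1, 37.2, 36.9]))
        cls = tl.classify_asymmetry(d)
        assert cls.short_term_asymmetric == (d.sd1d > d.sd1i)

    def test_exact_tie_is_not_asymmetric(self):
        d = tl.poincare_descriptors(np.tile([37.0, 36.0], 361)[:721])
        cls = tl.classify_asymmetry(d)
        assert not cls.short_term_asymmetric and not cls.long_term_asymmetric


def test_dark_variability_exceeds_light_in_control_cohort(pooled_descriptors):
    """Dark-phase SD1 and SD2 exceed light-phase values (group-level check)."""
    from scipy.stats import mannwhitneyu

    light = pooled_descriptors[("control", "light")]["poincare"]
    dark = pooled_descriptors[("control", "dark")]["poincare"]
    for attr in ("sd1", "sd2"):
        l = [getattr(d, attr) for d in light]
        da = [getattr(d, attr) for d in dark]
        assert mannwhitneyu(da, l, alternative="greater").pvalue < 0.05
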