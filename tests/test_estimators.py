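"""Estimator-layer tests: gamma_q, natural, shrinkage, targets, divergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from balshrink import (
    DegenerateInputError,
    R_PRESETS,
    RFunction,
    ShrinkageConfig,
    divergence_g,
    g_fn,
    gamma_q,
    get_r,
    natural_estimator,
    shrinkage_estimator,
    target_estimator,
)

vectors = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8
).map(lambda v: np.asarray(v))


class TestGammaQ:
    @pytest.mark.parametrize(
        "x,q,expected",
        [
            ([-1.5, 2.0, -0.5, 3.0], 2, [1.5, 0, 0, 0]),
            ([1.0, 2.0, 3.0], 3, [0, 0, 0]),
            ([-1.0, -2.0], 0, [0, 0]),
        ],
    )
    def test_componentwise_cases(self, x, q, expected):
        np.testing.assert_array_equal(gamma_q(np.asarray(x, float), q), expected)

    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            gamma_q(np.zeros(3), 4)
        with pytest.raises(ValueError):
            gamma_q(np.zeros(3), -1)

    @given(x=vectors, data=st.data())
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_no_dependence_beyond_q(self, x, data):
        q = data.draw(st.integers(0, len(x)))
        y = x.copy()
        y[q:] = -99.0  # perturb only unrestricted coordinates
        np.testing.assert_array_equal(gamma_q(x, q), gamma_q(y, q))


class TestNaturalEstimator:
    @pytest.mark.parametrize(
        "x,q,expected",
        [([-1, 2, -3], 2, [0, 2, -3]), ([-1, 2, -3], 3, [0, 2, 0])],
    )
    def test_positive_part_of_restricted_block(self, x, q, expected):
        np.testing.assert_array_equal(natural_estimator(np.asarray(x, float), q), expected)

    @given(x=vectors, data=st.data())
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_projection_is_idempotent_and_feasible(self, x, data):
        q = data.draw(st.integers(0, len(x)))
        once = natural_estimator(x, q)
        np.testing.assert_array_equal(natural_estimator(once, q), once)
        assert np.all(once[:q] >= 0)


class TestRFunctions:
    @pytest.mark.parametrize("name", sorted(R_PRESETS))
    def test_preset_profile_properties(self, name):
        # bounded in [0,1], nondecreasing, r(t)/t nonincreasing, r' >= 0
        r = R_PRESETS[name]
        t = np.linspace(1e-6, 100.0, 1000)
        v = r.value(t)
        assert np.all(v >= 0) and np.all(v <= 1)
        assert np.all(np.diff(v) >= -1e-12)
        assert np.all(np.diff(v / t) <= 1e-12)
        assert np.all(r.derivative(t) >= 0)

    def test_construction_rejects_unbounded_profile(self):
        with pytest.raises(ValueError, match="leaves"):
            RFunction("bad", lambda t: 2 * t, lambda t: np.full_like(t, 2.0))

    def test_construction_rejects_decreasing_profile(self):
        with pytest.raises(ValueError):
            RFunction("bad", lambda t: np.exp(-t), lambda t: -np.exp(-t))

    def test_unknown_preset_name(self):
        with pytest.raises(ValueError, match="unknown r preset"):
            get_r("r_quadratic")


class TestShrinkageField:
    def test_r_one_closed_form(self):
        cfg = ShrinkageConfig(c=0.5, r="r_one", q=0)
        np.testing.assert_allclose(
            g_fn(np.array([3.0, 4.0]), 2.0, cfg), [-0.12, -0.16], atol=1e-15
        )

    def test_r_rational_closed_form(self):
        cfg = ShrinkageConfig(c=1.0, r="r_rational", q=0)
        np.testing.assert_allclose(
            g_fn(np.array([3.0, 4.0]), 1.0, cfg), [-3 / 26, -4 / 26], atol=1e-15
        )

    def test_r_zero_vanishes(self):
        cfg = ShrinkageConfig(c=2.0, r="r_zero", q=0)
        np.testing.assert_array_equal(g_fn(np.array([1.0, -2.0]), 0.7, cfg), [0.0, 0.0])

    def test_antiparallel_and_norm_bound(self, rng):
        cfg = ShrinkageConfig(c=0.8, r="r_rational", q=0)
        for _ in range(20):
            x = rng.normal(size=5)
            s2 = rng.uniform(0.1, 3.0)
            g = g_fn(x, s2, cfg)
            assert g @ x <= 0
            assert np.linalg.norm(g) <= cfg.c * s2 / np.linalg.norm(x) + 1e-12

    def test_degenerate_origin_raises(self):
        cfg = ShrinkageConfig(c=1.0, r="r_one", q=0)
        with pytest.raises(DegenerateInputError):
            g_fn(np.zeros(3), 1.0, cfg)
        with pytest.raises(DegenerateInputError):
            divergence_g(np.zeros(3), 1.0, cfg)


def _fd_divergence(x, s2, cfg, h=1e-6):
    """Central finite-difference divergence of g_fn: the independent oracle."""
    total = 0.0
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h * (1.0 + abs(x[i]))
        total += (g_fn(x + e, s2, cfg)[i] - g_fn(x - e, s2, cfg)[i]) / (2 * e[i])
    return total


class TestDivergence:
    def test_p2_r_one_is_zero(self):
        cfg = ShrinkageConfig(c=1.3, r="r_one", q=0)
        for x, s2 in [([3.0, 4.0], 1.0), ([-1.0, 0.5], 2.5)]:
            assert divergence_g(np.asarray(x), s2, cfg) == pytest.approx(0.0, abs=1e-15)

    def test_r_one_closed_form(self):
        cfg = ShrinkageConfig(c=1.0, r="r_one", q=0)
        assert divergence_g(np.ones(4), 1.0, cfg) == pytest.approx(-0.5, abs=1e-15)

    @pytest.mark.parametrize("name", sorted(R_PRESETS))
    def test_matches_finite_differences(self, name, rng):
        cfg = ShrinkageConfig(c=0.7, r=name, q=0)
        for _ in range(25):
            p = rng.integers(2, 9)
            x = rng.normal(size=p) * rng.uniform(0.5, 5.0)
            while np.linalg.norm(x) < 0.3:
                x = rng.normal(size=p)
            s2 = rng.uniform(0.2, 4.0)
            exact = divergence_g(x, s2, cfg)
            fd = _fd_divergence(x, s2, cfg)
            assert exact == pytest.approx(fd, rel=1e-6, abs=1e-8)


class TestShrinkageEstimator:
    def test_r_zero_reduces_to_natural(self, rng):
        cfg = ShrinkageConfig(c=1.0, r="r_zero", q=2)
        x, u = rng.normal(size=4), rng.normal(size=6)
        s2 = u @ u / 6
        np.testing.assert_array_equal(
            shrinkage_estimator((x, u, s2), cfg), natural_estimator(x, 2)
        )

    def test_spherical_composition_example(self):
        cfg = ShrinkageConfig(c=0.5, r="r_one", q=0)
        x, u = np.array([3.0, 4.0]), np.array([2.0, 0.0])
        np.testing.assert_allclose(
            shrinkage_estimator((x, u, 2.0), cfg), [2.52, 3.36], atol=1e-14
        )

    def test_utu_equals_k_s2_scaling_identity(self, rng):
        # when ||u||^2 = k * s2 the added term equals k * s2 * g_fn
        cfg = ShrinkageConfig(c=0.4, r="r_rational", q=1)
        x = rng.normal(size=3)
        k = 4
        s2 = 1.7
        u = np.zeros(k)
        u[0] = np.sqrt(k * s2)
        expected = natural_estimator(x, 1) + k * s2 * g_fn(x, s2, cfg)
        np.testing.assert_allclose(shrinkage_estimator((x, u, s2), cfg), expected)

    def test_normal_variant_drops_utu_factor(self, rng):
        cfg = ShrinkageConfig(c=0.4, r="r_rational", q=1, variant="normal")
        x, u = rng.normal(size=3), rng.normal(size=5)
        s2 = 0.9
        expected = natural_estimator(x, 1) + g_fn(x, s2, cfg)
        np.testing.assert_allclose(shrinkage_estimator((x, u, s2), cfg), expected)

    def test_approaches_natural_far_from_origin(self, rng):
        cfg = ShrinkageConfig(c=1.0, r="r_rational", q=2)
        u = rng.normal(size=6)
        s2 = 1.1
        gaps = []
        for scale in (1e2, 1e4, 1e6):
            x = scale * np.array([1.0, -1.0, 2.0])
            gaps.append(
                np.linalg.norm(
                    shrinkage_estimator((x, u, s2), cfg) - natural_estimator(x, 2)
                )
            )
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-4


class TestTargetEstimators:
    def test_r_zero_t1_is_identity(self, rng):
        cfg = ShrinkageConfig(c=1.0, r="r_zero", q=2)
        x, u = rng.normal(size=4), rng.normal(size=3)
        np.testing.assert_array_equal(
            target_estimator((x, u, 1.0), cfg, 0.7, "t1"), x
        )

    def test_t2_at_omega_zero_is_natural(self, rng):
        cfg = ShrinkageConfig(c=1.0, r="r_one", q=3)
        x, u = rng.normal(size=5), rng.normal(size=3)
        np.testing.assert_array_equal(
            target_estimator((x, u, 1.0), cfg, 0.0, "t2"), natural_estimator(x, 3)
        )

    def test_t2_arithmetic(self):
        cfg = ShrinkageConfig(c=1.0, r="r_one", q=1)
        out = target_estimator((np.array([-1.0, 2.0]), np.ones(2), 1.0), cfg, 0.5, "t2")
        np.testing.assert_allclose(out, [-0.5, 2.0])

    def test_omega_validation(self):
        cfg = ShrinkageConfig(c=1.0, r="r_one", q=1)
        with pytest.raises(ValueError):
            target_estimator((np.ones(2), np.ones(2), 1.0), cfg, 1.0, "t1")

    def test_algebraic_decompositions(self, rng):
        # delta_q1 = t1 + gamma_q - (1-w) U'U g  and
        # delta_q2 = t1 + gamma_q + w U'U g, as vector identities
        for _ in range(20):
            cfg = ShrinkageConfig(c=rng.uniform(0.1, 2), r="r_rational", q=2)
            w = rng.uniform(0, 0.99)
            x, u = rng.normal(size=5), rng.normal(size=4)
            s2 = rng.uniform(0.2, 3)
            utu = u @ u
            g = g_fn(x, s2, cfg)
            t1 = target_estimator((x, u, s2), cfg, w, "t1")
            d1 = natural_estimator(x, 2)
            d2 = shrinkage_estimator((x, u, s2), cfg)
            np.testing.assert_allclose(
                d1, t1 + gamma_q(x, 2) - (1 - w) * utu * g, atol=1e-12
            )
            np.testing.assert_allclose(
                d2, t1 + gamma_q(x, 2) + w * utu * g, atol=1e-12
            )
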