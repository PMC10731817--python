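import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copsway.errors import LengthError, NormalizationError
from copsway.features import (ApEnConfig, NormalizationScheme, PARAMETER_ORDER,
                              approximate_entropy, compute_parameters,
                              confidence_ellipse, instantaneous_velocity,
                              normalize_parameters, path_metrics,
                              velocity_stats)
from copsway.io import SubjectMeta

from conftest import make_processed
from oracles import adjusted_skewness, naive_apen, path_length_planar, sample_std

CHI2_2_95 = 5.991464547107979


class TestInstantaneousVelocity:
    def test_uniform_ramp(self):
        p = make_processed([0, 1, 2, 3], [0, 0, 0, 0])
        v = instantaneous_velocity(p)
        np.testing.assert_allclose(v["X"], [50.0, 50.0, 50.0])
        np.testing.assert_allclose(v["R"], [50.0, 50.0, 50.0])

    def test_constant_series_zero_velocity(self):
        p = make_processed(np.full(10, 3.0), np.full(10, -2.0))
        v = instantaneous_velocity(p)
        assert not v["X"].any() and not v["Y"].any() and not v["R"].any()

    def test_matches_hand_difference_oracle(self, rng):
        x = rng.normal(0, 5, 50)
        y = rng.normal(0, 5, 50)
        p = make_processed(x, y)
        v = instantaneous_velocity(p)
        for i in range(49):
            assert v["X"][i] == pytest.approx((x[i + 1] - x[i]) * 50.0)
            assert v["R"][i] == pytest.approx(
                math.hypot((x[i + 1] - x[i]) * 50, (y[i + 1] - y[i]) * 50))

    def test_too_short_raises(self):
        with pytest.raises(LengthError):
            instantaneous_velocity(make_processed([1.0], [1.0]))


class TestVelocityStats:
    def test_constant_velocity(self):
        s = velocity_stats(np.array([50.0, 50.0, 50.0]))
        assert s == {"std": 0.0, "rms": 50.0, "skewness": 0.0, "range": 0.0}

    def test_textbook_formula_oracle(self):
        v = [1.0, 2.0, 3.0, 4.0]
        s = velocity_stats(np.array(v))
        assert s["std"] == pytest.approx(sample_std(v))
        assert s["rms"] == pytest.approx(math.sqrt(sum(x * x for x in v) / 4))
        # symmetric values: adjusted skewness exactly 0
        assert s["skewness"] == pytest.approx(0.0, abs=1e-12)
        v2 = [1.0, 1.0, 2.0, 5.0, 9.0]
        assert velocity_stats(np.array(v2))["skewness"] == pytest.approx(
            adjusted_skewness(v2))

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        v = np.array([3.0, -1.0, 4.0, 1.0, -5.0, 9.0])
        base = velocity_stats(v)
        scaled = velocity_stats(c * v)
        assert scaled["std"] == pytest.approx(c * base["std"])
        assert scaled["rms"] == pytest.approx(c * base["rms"])
        assert scaled["range"] == pytest.approx(c * base["range"])
        assert scaled["skewness"] == pytest.approx(base["skewness"], abs=1e-9)


class TestPathMetrics:
    def test_collinear_path_pythagoras(self):
        # (0,0) -> (3,4) in 5 collinear steps
        x = np.linspace(0, 3, 6)
        y = np.linspace(0, 4, 6)
        m = path_metrics(make_processed(x, y))
        assert m["total_distance_R"] == pytest.approx(5.0)

    def test_constant_position_all_zero(self):
        m = path_metrics(make_processed(np.full(10, 1.0), np.full(10, 2.0)))
        assert m["total_distance_X"] == 0.0
        assert m["total_distance_R"] == 0.0
        assert m["average_distance"] == 0.0

    def test_random_walk_matches_stepwise_oracle(self, rng):
        x = np.cumsum(rng.normal(0, 1, 100))
        y = np.cumsum(rng.normal(0, 1, 100))
        m = path_metrics(make_processed(x, y))
        assert m["total_distance_R"] == pytest.approx(
            path_length_planar(x.tolist(), y.tolist()))
        assert m["total_distance_X"] == pytest.approx(
            sum(abs(x[i + 1] - x[i]) for i in range(99)))

    def test_rms_dominates_mean_distance(self, random_processed):
        m = path_metrics(random_processed)
        assert m["instantaneous_distance_rms_R"] >= m["average_distance"]


class TestConfidenceEllipse:
    def test_identical_points_degenerate(self):
        e = confidence_ellipse(make_processed(np.full(10, 1.0), np.full(10, 1.0)))
        assert e["area"] == 0.0
        assert e["degenerate"]

    def test_known_covariance_closed_form(self, rng):
        # anisotropic Gaussian: area -> pi * chi2 * sqrt(sx^2 * sy^2)
        n = 20000
        sx, sy = 3.0, 1.5
        p = make_processed(rng.normal(0, sx, n), rng.normal(0, sy, n))
        e = confidence_ellipse(p)
        assert e["area"] == pytest.approx(math.pi * CHI2_2_95 * sx * sy, rel=0.05)
        assert e["major_axis"] == pytest.approx(2 * math.sqrt(CHI2_2_95) * sx,
                                                rel=0.05)
        assert abs(e["orientation"]) < 0.2  # major axis along x

    def test_doubling_coordinates_quadruples_area(self, random_processed):
        e1 = confidence_ellipse(random_processed)
        p2 = make_processed(2 * random_processed.x, 2 * random_processed.y)
        e2 = confidence_ellipse(p2)
        assert e2["area"] == pytest.approx(4 * e1["area"])


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(100, 3.3)) == 0.0

    def test_periodic_series_matches_naive_oracle(self):
        s = np.tile([1.0, 2.0, 3.0], 10)
        cfg = ApEnConfig(m=2, r_factor=0.5)
        r = 0.5 * np.std(s, ddof=1)
        assert approximate_entropy(s, cfg) == pytest.approx(
            naive_apen(s, 2, r), abs=1e-12)

    def test_white_noise_more_irregular_than_sine(self, rng):
        noise = rng.uniform(size=1000)
        sine = np.sin(2 * np.pi * np.arange(1000) / 50)
        assert approximate_entropy(noise) > approximate_entropy(sine)

    def test_short_series_raises(self):
        with pytest.raises(LengthError):
            approximate_entropy(np.arange(20.0), ApEnConfig(m=2))

    @given(seed=st.integers(0, 2**16), n=st.integers(35, 90))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_near_nonnegative_and_scale_invariant(self, seed, n):
        # self-matches keep ApEn essentially nonnegative (exactly periodic
        # short series can dip a hair below zero); r scales with SD so the
        # statistic is scale-invariant
        s = np.random.default_rng(seed).normal(size=n)
        a = approximate_entropy(s)
        assert a >= -1e-3
        assert approximate_entropy(7.3 * s) == pytest.approx(a, abs=1e-12)


class TestComputeParameters:
    def test_schema_complete(self, random_processed):
        ps = compute_parameters(random_processed)
        assert tuple(ps.values.keys()) == PARAMETER_ORDER

    def test_pure_sine_arc_length(self):
        # planar path length of a sampled sine sway vs stepwise oracle
        t = np.arange(0, 30, 0.02)
        x = 12 * np.sin(2 * np.pi * 0.8 * t)
        y = np.zeros_like(t)
        ps = compute_parameters(make_processed(x, y))
        assert ps.get("total_distance", "R") == pytest.approx(
            path_length_planar(x.tolist(), y.tolist()), rel=1e-3)

    def test_deterministic(self, random_processed):
        a = compute_parameters(random_processed)
        b = compute_parameters(random_processed)
        assert a.values == b.values


class TestNormalization:
    def params(self, rng, subject=None):
        p = make_processed(rng.normal(0, 5, 300), rng.normal(0, 5, 300),
                           subject=subject or SubjectMeta(height=62.0,
                                                          weight=6000.0))
        return compute_parameters(p)

    def test_kind_none_is_identity_with_flag(self, rng):
        ps = self.params(rng)
        out = normalize_parameters(ps, NormalizationScheme(kind="none"))
        assert out.normalized
        assert out.values == ps.values

    def test_height_divides_lengths(self, rng):
        ps = self.params(rng)
        out = normalize_parameters(ps, NormalizationScheme(kind="height"))
        td = ps.get("total_distance", "R")
        assert out.get("total_distance", "R") == pytest.approx(td / 62.0)
        # worked example: 500 mm at 62 cm -> ~8.0645
        assert 500.0 / 62.0 == pytest.approx(8.0645, abs=1e-4)

    def test_area_divided_twice(self, rng):
        ps = self.params(rng)
        out = normalize_parameters(ps, NormalizationScheme(kind="height"))
        assert out.get("ellipse_area", "R") == pytest.approx(
            ps.get("ellipse_area", "R") / 62.0**2)

    def test_height_weight_uses_kg(self, rng):
        ps = self.params(rng)
        out = normalize_parameters(ps, NormalizationScheme(kind="height_weight"))
        td = ps.get("total_distance", "R")
        assert out.get("total_distance", "R") == pytest.approx(td / (62.0 * 6.0))

    @pytest.mark.parametrize("kind", ["none", "height", "weight", "height_weight"])
    def test_dimensionless_parameters_untouched(self, rng, kind):
        ps = self.params(rng)
        out = normalize_parameters(ps, NormalizationScheme(kind=kind))
        for d in ("X", "Y", "R"):
            assert out.get("approximate_entropy", d) == ps.get(
                "approximate_entropy", d)
            assert out.get("instantaneous_velocity_skewness", d) == ps.get(
                "instantaneous_velocity_skewness", d)

    def test_missing_anthropometrics_named(self, rng):
        ps = self.params(rng, subject=SubjectMeta(weight=6000.0))
        with pytest.raises(NormalizationError, match="height"):
            normalize_parameters(ps, NormalizationScheme(kind="height"))
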