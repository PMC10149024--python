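import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scigait import (FeatureError, TrialMetadata, analysis_side,
                     build_reference, compute_asym, compute_change_metrics,
                     compute_cov, compute_d2r, compute_smoothness,
                     cyclogram_acc, cyclogram_area, cyclogram_ssd,
                     feature_names)
from scigait.features import HealthyReference, normalize_shape

FS = 200.0


class TestFormulaOracles:
    """cov/asym/d2r against independent one-line reimplementations."""

    def test_cov_worked_example(self):
        assert compute_cov([1.0, 1.0, 1.0]) == 0.0
        assert compute_cov([0.9, 1.0, 1.1]) == pytest.approx(10.0)

    def test_cov_scale_invariance(self, rng):
        x = rng.uniform(0.5, 2.0, 50)
        assert compute_cov(5 * x) == pytest.approx(compute_cov(x), abs=1e-9)

    def test_cov_matches_oracle_on_random_inputs(self, rng):
        for _ in range(1000):
            x = rng.uniform(0.1, 10.0, rng.integers(2, 30))
            oracle = np.std(x, ddof=1) / np.mean(x) * 100.0
            assert abs(compute_cov(x) - oracle) < 1e-9

    def test_asym_worked_examples_and_symmetry(self):
        assert compute_asym(1.0, 1.0) == 0.0
        assert compute_asym(1.1, 0.9) == pytest.approx(20.0)
        assert compute_asym(0.9, 1.1) == pytest.approx(20.0)

    def test_asym_matches_oracle_on_random_inputs(self, rng):
        for _ in range(1000):
            a, b = rng.uniform(0.01, 5.0, 2)
            oracle = abs(a - b) / (0.5 * (a + b)) * 100.0
            assert abs(compute_asym(a, b) - oracle) < 1e-9

    def test_cov_zero_mean_errors(self):
        with pytest.raises(FeatureError):
            compute_cov([-1.0, 1.0])

    @given(st.floats(0.2, 5.0), st.floats(0.5, 1.4))
    @settings(max_examples=50, deadline=None)
    def test_d2r_sign_and_magnitude(self, scale, speed):
        ref = HealthyReference(speeds=np.array([0.5, 1.0, 1.5]),
                               tables={"p": np.array([2.0, 2.0, 2.0])})
        d2r = compute_d2r(2.0 * scale, speed, ref, "p")
        assert d2r == pytest.approx((scale - 1.0) * 100.0, abs=1e-9)


class TestHealthyReference:
    def test_linear_interpolation(self):
        ref = build_reference([{"p": 10.0}, {"p": 12.0}, {"p": 14.0}],
                              [1.0, 1.2, 1.4])
        assert ref.query("p", 1.1) == pytest.approx(11.0)

    def test_out_of_range_clamped_and_flagged(self):
        ref = build_reference([{"p": 10.0}, {"p": 12.0}, {"p": 14.0}],
                              [1.0, 1.2, 1.4])
        assert ref.query("p", 0.8) == pytest.approx(10.0)
        assert ref.is_extrapolated(0.8)
        assert not ref.is_extrapolated(1.2)

    def test_insufficient_span_errors(self):
        with pytest.raises(FeatureError, match="span"):
            build_reference([{"p": 1.0}] * 3, [1.0, 1.1, 1.2])

    def test_d2r_examples(self):
        ref = build_reference([{"p": 10.0}, {"p": 12.0}, {"p": 14.0}],
                              [1.0, 1.2, 1.4])
        assert compute_d2r(12.0, 1.2, ref, "p") == 0.0
        assert compute_d2r(14.4, 1.2, ref, "p") == pytest.approx(20.0)
        assert compute_d2r(9.6, 1.2, ref, "p") == pytest.approx(-20.0)


def _closed_shape(n=100, a=1.0, b=1.0, phase=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


class TestCyclogramShapes:
    def test_normalized_centroid_and_rms(self, rng):
        pts = rng.normal(3.0, 2.0, (100, 2))
        norm = normalize_shape(pts)
        assert np.allclose(norm.mean(axis=0), 0.0, atol=1e-9)
        assert np.sqrt(np.mean(np.sum(norm**2, axis=1))) == pytest.approx(1.0,
                                                                          abs=1e-9)

    def test_scale_invariance(self, rng):
        pts = rng.normal(0, 1, (100, 2))
        assert np.allclose(normalize_shape(pts), normalize_shape(7.5 * pts))

    def test_degenerate_shape_returns_none(self):
        assert normalize_shape(np.zeros((100, 2))) is None

    def test_ssd_self_is_zero(self):
        s = normalize_shape(_closed_shape())
        assert cyclogram_ssd(s, s) == 0.0

    def test_ssd_offset_removed_by_centering(self):
        s1 = normalize_shape(_closed_shape())
        s2 = normalize_shape(_closed_shape() + np.array([5.0, -3.0]))
        assert cyclogram_ssd(s1, s2) == pytest.approx(0.0, abs=1e-18)

    def test_ssd_circle_vs_ellipse_matches_bruteforce(self):
        c = normalize_shape(_closed_shape())
        e = normalize_shape(_closed_shape(a=2.0, b=1.0))
        brute = float(sum(np.sum((p - r) ** 2) for p, r in zip(c, e)))
        assert cyclogram_ssd(c, e) == pytest.approx(brute, abs=1e-12)

    def test_ssd_length_mismatch_errors(self):
        with pytest.raises(FeatureError):
            cyclogram_ssd(np.zeros((100, 2)), np.zeros((50, 2)))


class TestAcc:
    def test_identical_cycles_score_100(self):
        shapes = [normalize_shape(_closed_shape()) for _ in range(10)]
        assert cyclogram_acc(shapes) == pytest.approx(100.0)

    def test_random_directions_score_near_zero(self, rng):
        # cycles built from uniformly random segment angles
        shapes = []
        for _ in range(200):
            ang = rng.uniform(0, 2 * np.pi, 99)
            pts = np.vstack([[0, 0], np.cumsum(
                np.column_stack([np.cos(ang), np.sin(ang)]), axis=0)])
            shapes.append(normalize_shape(pts))
        assert cyclogram_acc(shapes) <= 15.0

    def test_monotone_decrease_with_noise(self):
        base = _closed_shape()
        mean_acc = []
        for noise in (0.0, 0.1, 0.4):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                shapes = [normalize_shape(base + rng.normal(0, noise, base.shape))
                          for _ in range(12)]
                vals.append(cyclogram_acc(shapes))
            mean_acc.append(np.mean(vals))
        assert mean_acc[0] > mean_acc[1] > mean_acc[2]

    def test_too_few_cycles_errors(self):
        with pytest.raises(FeatureError):
            cyclogram_acc([normalize_shape(_closed_shape())] * 4)


class TestArea:
    def test_unit_circle_is_pi(self):
        assert cyclogram_area(_closed_shape()) == pytest.approx(np.pi, rel=0.005)

    def test_degenerate_line_is_zero(self):
        line = np.column_stack([np.linspace(0, 1, 100), np.zeros(100)])
        assert cyclogram_area(line) == pytest.approx(0.0, abs=1e-12)

    def test_raw_ellipse_matches_closed_form(self):
        a, b = 0.6, 0.05
        assert cyclogram_area(_closed_shape(a=a, b=b)) == pytest.approx(
            a * b * np.pi, rel=0.01)


class TestSmoothness:
    def test_noise_reduces_smoothness_in_all_seeds(self):
        t = np.arange(0, 30, 1 / FS)
        clean = np.sin(2 * np.pi * 1.0 * t)
        s_clean = compute_smoothness(clean, FS)
        assert s_clean <= 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean + np.sqrt(0.1) * np.sin(
                2 * np.pi * 8 * t + rng.uniform(0, 2 * np.pi))
            assert s_clean > compute_smoothness(noisy, FS)

    def test_time_rescaling_robustness(self):
        t = np.arange(0, 30, 1 / FS)
        a = compute_smoothness(np.sin(2 * np.pi * 1.0 * t), FS)
        b = compute_smoothness(np.sin(2 * np.pi * 1.1 * t), FS)
        assert abs((b - a) / a) < 0.05

    def test_short_input_errors(self):
        with pytest.raises(FeatureError):
            compute_smoothness(np.sin(np.arange(0, 5, 1 / FS)), FS)


class TestChangeMetrics:
    def test_constant_speed_is_zero(self):
        t = np.linspace(0, 360, 300)
        fm = compute_change_metrics(t, np.ones(300), 1.2 * np.ones(300),
                                    55 * np.ones(300))
        assert fm.change_speed == pytest.approx(0.0, abs=1e-12)
        assert fm.speed_inconsistency == pytest.approx(0.0, abs=1e-12)

    def test_linear_decay_closed_form(self):
        t = np.linspace(0, 360, 300)
        speed = 1.0 - 0.1 * t / 360.0
        fm = compute_change_metrics(t, speed, 1.2 * np.ones(300),
                                    55 * np.ones(300))
        assert fm.change_speed == pytest.approx((-0.1 / 360) / 1.0, rel=1e-6)
        assert fm.speed_inconsistency == pytest.approx(abs(fm.change_speed))

    def test_unit_invariance(self):
        t = np.linspace(0, 200, 50)
        v = 1.0 + 0.001 * t
        a = compute_change_metrics(t, v, v, v).change_speed
        b = compute_change_metrics(t, 100 * v, v, v).change_speed
        assert a == pytest.approx(b, rel=1e-9)

    def test_short_window_errors(self):
        with pytest.raises(FeatureError):
            compute_change_metrics(np.linspace(0, 60, 20), np.ones(20),
                                   np.ones(20), np.ones(20))


class TestSideRule:
    def test_lower_lems_side_selected(self):
        assert analysis_side("SCI", 20, 24) == "left"
        assert analysis_side("SCI", 24, 20) == "right"

    def test_controls_and_ties_use_right(self):
        assert analysis_side("HC", None, None) == "right"
        assert analysis_side("SCI", 22, 22) == "right"

    def test_missing_lems_errors_unless_forced(self):
        with pytest.raises(FeatureError):
            analysis_side("SCI", None, 20)
        assert analysis_side("SCI", None, 20, forced="left") == "left"

    def test_metadata_validation(self):
        with pytest.raises(ValueError):
            TrialMetadata(subject_id="x", lems_left=30)


def test_feature_ordering_is_fixed_and_documented():
    names = feature_names()
    assert names.index("stride_duration_mean") == 0
    assert "stride_length_asym" not in names  # no asym for stride length
    assert "stride_length_d2r" in names
    assert "step_duration_d2r" in names
    assert names[-1] == "mean_speed"
    assert len(names) == len(set(names))
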