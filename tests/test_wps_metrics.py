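"""Windowed PS metrics, circular statistics and sliding-window baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasesync import (
    InputError,
    NumericalError,
    RawSeries,
    WindowSpec,
    analytic_signal,
    circ_circ_corr,
    circular_mean,
    csw,
    order_function,
    phase_difference,
    plv,
    prewhiten_ar1,
    sliding_windows,
    toroidal_corr,
    windowed_csw,
    windowed_metric,
    wrap_phase,
)

TR = 2.0


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def toroidal_bruteforce(phix, phiy):
    """Literal double loop over ordered pairs t_i < t_j of the toroidal
    correlation estimator, with the order function written out piecewise."""

    def h(delta):
        return delta + np.pi if delta < 0 else delta - np.pi

    x = np.mod(np.asarray(phix, float), 2 * np.pi)
    y = np.mod(np.asarray(phiy, float), 2 * np.pi)
    num = dx = dy = 0.0
    n = x.size
    for i in range(n):
        for j in range(i + 1, n):
            hx, hy = h(x[i] - x[j]), h(y[i] - y[j])
            num += hx * hy
            dx += hx * hx
            dy += hy * hy
    return num / np.sqrt(dx * dy)


def circular_mean_literal(angles):
    """Mean direction written exactly as the quadrant-correct arctangent of
    the sine and cosine sums."""
    return np.arctan2(np.sum(np.sin(angles)), np.sum(np.cos(angles)))


class TestPhaseDifference:
    def test_equal_phases_give_zero(self, make_sinusoid, band):
        px = analytic_signal(make_sinusoid(0.05))
        delta = phase_difference(px, px)
        assert np.allclose(delta.delta_phi, 0.0)

    def test_wrapping_takes_short_way_round(self):
        assert wrap_phase(0.9 * np.pi - (-0.9 * np.pi)) == pytest.approx(-0.2 * np.pi)

    def test_length_mismatch_rejected(self, make_sinusoid):
        px = analytic_signal(make_sinusoid(0.05, n=210))
        py = analytic_signal(make_sinusoid(0.05, n=128))
        with pytest.raises(InputError):
            phase_difference(px, py)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n, length, expect",
        [(210, 30, 181), (10, 10, 1), (210, 28, 183)],
    )
    def test_window_count(self, n, length, expect):
        assert len(sliding_windows(n, WindowSpec(length))) == expect

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(InputError):
            sliding_windows(10, WindowSpec(11))


class TestPlv:
    def test_constant_difference_locks_at_one(self):
        assert plv(np.full(50, 1.3)) == pytest.approx(1.0)

    def test_antipodal_angles_cancel(self):
        assert plv(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_equally_spaced_angles_cancel(self):
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        assert plv(angles) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-np.pi, np.pi))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_constant_offset(self, offset):
        rng = np.random.default_rng(7)
        delta = rng.uniform(-np.pi, np.pi, 40)
        assert plv(delta + offset) == pytest.approx(plv(delta), abs=1e-12)


class TestCircularMean:
    def test_symmetric_pair(self):
        assert circular_mean(np.array([0.0, np.pi / 2])) == pytest.approx(np.pi / 4)

    def test_zero_resultant_flagged_undefined(self):
        assert np.isnan(circular_mean(np.array([-np.pi / 2, np.pi / 2])))

    def test_concentrated_angles(self):
        assert circular_mean(np.array([0.1, 0.2, 0.3])) == pytest.approx(0.2, abs=1e-12)

    def test_matches_literal_arctangent_formula(self, rng):
        for _ in range(200):
            angles = rng.uniform(-np.pi, np.pi, rng.integers(2, 20))
            assert circular_mean(angles) == pytest.approx(
                circular_mean_literal(angles), abs=1e-12
            )


class TestCircCircCorr:
    def test_identical_nonconstant_phases(self, rng):
        x = rng.uniform(-1, 1, 30)
        assert circ_circ_corr(x, x) == pytest.approx(1.0)

    def test_negated_phases(self, rng):
        x = rng.uniform(-1, 1, 30)
        assert circ_circ_corr(x, -x) == pytest.approx(-1.0)

    def test_rotation_invariance_on_torus(self, rng):
        x = rng.vonmises(0.3, 2.0, 40)
        y = x + rng.vonmises(0.0, 5.0, 40)
        base = circ_circ_corr(x, y)
        for ax, ay in [(0.7, 0.0), (0.0, -1.2), (2.1, 0.9)]:
            assert circ_circ_corr(x + ax, y + ay) == pytest.approx(base, abs=1e-9)


class TestOrderFunction:
    @pytest.mark.parametrize(
        "delta, expect",
        [(np.pi / 2, -np.pi / 2), (-np.pi / 2, np.pi / 2), (0.0, -np.pi)],
    )
    def test_piecewise_branches(self, delta, expect):
        assert order_function(delta) == pytest.approx(expect)

    def test_domain_validated(self):
        with pytest.raises(InputError):
            order_function(2 * np.pi)

    @given(st.floats(-2 * np.pi + 1e-9, 2 * np.pi - 1e-9))
    @settings(deadline=None, max_examples=50)
    def test_matches_piecewise_definition(self, delta):
        # away from the jump at 0, where float rounding of delta + 2*pi
        # cannot move the argument across the branch boundary
        if abs(delta) < 1e-9:
            delta = 1e-6
        expect = delta + np.pi if delta < 0 else delta - np.pi
        assert order_function(delta) == pytest.approx(expect, abs=1e-9)


class TestToroidalCorr:
    def test_identical_phases(self, rng):
        x = rng.uniform(0.1, 6.0, 20)
        assert toroidal_corr(x, x) == pytest.approx(1.0)

    def test_negated_phases(self, rng):
        x = rng.uniform(0.1, 3.0, 20)  # no zero pairwise differences
        assert toroidal_corr(x, -x) == pytest.approx(-1.0)

    def test_matches_bruteforce_double_loop(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            x = rng.uniform(-np.pi, np.pi, n)
            y = rng.uniform(-np.pi, np.pi, n)
            assert toroidal_corr(x, y) == pytest.approx(
                toroidal_bruteforce(x, y), abs=1e-12
            )

    def test_rotation_invariance_on_torus(self, rng):
        x = rng.uniform(-np.pi, np.pi, 25)
        y = rng.uniform(-np.pi, np.pi, 25)
        base = toroidal_corr(x, y)
        # h() recentres each pairwise difference, so joint rotations of either
        # margin leave the estimator unchanged up to pair-crossing effects at
        # exact wrap boundaries (absent for generic continuous data)
        for ax, ay in [(0.4, 0.0), (0.0, 1.1)]:
            assert toroidal_corr(x + ax, y + ay) == pytest.approx(base, abs=1e-9)


class TestWindowedMetric:
    def test_full_length_window_equals_whole_segment_metric(self, rng):
        x = rng.uniform(-np.pi, np.pi, 40)
        y = rng.uniform(-np.pi, np.pi, 40)
        spec = WindowSpec(40)
        assert windowed_metric(x, y, spec, "plv").values[0] == pytest.approx(
            plv(wrap_phase(x - y))
        )
        assert windowed_metric(x, y, spec, "toroidal").values[0] == pytest.approx(
            toroidal_corr(x, y)
        )
        assert windowed_metric(x, y, spec, "circ").values[0] == pytest.approx(
            circ_circ_corr(x, y)
        )

    def test_constant_difference_pair_gives_all_ones_plv(self):
        t = np.linspace(0, 20, 100)
        trace = windowed_metric(t, t - 0.7, WindowSpec(20), "plv")
        assert trace.values == pytest.approx(np.ones(81))

    def test_traces_respect_declared_ranges(self, rng, band, make_sinusoid):
        x = RawSeries(rng.normal(size=210), TR)
        y = RawSeries(rng.normal(size=210), TR)
        px, py = analytic_signal(x), analytic_signal(y)
        for metric, (lo, hi) in [("plv", (0, 1)), ("circ", (-1, 1)), ("toroidal", (-1, 1))]:
            trace = windowed_metric(px, py, WindowSpec(30), metric)
            valid = trace.values[trace.valid_mask]
            assert np.all(valid >= lo) and np.all(valid <= hi)


class TestCsw:
    def test_affine_relation_gives_unit_correlation(self, rng):
        x = rng.normal(size=50)
        assert csw(x, 2 * x + 3) == pytest.approx(1.0)
        assert csw(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_window_masked(self):
        assert np.isnan(csw(np.ones(10), np.arange(10.0)))

    def test_independent_pairs_scatter_around_zero(self, rng):
        vals = []
        for _ in range(200):
            x = rng.normal(size=2000)
            y = rng.normal(size=2000)
            trace = windowed_csw(x, y, WindowSpec(28, step=28))
            vals.extend(trace.values[trace.valid_mask])
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 0.01
        # null Pearson sd for window n is ~ 1/sqrt(n-1)
        assert vals.std() == pytest.approx(1 / np.sqrt(27), rel=0.1)


class TestPrewhitenAr1:
    def test_recovers_ar1_coefficient(self, rng):
        rho, n = 0.6, 5000
        e = rng.normal(size=n)
        x = np.empty(n)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = rho * x[t - 1] + e[t]
        resid = prewhiten_ar1(RawSeries(x, TR)).values
        c = resid - resid.mean()
        lag1 = np.sum(c[1:] * c[:-1]) / np.sum(c**2)
        assert abs(lag1) < 2 / np.sqrt(n)

    def test_white_noise_nearly_unchanged(self, rng):
        x = rng.normal(size=1000)
        resid = prewhiten_ar1(RawSeries(x, TR)).values
        assert resid.size == 999
        assert np.corrcoef(resid, x[1:])[0, 1] > 0.99

    def test_constant_series_degenerate(self):
        with pytest.raises((NumericalError, InputError)):
            prewhiten_ar1(RawSeries(np.ones(50), TR))
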