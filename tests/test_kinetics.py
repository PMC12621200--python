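"""Rate extraction: window detection, OLS slopes, normalization, saturation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orcakit import kinetics, synthetic
from orcakit.kinetics import LinearWindow
from orcakit.types import KineticTrace


def _trace(t, f, role="compound"):
    return KineticTrace(times=np.asarray(t, float), fluorescence=np.asarray(f, float),
                        role=role)


def brute_force_window(trace, min_frac, r2_min):
    """Exhaustive prefix-enumeration oracle for the linear-window rule."""
    import math
    n = len(trace)
    min_len = max(3, math.ceil(min_frac * n))
    best = None
    for stop in range(min_len, n + 1):
        t, f = trace.times[:stop], trace.fluorescence[:stop]
        slope, intercept = np.polyfit(t, f, 1)
        resid = f - (intercept + slope * t)
        ss_tot = np.sum((f - f.mean()) ** 2)
        r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
        if r2 >= r2_min:
            best = stop
    return best, min_len


class TestDetectLinearWindow:
    def test_exactly_linear_trace_keeps_full_range(self):
        t = np.arange(10.0)
        w = kinetics.detect_linear_window(_trace(t, 3 + 2 * t), r2_min=1.0 - 1e-12)
        assert (w.start, w.stop, w.low_quality) == (0, 10, False)

    @pytest.mark.parametrize("r2_min", [0.95, 0.995])
    def test_saturating_curve_matches_prefix_enumeration_oracle(self, r2_min):
        t = np.linspace(0, 5, 21)
        tr = _trace(t, 1 - np.exp(-t))
        w = kinetics.detect_linear_window(tr, min_frac=0.2, r2_min=r2_min)
        stop, min_len = brute_force_window(tr, 0.2, r2_min)
        if stop is None:
            assert w.low_quality and w.stop == min_len
        else:
            assert not w.low_quality and w.stop == stop

    def test_constant_trace_full_range_zero_slope(self):
        t = np.arange(8.0)
        w = kinetics.detect_linear_window(_trace(t, np.full(8, 5.0)), r2_min=0.99)
        est = kinetics.initial_rate(_trace(t, np.full(8, 5.0)), w)
        assert w.stop == 8 and not w.low_quality
        assert est.slope == 0.0 and est.r2 == 1.0

    def test_hopeless_trace_flagged_low_quality_with_minimal_window(self):
        rng = np.random.default_rng(0)
        t = np.arange(20.0)
        tr = _trace(t, np.sin(t) * 100 + rng.normal(0, 50, 20))
        w = kinetics.detect_linear_window(tr, min_frac=0.5, r2_min=0.999)
        assert w.low_quality and w.stop == 10

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 50))
    def test_agrees_with_oracle_on_random_traces(self, seed, n):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, n))
        t += np.arange(n) * 1e-6  # strict monotonicity
        f = rng.normal(0, 1, n).cumsum()
        tr = _trace(t, f)
        w = kinetics.detect_linear_window(tr, min_frac=0.2, r2_min=0.9)
        stop, min_len = brute_force_window(tr, 0.2, 0.9)
        if stop is None:
            assert w.low_quality and w.stop == min_len
        else:
            assert not w.low_quality and w.stop == stop


class TestInitialRate:
    def test_exact_line_recovered(self):
        t = np.arange(6.0)
        est = kinetics.initial_rate(_trace(t, 3 + 2 * t), LinearWindow(0, 6, False))
        assert est.slope == pytest.approx(2.0)
        assert est.intercept == pytest.approx(3.0)
        assert est.r2 == pytest.approx(1.0)

    def test_window_choice_irrelevant_on_linear_trace(self):
        t = np.arange(12.0)
        tr = _trace(t, 1 + 0.7 * t)
        slopes = {kinetics.initial_rate(tr, LinearWindow(0, stop, False)).slope
                  for stop in range(3, 13)}
        assert all(s == pytest.approx(0.7) for s in slopes)

    def test_synthetic_trace_slope_matches_taylor_bound(self, params):
        c = 1.0
        k = synthetic.effective_rate(params, c)
        tp = np.linspace(0, 0.05 / k, 8)
        tr = synthetic.simulate_trace(params, c, timepoints=tp)
        est = kinetics.initial_rate(tr, LinearWindow(0, 8, False))
        assert est.slope == pytest.approx(params.gain * params.S0 * k, rel=0.03)

    def test_reported_se_matches_monte_carlo_spread(self):
        p = synthetic.MechanisticParams(sigma=10.0)
        rng = np.random.default_rng(5)
        slopes, ses = [], []
        for _ in range(200):
            tr = synthetic.simulate_trace(p, 1.0, rng=rng)
            est = kinetics.initial_rate(tr, LinearWindow(0, len(tr), False))
            slopes.append(est.slope)
            ses.append(est.se)
        assert np.std(slopes) == pytest.approx(np.mean(ses), rel=0.25)

    def test_degenerate_times_rejected(self):
        tr = _trace([0, 1, 2], [0, 1, 2])
        tr.times = np.array([1.0, 1.0, 1.0])  # bypass constructor check
        with pytest.raises(ValueError):
            kinetics.initial_rate(tr, LinearWindow(0, 3, False))


class TestPercentActivation:
    @pytest.mark.parametrize("v_c,expected", [(10.0, 100.0), (2.0, 0.0), (6.0, 50.0)])
    def test_anchors_and_midpoint(self, v_c, expected):
        assert kinetics.percent_activation(v_c, 2.0, 10.0) == pytest.approx(expected)

    def test_exact_invariance_under_common_rescaling(self):
        base = kinetics.percent_activation(4.0, 2.0, 10.0)
        for alpha in (0.25, 3.0, 1e4):
            assert kinetics.percent_activation(4 * alpha, 2 * alpha, 10 * alpha) \
                == pytest.approx(base)

    def test_invalid_control_pair_rejected(self):
        with pytest.raises(ValueError):
            kinetics.percent_activation(1.0, 5.0, 5.0)

    def test_inhibition_below_basal_is_negative(self):
        assert kinetics.percent_activation(1.0, 2.0, 10.0) < 0


class TestRelativeRate:
    def test_basic_ratios(self):
        assert kinetics.relative_rate(3.0, 3.0) == 1.0
        assert kinetics.relative_rate(0.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            kinetics.relative_rate(1.0, 0.0)

    def test_half_rate_mutant_recovered_from_simulation(self):
        p = synthetic.MechanisticParams(sigma=2.0, seed=9)
        mutant = synthetic.MechanisticParams(
            k0=p.k0 / 2, k_ape1=p.k_ape1, sigma=2.0, seed=10)
        rng_wt, rng_mut = np.random.default_rng(9), np.random.default_rng(10)
        v_wt = np.mean([kinetics.initial_rate(
            synthetic.simulate_trace(p, 0.0, role="dmso", rng=rng_wt)).slope
            for _ in range(20)])
        v_mut = np.mean([kinetics.initial_rate(
            synthetic.simulate_trace(mutant, 0.0, role="dmso", rng=rng_mut)).slope
            for _ in range(20)])
        assert kinetics.relative_rate(v_mut, v_wt) == pytest.approx(0.5, abs=0.15)


class TestSaturationProfile:
    def test_noiseless_michaelis_menten_recovered(self):
        s = np.array([1.0, 2, 5, 10, 20, 40])
        v = 1.0 * s / (5.0 + s)
        fit = kinetics.saturation_profile(list(zip(s, v)))
        assert fit.vmax == pytest.approx(1.0, abs=1e-6)
        assert fit.km == pytest.approx(5.0, abs=1e-5)
        assert not fit.non_saturating

    def test_linear_data_flagged_non_saturating(self):
        s = np.array([1.0, 2, 5, 10, 20, 40])
        fit = kinetics.saturation_profile(list(zip(s, 0.001 * s)))
        assert fit.non_saturating and fit.km > 40

    def test_all_zero_rates_give_zero_vmax(self):
        fit = kinetics.saturation_profile([(1, 0.0), (2, 0.0), (5, 0.0), (10, 0.0)])
        assert fit.vmax == 0.0

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            kinetics.saturation_profile([(1, 0.1), (2, 0.2), (5, 0.3)])
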