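"""Waveform feature extraction against analytic cases and brute-force oracles."""

import numpy as np
import pytest

from cardioinverse.features import (
    FeatureError, extract_features, max_upstroke, transient_duration, voltage_integral,
)
from cardioinverse.trace import Trace
from conftest import synthetic_beat


def brute_force_duration(t, x, percent, resolution=0.001):
    """Independent oracle: dense piecewise-linear resampling + crossing scan."""
    td = np.arange(t[0], t[-1], resolution)
    xd = np.interp(td, t, x)
    dxd = np.diff(xd)
    i_up = int(np.argmax(np.diff(np.interp(np.arange(t[0], t[-1], t[1] - t[0]), t, x))))
    base = xd[: int(i_up * (t[1] - t[0]) / resolution) + 1].min() if i_up > 0 else xd.min()
    peak = xd.max()
    thr = peak - percent / 100.0 * (peak - base)
    above = xd >= thr
    i0 = int(np.argmax(above))
    i1 = i0 + int(np.argmax(~above[i0:]))
    return td[i1] - td[i0]


class TestTransientDuration:
    def test_symmetric_triangle_pulse(self):
        # linear ramp 0->1 over 50 ms and back: duration at level L% is
        # (100-L)% of the 100 ms base by similar triangles... measured from
        # the (100-L)/100 amplitude crossing on each flank: 2*50*(L/100)
        t = np.arange(0.0, 101.0)
        x = np.minimum(t, 100.0 - t) / 50.0
        x[x < 0] = 0.0
        d30, _, _ = transient_duration(t, x, 30)
        d80, _, _ = transient_duration(t, x, 80)
        assert d30 == pytest.approx(2 * 50 * 0.30, abs=1e-9)
        assert d80 == pytest.approx(2 * 50 * 0.80, abs=1e-9)

    def test_offset_invariance(self):
        t, x = synthetic_beat(np.random.default_rng(7))
        d1, s1, e1 = transient_duration(t, x, 50)
        d2, s2, e2 = transient_duration(t, x + 123.4, 50)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_positive_scale_invariance(self):
        t, x = synthetic_beat(np.random.default_rng(8))
        for pct in (30, 50, 80):
            d1, _, _ = transient_duration(t, x, pct)
            d2, _, _ = transient_duration(t, 7.5 * x - 3.0, pct)
            assert d1 == pytest.approx(d2, rel=1e-12)

    @pytest.mark.parametrize("percent", [30, 50, 80])
    def test_brute_force_oracle_on_randomized_beats(self, percent):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t, x = synthetic_beat(rng)
            d, _, _ = transient_duration(t, x, percent)
            assert d == pytest.approx(brute_force_duration(t, x, percent), abs=0.1)

    def test_monotone_in_level(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t, x = synthetic_beat(rng)
            d30, _, _ = transient_duration(t, x, 30)
            d50, _, _ = transient_duration(t, x, 50)
            d80, _, _ = transient_duration(t, x, 80)
            assert d30 <= d50 <= d80

    def test_non_repolarizing_trace_raises(self):
        t = np.arange(0.0, 200.0)
        x = 1.0 / (1.0 + np.exp(-(t - 50) / 5))  # rises and stays up
        with pytest.raises(FeatureError, match="repolarize"):
            transient_duration(t, x, 80)

    def test_multiple_beats_are_rejected(self):
        t = np.arange(0.0, 400.0)
        one = np.exp(-((t - 100) ** 2) / 200.0)
        two = one + np.exp(-((t - 300) ** 2) / 200.0)
        with pytest.raises(FeatureError, match="multiple beats"):
            transient_duration(t, two, 50)

    def test_bad_percent_rejected(self):
        t, x = synthetic_beat(np.random.default_rng(0))
        for bad in (0, 100, -5):
            with pytest.raises(ValueError):
                transient_duration(t, x, bad)


class TestMaxUpstroke:
    def test_linear_ramp(self):
        t = np.arange(0.0, 50.0)
        v, _ = max_upstroke(t, 0.25 * t)
        assert v == pytest.approx(0.25)

    def test_scaling_linearity(self):
        t, x = synthetic_beat(np.random.default_rng(5))
        v1, tm1 = max_upstroke(t, x)
        v2, tm2 = max_upstroke(t, 4.0 * x)
        assert v2 == pytest.approx(4.0 * v1, rel=1e-12)
        assert tm1 == tm2

    def test_spline_oracle_on_simulated_beat(self, base_model, base_p):
        # sampled finely enough that the discrete estimator resolves the
        # derivative peak of the calcium upstroke
        import cardioinverse as ci
        from cardioinverse.models import PacingProtocol
        from scipy.interpolate import CubicSpline

        tr = ci.simulate(base_model, base_p, PacingProtocol(
            n_prepace=0, n_record=1, start_from="paced", dt_ms=0.2))
        v, _ = max_upstroke(tr.t, tr.ca)
        cs = CubicSpline(tr.t, tr.ca)
        td = np.arange(tr.t[0], tr.t[-1], 0.01)
        v_spline = cs(td, 1).max()
        assert v == pytest.approx(v_spline, rel=0.02)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            max_upstroke(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestVoltageIntegral:
    def test_constant_integrand(self):
        t = np.arange(0.0, 100.0)
        assert voltage_integral(t, np.full_like(t, 3.0), 10.0, 60.0) == pytest.approx(150.0)

    def test_grid_refinement_stability(self, base_model, base_p):
        import cardioinverse as ci
        from cardioinverse.models import PacingProtocol

        fine = ci.simulate(base_model, base_p,
                           PacingProtocol(n_prepace=0, n_record=1, start_from="paced", dt_ms=0.1))
        coarse = ci.simulate(base_model, base_p,
                             PacingProtocol(n_prepace=0, n_record=1, start_from="paced", dt_ms=1.0))
        i_f = voltage_integral(fine.t, fine.v, 50.0, 400.0)
        i_c = voltage_integral(coarse.t, coarse.v, 50.0, 400.0)
        assert i_c == pytest.approx(i_f, rel=1e-3)

    def test_reversed_interval_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            voltage_integral(t, t, 60.0, 10.0)

    def test_interval_outside_trace_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            voltage_integral(t, t, 10.0, 150.0)


class TestExtractFeatures:
    def test_simulated_beat_has_ordered_durations(self, baseline_features):
        f = baseline_features
        assert 0 < f.apd_v30 <= f.apd_v50 <= f.apd_v80 < 1000.0
        assert 0 < f.apd_ca30 <= f.apd_ca50 <= f.apd_ca80 < 1000.0
        assert f.dcdt_max > 0

    def test_kr_block_prolongs_all_voltage_durations(self, baseline_features, kr_blocked_trace):
        import cardioinverse as ci

        blocked = ci.extract_features(kr_blocked_trace)
        assert blocked.apd_v30 > baseline_features.apd_v30
        assert blocked.apd_v50 > baseline_features.apd_v50
        assert blocked.apd_v80 > baseline_features.apd_v80

    def test_affine_rescaled_trace_keeps_duration_features(self, baseline_trace):
        import cardioinverse as ci

        scaled = Trace(baseline_trace.t, 3.0 * baseline_trace.v + 100.0,
                       50.0 * baseline_trace.ca, provenance="measured")
        f0 = ci.extract_features(baseline_trace)
        f1 = ci.extract_features(scaled)
        for name in ("apd_v30", "apd_v50", "apd_v80", "apd_ca30", "apd_ca50", "apd_ca80"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), abs=1e-6)

    def test_mature_model_has_faster_calcium_upstroke(self, baseline_features, base_model, base_p):
        import cardioinverse as ci
        from cardioinverse.models import PacingProtocol

        p_m = ci.apply_map(ci.paci_map(), base_p)
        tr = ci.simulate(base_model, p_m, PacingProtocol(n_prepace=20, n_record=1))
        f_m = ci.extract_features(tr)
        assert f_m.dcdt_max > baseline_features.dcdt_max

    def test_feature_file_roundtrip(self, baseline_features, tmp_path):
        p = tmp_path / "features.txt"
        baseline_features.save(p)
        text = p.read_text()
        assert "apd_v80" in text and "dcdt_max" in text
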