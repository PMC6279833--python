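"""Structure and behavior of the conductance-scalable AP models."""

import numpy as np
import pytest

import cardioinverse as ci
from cardioinverse.models import (
    PacingProtocol, EVAL_PROTOCOL, SimulationError, current_integrals, simulate,
)
from cardioinverse.parameters import ParameterVector, BlockVector, apply_block

PACI_IDS = ["I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1", "I_NaCa", "I_NaK",
            "I_pCa", "I_f", "I_bNa", "I_bCa", "J_leak", "J_up", "J_rel"]


class TestModelStructure:
    def test_base_model_exposes_the_fifteen_scalable_currents(self, base_model):
        assert sorted(base_model.parameter_names) == sorted(PACI_IDS)
        assert len(base_model.parameter_names) == 15

    def test_mature_model_additionally_exposes_ipk(self, mature_model):
        assert "I_pK" in mature_model.parameter_names
        assert set(mature_model.parameter_names) - set(PACI_IDS) == {"I_pK"}

    def test_scaling_linearity_of_each_current(self, base_model, mature_model):
        # Eq-1 structure: doubling the scale factor exactly doubles the
        # instantaneous current at a fixed state
        for model in (base_model, mature_model):
            y = model.y0 + 0.01 * np.abs(model.y0)  # off-manifold state
            ones = ParameterVector.ones(model.parameter_names)
            c1 = model.currents_at(0.0, y, ones)
            for name in model.parameter_names:
                p2 = ones.copy()
                p2.values[name] = 2.0
                c2 = model.currents_at(0.0, y, p2)
                assert c2[name] == pytest.approx(2.0 * c1[name], rel=1e-12, abs=1e-300)
                for other in model.parameter_names:
                    if other != name:
                        assert c2[other] == pytest.approx(c1[other], rel=1e-12, abs=1e-300)

    def test_all_ones_rhs_matches_independent_current_recomputation(self, base_model):
        """Spot-check the published immature equations at the initial state.

        Independent transcription of the algebraically simple currents
        (driving-force forms) and the voltage equation assembly.
        """
        y = base_model.y0
        R, T, F = 8.314472, 310.0, 96485.3415
        Vm, Nai, Cai = y[0], y[14], y[16]
        q, r = y[12], y[13]
        E_Na = R * T / F * np.log(151.0 / Nai)
        E_K = R * T / F * np.log(5.4 / 150.0)
        E_Ca = 0.5 * R * T / F * np.log(1.8 / Cai)
        cur = base_model.currents_at(0.0, y)
        m, h, j = y[1], y[2], y[3]
        assert cur["I_Na"] == pytest.approx(3671.2302 * m ** 3 * h * j * (Vm - E_Na), rel=1e-10)
        assert cur["I_to"] == pytest.approx(29.9038 * (Vm - E_K) * q * r, rel=1e-10)
        assert cur["I_bNa"] == pytest.approx(0.9 * (Vm - E_Na), rel=1e-10)
        assert cur["I_bCa"] == pytest.approx(0.69264 * (Vm - E_Ca), rel=1e-10)
        assert cur["I_pCa"] == pytest.approx(0.4125 * Cai / (Cai + 0.0005), rel=1e-10)
        assert cur["I_f"] == pytest.approx(30.10312 * y[11] * (Vm + 0.017), rel=1e-10)
        # voltage equation is minus the sum of all transmembrane currents
        dv = base_model.rhs(0.0, y)[0]
        total = sum(v for k, v in cur.items() if k.startswith("I_"))
        assert dv == pytest.approx(-total * 1e-3, rel=1e-10)  # per ms

    def test_all_ones_rhs_matches_independent_tt_recomputation(self, mature_model):
        y = mature_model.y0
        RTONF = 8314.472 * 310.0 / 96485.3415
        Vm, Cai, Nai, Ki = y[0], y[13], y[16], y[17]
        E_Na = RTONF * np.log(140.0 / Nai)
        E_K = RTONF * np.log(5.4 / Ki)
        E_Ca = 0.5 * RTONF * np.log(2.0 / Cai)
        cur = mature_model.currents_at(0.0, y)
        m, h, j = y[4], y[5], y[6]
        assert cur["I_Na"] == pytest.approx(14.838 * m ** 3 * h * j * (Vm - E_Na), rel=1e-10)
        assert cur["I_bNa"] == pytest.approx(0.00029 * (Vm - E_Na), rel=1e-10)
        assert cur["I_bCa"] == pytest.approx(0.000592 * (Vm - E_Ca), rel=1e-10)
        assert cur["I_pCa"] == pytest.approx(0.1238 * Cai / (Cai + 0.0005), rel=1e-10)
        assert cur["I_pK"] == pytest.approx(
            0.0146 * (Vm - E_K) / (1.0 + np.exp((25.0 - Vm) / 5.98)), rel=1e-10)
        assert cur["I_f"] == 0.0
        dv = mature_model.rhs(0.0, y)[0]
        total = sum(v for k, v in cur.items() if k.startswith("I_"))
        assert dv == pytest.approx(-total, rel=1e-10)

    def test_manifest_export(self, base_model, tmp_path):
        p = tmp_path / "manifest.txt"
        base_model.export_manifest(p)
        text = p.read_text()
        assert "I_CaL\t8.635702e-05" in text
        assert "geometry.Cm_F" in text

    def test_conductance_patch_rescales_current(self, base_model):
        patched = ci.build_base_model(patch={"I_Kr": 14.93335})  # half the published value
        y = base_model.y0
        c0 = base_model.currents_at(0.0, y)
        c1 = patched.currents_at(0.0, y)
        assert c1["I_Kr"] == pytest.approx(0.5 * c0["I_Kr"], rel=1e-9)
        assert "I_Kr" in patched.changelog


class TestSimulation:
    def test_repeated_simulation_is_bitwise_identical(self, base_model, base_p):
        a = simulate(base_model, base_p, EVAL_PROTOCOL)
        b = simulate(base_model, base_p, EVAL_PROTOCOL)
        assert np.array_equal(a.v, b.v) and np.array_equal(a.ca, b.ca)

    def test_resting_immature_model_is_finite_over_ten_seconds(self, base_model):
        # no stimulus: the spontaneous model keeps firing but stays bounded
        tr = simulate(base_model, protocol=PacingProtocol(
            n_prepace=0, n_record=10, stim_amplitude=0.0, dt_ms=5.0))
        assert np.all(np.isfinite(tr.v)) and np.all(np.isfinite(tr.ca))
        assert -120 < tr.v.min() < tr.v.max() < 80

    def test_paced_beat_has_physiological_shape(self, baseline_trace):
        assert -90 < baseline_trace.v.min() < -60
        assert 10 < baseline_trace.v.max() < 60
        assert baseline_trace.ca.max() > 2 * baseline_trace.ca.min()

    def test_kr_block_prolongs_apd(self, baseline_trace, kr_blocked_trace):
        f0 = ci.extract_features(baseline_trace)
        f1 = ci.extract_features(kr_blocked_trace)
        assert f1.apd_v80 > f0.apd_v80

    def test_adult_ap_is_shorter_than_immature(self, base_model, mature_model, baseline_features):
        tr = simulate(mature_model, protocol=PacingProtocol(n_prepace=5, n_record=1))
        f_m = ci.extract_features(tr)
        assert f_m.apd_v80 < baseline_features.apd_v80

    def test_tolerance_tightening_barely_moves_apd(self, base_model, base_p):
        loose = simulate(base_model, base_p, EVAL_PROTOCOL)
        tight = simulate(base_model, base_p, PacingProtocol(
            n_prepace=EVAL_PROTOCOL.n_prepace, n_record=1, start_from="paced",
            rtol=1e-7, atol=1e-10))
        a80 = ci.extract_features(loose).apd_v80
        b80 = ci.extract_features(tight).apd_v80
        assert abs(a80 - b80) < 0.5

    def test_currents_recorded_on_request(self, base_model, base_p):
        tr = simulate(base_model, base_p, EVAL_PROTOCOL, record_currents=True)
        assert set(tr.currents) == set(base_model.parameter_names)
        assert all(len(v) == len(tr.t) for v in tr.currents.values())


class TestCurrentIntegrals:
    def test_unperturbed_ranking_matches_published_table(self, base_model, base_p):
        ints = current_integrals(base_model, base_p,
                                 PacingProtocol(n_prepace=0, n_record=1, start_from="paced"))
        order = ["I_K1", "I_CaL", "I_Kr", "I_Na", "I_to", "I_Ks"]
        vals = [ints[k] for k in order]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_blocked_current_integral_shrinks_monotonically(self, base_model, base_p):
        proto = PacingProtocol(n_prepace=0, n_record=1, start_from="paced")
        vals = []
        for frac in (0.0, -0.5, -0.9):
            p = apply_block(base_p, BlockVector({"I_Kr": frac}))
            vals.append(current_integrals(base_model, p, proto)["I_Kr"])
        assert vals[0] > vals[1] > vals[2] > 0
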