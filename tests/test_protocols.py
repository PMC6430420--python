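"""Stimulus schedules, deprivation transforms, protocol-level behavior."""
import dataclasses

import numpy as np
import pytest

from odplast.build import build_simplified
from odplast.params import Deprivation, DriveParams, EEMode, ModelParams
from odplast.protocols import ProtocolSpec, run_simplified
from odplast.simulate import SimplifiedSimulator, apply_deprivation, l4_drive, l4_rates


class TestDrive:
    def test_on_period_input_composition(self):
        from odplast.build import Eyemap
        em = Eyemap(w_ipsi=np.array([0.4]))
        assert l4_drive(em, DriveParams())[0] == pytest.approx(20.0)
        assert l4_rates(em, DriveParams())[0] == pytest.approx(6.0)

    def test_fully_closed_eye_neuron_under_mi(self):
        from odplast.build import Eyemap
        em = Eyemap(w_ipsi=np.array([0.0]))   # w_contra = 1
        mi = apply_deprivation(DriveParams(), Deprivation.MI)
        assert l4_drive(em, mi)[0] == 0.0

    @pytest.mark.parametrize("kind,expected", [
        (Deprivation.MD_CL, (0.0, 10.0, 10.0)),
        (Deprivation.MD_IL, (10.0, 0.0, 10.0)),
        (Deprivation.BD, (0.0, 0.0, 10.0)),
        (Deprivation.MI, (0.0, 10.0, 0.0)),
        (Deprivation.NONE, (10.0, 10.0, 10.0)),
    ])
    def test_deprivation_amplitude_mapping(self, kind, expected):
        d = apply_deprivation(DriveParams(), kind)
        assert (d.a_cl, d.a_il, d.b) == expected

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            apply_deprivation(DriveParams(), "patch")  # type: ignore[arg-type]

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            DriveParams(a_cl=-1.0).validate()


class TestSimplifiedProtocol:
    def test_control_run_keeps_weights_at_upper_bound(self):
        """Under normal vision all products stay in the LTP regime, so
        the feedforward weights never leave the upper bound."""
        p = ModelParams()
        r = run_simplified(ProtocolSpec(deprivation=Deprivation.NONE), p)
        assert np.all(r.w_final == p.ee.w_max)
        assert r.odi_final == pytest.approx(r.odi_initial)

    def test_off_period_silences_the_circuit(self):
        p = ModelParams()
        em, w = build_simplified(1, p)
        sim = SimplifiedSimulator(em, w, p)
        sim.run(25, p.drive, plastic=False)   # ends inside the OFF period
        assert sim.state.r_e == 0.0 and sim.state.r_i == 0.0

    def test_determinism(self):
        spec = ProtocolSpec(deprivation=Deprivation.MD_CL, seed=5)
        p = ModelParams()
        p.simplified.duration_ms = 1500
        r1 = run_simplified(spec, p)
        r2 = run_simplified(spec, p)
        assert np.array_equal(r1.w_final, r2.w_final)
        assert r1.odi_final == r2.odi_final

    def test_bd_moves_all_weights_together(self):
        """Under BD every afferent fires at the same rate, so every
        plastic weight receives the identical update each step."""
        p = ModelParams()
        p.simplified.duration_ms = 3000
        r = run_simplified(ProtocolSpec(deprivation=Deprivation.BD), p)
        assert np.ptp(r.w_final) == pytest.approx(0.0, abs=1e-15)

    def test_network_determinism(self):
        from odplast.build import build_network
        from odplast.simulate import NetworkSimulator
        p = ModelParams()
        args = build_network(3, p)
        sims = []
        for _ in range(2):
            em, w, het = build_network(3, p)
            sim = NetworkSimulator(em, w, het, p)
            sim.run(700, p.drive, rho_target=p.ei.rho_target)
            sims.append(sim)
        assert np.array_equal(sims[0].weights.w_ffw_e, sims[1].weights.w_ffw_e)
        assert np.array_equal(sims[0].weights.w_ie, sims[1].weights.w_ie)
        assert np.array_equal(sims[0].trace, sims[1].trace)

    def test_plasticity_flags_freeze_weights(self):
        from odplast.build import build_network
        from odplast.simulate import NetworkSimulator
        p = ModelParams()
        em, w, het = build_network(2, p)
        sim = NetworkSimulator(em, w, het, p)
        before = {k: v.copy() for k, v in
                  (("fe", w.w_ffw_e), ("fi", w.w_ffw_i),
                   ("re", w.w_rec_ee), ("ie", w.w_ie))}
        sim.run(400, p.drive, rho_target=p.ei.rho_target,
                plastic_ee=False, plastic_ei=False, plastic_ie=False)
        assert np.array_equal(before["fe"], sim.weights.w_ffw_e)
        assert np.array_equal(before["fi"], sim.weights.w_ffw_i)
        assert np.array_equal(before["re"], sim.weights.w_rec_ee)
        assert np.array_equal(before["ie"], sim.weights.w_ie)

    def test_probe_is_side_effect_free(self):
        from odplast.build import build_network
        from odplast.simulate import NetworkSimulator
        p = ModelParams()
        em, w, het = build_network(4, p)
        sim = NetworkSimulator(em, w, het, p)
        sim.run(200, p.drive, rho_target=p.ei.rho_target)
        state = (sim.r_e.copy(), sim.trace.copy(), sim.weights.w_ffw_e.copy())
        pr1 = sim.probe(p.drive)
        pr2 = sim.probe(p.drive)
        assert np.array_equal(pr1["resp_cl"], pr2["resp_cl"])
        assert np.array_equal(state[0], sim.r_e)
        assert np.array_equal(state[1], sim.trace)
        assert np.array_equal(state[2], sim.weights.w_ffw_e)
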