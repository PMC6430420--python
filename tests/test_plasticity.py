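"""The three plasticity rules: thresholds, bounds, batch equivalence."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odplast.params import (
    EEMode,
    EEPlasticityParams,
    EIPlasticityParams,
    IEPlasticityParams,
)
from odplast.plasticity import clip_to_bounds, ee_update, ei_update, ie_update

EE = EEPlasticityParams()
EI = EIPlasticityParams()
IE = IEPlasticityParams()
W0 = 0.01  # interior weight, away from both bounds


class TestEEUpdate:
    @pytest.mark.parametrize("pre,post,expected_dw", [
        (5.0, 6.0, +EE.eta),    # q = 30 > theta_H = 26: potentiation
        (4.0, 5.0, -EE.eta),    # q = 20 in (15, 26): depression
        (2.0, 5.0, 0.0),        # q = 10 < theta_L = 15: no plasticity
    ])
    def test_double_threshold_regimes(self, pre, post, expected_dw):
        assert ee_update(W0, pre, post, EE) == pytest.approx(W0 + expected_dw)

    def test_exactly_at_threshold_is_neutral(self):
        pre, post = 2.0, EE.theta_h / 2.0    # q == theta_H
        for mode in (EEMode.SINGLE, EEMode.DOUBLE):
            p = EEPlasticityParams(mode=mode)
            assert ee_update(W0, pre, post, p) == W0

    def test_single_threshold_depresses_below_theta_h(self):
        p = EEPlasticityParams(mode=EEMode.SINGLE)
        assert ee_update(W0, 1.0, 1.0, p) == pytest.approx(W0 - p.eta)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            ee_update(W0, -1.0, 2.0, EE)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0, 12), st.floats(0, 12), st.floats(0, 12), st.floats(0, 12))
    def test_depends_on_rates_only_through_product(self, a, b, c, d):
        """Two rate pairs with the same product give the same update."""
        q1, q2 = a * b, c * d
        if abs(q1 - q2) < 1e-9:
            assert ee_update(W0, a, b, EE) == ee_update(W0, c, d, EE)

    def test_regime_map_partitions_plane(self):
        """Sign of the update over a rate grid: no-plasticity island at
        low products, depression at intermediate, potentiation at high."""
        pre, post = np.meshgrid(np.linspace(0, 8, 40), np.linspace(0, 8, 40))
        out = ee_update(np.full(pre.shape, W0), pre, post, EE)
        q = pre * post
        assert np.all(out[q < EE.theta_l] == W0)
        mid = (q > EE.theta_l) & (q < EE.theta_h)
        assert np.all(out[mid] < W0)
        assert np.all(out[q > EE.theta_h] > W0)


class TestEIUpdate:
    def test_bcm_fixed_point(self):
        trace = np.sqrt(6.0 * EI.rho_target)   # theta_BCM == 6
        assert ei_update(W0, 5.0, 6.0, trace, EI) == W0

    def test_depression_uses_constant_presynaptic_factor(self):
        trace = np.sqrt(6.0 * EI.rho_target)   # theta_BCM = 6
        out = ei_update(W0, 0.0, 4.0, trace, EI)
        assert out - W0 == pytest.approx(EI.eta * 2.0 * 4.0 * (4.0 - 6.0))
        # identical for any presynaptic rate
        assert ei_update(W0, 9.0, 4.0, trace, EI) == out

    def test_potentiation_gated_at_low_presynaptic_rate(self):
        trace = np.sqrt(6.0 * EI.rho_target)
        assert ei_update(W0, 2.0, 8.0, trace, EI) == W0      # 2 < 3.2 Hz gate
        assert ei_update(W0, 4.0, 8.0, trace, EI) > W0

    def test_sign_changes_exactly_at_threshold(self):
        """Bisection around rho_post = theta_BCM finds the crossover."""
        trace = 5.0
        theta = trace**2 / EI.rho_target
        lo, hi = theta - 1.0, theta + 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if ei_update(W0, 9.0, mid, trace, EI) > W0:
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(theta, abs=1e-6)

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            ei_update(W0, 1.0, 1.0, 1.0, EI, rho_target=0.0)


class TestIEUpdate:
    def test_zero_at_cap(self):
        assert ie_update(W0, 5.0, IE.phi_h_mean, IE) == W0

    def test_silent_below_lower_threshold(self):
        assert ie_update(W0, 5.0, 3.0, IE) == W0      # 3 < phi_L = 5.25

    def test_strengthens_above_cap(self):
        out = ie_update(W0, 5.0, 7.0, IE)
        assert out - W0 == pytest.approx(IE.eta * 5.0 * 1.0)

    def test_releases_between_thresholds_with_floor(self):
        out = ie_update(IE.w_min, 5.0, 5.5, IE)    # phi_L < 5.5 < phi_H
        assert out == IE.w_min                      # clipped at the floor

    def test_per_neuron_cap(self):
        out = ie_update(W0, 5.0, 7.0, IE, phi_h=np.array([6.0, 7.0]))
        assert out[1] == W0 and out[0] > W0


class TestBoundsAndBatching:
    @pytest.mark.parametrize("w,expected", [
        (0.03, EE.w_max), (0.01, 0.01), (0.0, EE.w_min)])
    def test_clip(self, w, expected):
        assert clip_to_bounds(w, EE.w_min, EE.w_max) == expected

    def test_clip_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            clip_to_bounds(0.5, 1.0, 0.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_batched_equals_elementwise(self, seed):
        """Vectorized rule application is exactly per-synapse application."""
        rng = np.random.default_rng(seed)
        n = 16
        w = rng.uniform(EE.w_min, EE.w_max, n)
        pre = rng.uniform(0, 10, n)
        post = rng.uniform(0, 10)
        trace = rng.uniform(0, 10)
        batch_ee = ee_update(w, pre, post, EE)
        batch_ei = ei_update(w, pre, post, trace, EI)
        batch_ie = ie_update(w, pre, post, IE)
        for i in range(n):
            assert batch_ee[i] == ee_update(w[i], pre[i], post, EE)
            assert batch_ei[i] == ei_update(w[i], pre[i], post, trace, EI)
            assert batch_ie[i] == ie_update(w[i], pre[i], post, IE)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0, 20), st.floats(0, 20), st.floats(0, 10))
    def test_weights_stay_in_bounds(self, pre, post, trace):
        for w in (EE.w_min, EE.w_max, 0.5 * (EE.w_min + EE.w_max)):
            assert EE.w_min <= ee_update(w, pre, post, EE) <= EE.w_max
            assert EI.w_min <= ei_update(
                np.clip(w, EI.w_min, EI.w_max), pre, post, trace, EI) <= EI.w_max
            assert ie_update(max(w, IE.w_min), pre, post, IE) >= IE.w_min
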