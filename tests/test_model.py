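"""Flux network: SU kinetics, light capture, full flux sets, ODE structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coraldeb import (STANDARD_INIT, EnvironmentState, HolobiontState,
                      ModelParameters, compute_fluxes, light_capture, rhs,
                      su_rate)
from coraldeb.model import rhs_log
from coraldeb.scenarios import Forcing

BENIGN = EnvironmentState(T=28.0, L=30.0, N=2e-7, X=2e-7)


class TestSuRate:
    def test_missing_substrate_halts_synthesis(self):
        assert su_rate(1.0, 0.0, 5.0) == 0.0
        assert su_rate(1.0, 5.0, 0.0) == 0.0

    def test_closed_form(self):
        # oracle: (1/j_max + 1/A + 1/B - 1/(A+B))^-1 evaluated directly
        assert su_rate(1.0, 1.0, 1.0) == pytest.approx(1.0 / 2.5, rel=1e-12)
        assert su_rate(2.0, 3.0, 5.0) == pytest.approx(
            1.0 / (1 / 2 + 1 / 3 + 1 / 5 - 1 / 8), rel=1e-12)

    def test_saturates_at_capacity(self):
        assert su_rate(1.0, 1e12, 1e12) == pytest.approx(1.0, rel=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            su_rate(1.0, -0.1, 1.0)

    @given(j=st.floats(1e-3, 1e3), A=st.floats(0, 1e4), B=st.floats(0, 1e4))
    @settings(deadline=None, max_examples=200)
    def test_bounded_by_capacity_and_substrates(self, j, A, B):
        r = su_rate(j, A, B)
        assert 0.0 <= r <= min(j, A, B) + 1e-12


class TestLightCapture:
    def test_darkness(self, params):
        assert light_capture(0.0, 0.1, params) == 0.0

    def test_self_shading_monotone(self, params):
        ratios = np.linspace(0.0, 2.0, 20)
        j = [light_capture(30.0, r, params) for r in ratios]
        assert all(a >= b for a, b in zip(j, j[1:]))

    def test_amplification_factor_oracle(self, params):
        # oracle: direct evaluation of the spectral amplification expression
        expected = (1.26 + 1.39 * np.exp(-6.48 * 0.1)) * 1.34 * 30.0
        assert light_capture(30.0, 0.1, params) == pytest.approx(expected, rel=1e-12)

    def test_increasing_in_light(self, params):
        assert light_capture(40.0, 0.1, params) > light_capture(30.0, 0.1, params)


class TestComputeFluxes:
    def test_darkness_no_light_stress(self, params):
        state = HolobiontState(H=1.0, S=0.1, j_CP=0.0, j_SG=0.1)
        f = compute_fluxes(state, EnvironmentState(T=28, L=0.0, N=2e-7, X=2e-7), params)
        assert f.j_CP_target == 0.0
        assert f.j_eL == 0.0
        assert f.c_ROS == 1.0
        assert f.expulsion == 0.0

    def test_reference_temperature_identity_across_variants(self, params):
        state = STANDARD_INIT
        base = compute_fluxes(state, BENIGN, params.with_variant("base"))
        for variant in ("full", "acceleration", "damage"):
            f = compute_fluxes(state, BENIGN, params.with_variant(variant))
            for key, val in f.as_dict().items():
                assert val == pytest.approx(base.as_dict()[key], abs=1e-12), key

    def test_against_independent_base_model_evaluation(self, params):
        """Straight-line re-derivation of every flux from the model
        definitions, with no thermal terms, compared field by field."""
        st_ = HolobiontState(H=2.0, S=0.3, j_CP=1.9, j_SG=0.2)
        p = params
        f = compute_fluxes(st_, BENIGN, p.with_variant("base"))
        ratio = st_.S / st_.H
        j_X = p.j_Xm * 2e-7 / (2e-7 + p.K_X)
        j_N = p.j_Nm * 2e-7 / (2e-7 + p.K_N)
        r_NH = p.sigma_NH * p.n_NH * p.j_HT0
        rho_C = max(st_.j_CP - st_.j_SG / p.y_C, 0.0)
        j_HG = 1.0 / (1.0 / p.j_HGm + 1.0 / (p.y_C * (j_X + rho_C * ratio))
                      + p.n_NH / (j_N + p.n_NX * j_X + r_NH)
                      - 1.0 / (p.y_C * (j_X + rho_C * ratio)
                               + (j_N + p.n_NX * j_X + r_NH) / p.n_NH))
        rho_N = max(j_N + p.n_NX * j_X + r_NH - p.n_NH * j_HG, 0.0)
        j_eC = max(j_X + rho_C * ratio - j_HG / p.y_C, 0.0)
        j_CO2 = p.k_CO2 * j_eC
        r_CH = p.sigma_CH * (p.j_HT0 + (1 - p.y_C) / p.y_C * j_HG)
        r_CS = p.sigma_CS * (p.j_ST0 + (1 - p.y_C) / p.y_C * st_.j_SG)
        j_L = (1.26 + 1.39 * np.exp(-6.48 * ratio)) * p.astar * 30.0
        cin = (j_CO2 + r_CH) / ratio + r_CS
        pot = 1.0 / (1.0 / p.thermal.jCPm_ref + 1.0 / (p.y_CL * j_L) + 1.0 / cin
                     - 1.0 / (p.y_CL * j_L + cin))
        j_eL = max(j_L - st_.j_CP / p.y_CL, 0.0)
        j_NPQ = 1.0 / (1.0 / p.k_NPQ + 1.0 / j_eL)
        c_ROS = 1.0 + max(j_eL - j_NPQ, 0.0) / p.k_ROS
        expected = {
            "j_X": j_X, "j_N": j_N, "rho_C": rho_C, "j_HG": j_HG,
            "rho_N": rho_N, "j_eC": j_eC, "j_CO2": j_CO2, "j_L": j_L,
            "c_ROS": c_ROS, "j_CP_target": pot / c_ROS,
            "expulsion": p.b * (c_ROS - 1.0) * p.j_ST0,
        }
        for key, val in expected.items():
            assert getattr(f, key) == pytest.approx(val, rel=1e-12), key

    def test_mass_balance_identities(self, params):
        state = HolobiontState(H=1.0, S=0.15, j_CP=2.0, j_SG=0.2)
        f = compute_fluxes(state, BENIGN, params)
        ratio = 0.15
        # host carbon: acquisition = growth use + CCM fuel
        assert f.j_X + f.rho_C * ratio == pytest.approx(
            f.j_HG / params.y_C + f.j_eC, abs=1e-9)
        # host nitrogen: acquisition + recycling = growth use + shared surplus
        assert f.j_N + params.n_NX * f.j_X + f.r_NH == pytest.approx(
            params.n_NH * f.j_HG + f.rho_N, abs=1e-9)
        # symbiont carbon: photosynthate = growth use + shared surplus
        assert f.j_CP == pytest.approx(f.j_SG / params.y_C + f.rho_C, abs=1e-9)

    @given(ratio=st.floats(1e-4, 5.0), j_CP=st.floats(0, 3.5),
           j_SG=st.floats(0, 1.5), T=st.floats(15, 40),
           L=st.floats(0, 60), N=st.floats(0, 1e-5), X=st.floats(0, 1e-5))
    @settings(deadline=None, max_examples=150)
    def test_nonnegativity_and_ros_floor(self, ratio, j_CP, j_SG, T, L, N, X):
        p = ModelParameters()
        state = HolobiontState(H=1.0, S=ratio, j_CP=j_CP, j_SG=j_SG)
        f = compute_fluxes(state, EnvironmentState(T=T, L=L, N=N, X=X), p)
        for key in ("j_L", "j_CP_target", "j_eL", "j_NPQ", "expulsion", "j_X",
                    "j_N", "j_CO2", "j_eC", "rho_C", "rho_N", "j_HG",
                    "j_SG_target", "j_HT", "j_ST"):
            val = getattr(f, key)
            assert np.isfinite(val) and val >= 0.0, key
        assert f.c_ROS >= 1.0
        # SU outputs capped by capacity and substrates
        assert f.j_HG <= min(f.alpha * p.j_HGm, f.su_HG_C, f.su_HG_N) + 1e-9
        assert f.j_SG_target <= min(f.alpha * p.j_SGm, f.su_SG_C, f.su_SG_N) + 1e-9
        assert f.j_CP_target <= f.j_CPm + 1e-9

    def test_uptake_saturation(self, params):
        """Feeding and DIN uptake saturate at alpha-scaled maxima."""
        big = EnvironmentState(T=33.0, L=30.0, N=1.0, X=1.0)
        f = compute_fluxes(STANDARD_INIT, big, params)
        assert f.j_X == pytest.approx(f.alpha * params.j_Xm, rel=1e-5)
        assert f.j_N == pytest.approx(f.alpha * params.j_Nm, rel=1e-5)

    def test_negative_state_rejected(self, params):
        with pytest.raises(ValueError):
            HolobiontState(H=1.0, S=-0.1, j_CP=1.0, j_SG=1.0)
        with pytest.raises(ValueError):
            HolobiontState(H=0.0, S=0.1, j_CP=1.0, j_SG=1.0)


class TestRhs:
    def test_scale_invariance_of_specific_rates(self, params):
        forcing = Forcing.constant(28.0)
        y = np.array([1.0, 0.1, 2.8, 1.0])
        d1 = rhs(0.0, y, forcing, params)
        c = 7.3
        y2 = y.copy()
        y2[:2] *= c
        d2 = rhs(0.0, y2, forcing, params)
        np.testing.assert_allclose(d2[:2] / y2[:2], d1[:2] / y[:2], rtol=1e-12)
        np.testing.assert_allclose(d2[2:], d1[2:], rtol=1e-12)

    def test_log_form_consistent_with_linear_form(self, params):
        forcing = Forcing.constant(31.0)
        y = np.array([2.0, 0.3, 1.5, 0.4])
        lin = rhs(0.0, y, forcing, params)
        log = rhs_log(0.0, np.array([np.log(2.0), np.log(0.3), 1.5, 0.4]),
                      forcing, params)
        np.testing.assert_allclose(log[0], lin[0] / y[0], rtol=1e-12)
        np.testing.assert_allclose(log[1], lin[1] / y[1], rtol=1e-12)
        np.testing.assert_allclose(log[2:], lin[2:], rtol=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(y_C=1.5)
        with pytest.raises(ValueError):
            ModelParameters(variant="other")
        with pytest.raises(KeyError):
            ModelParameters().scaled("not_a_parameter", 2.0)
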