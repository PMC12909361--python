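"""Structural PK models: closed forms, mass balance, physiology scaling
and the reflection-coefficient constraint transform."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from dpinns import pk_models as pk

KE6 = np.log(2.0) / 6.0


class TestOneCompartment:
    @pytest.mark.parametrize("C,ke,expected", [
        (20.0, 0.1, -2.0),
        (0.0, 0.3, 0.0),
        (10.0, KE6, -1.1552453009332421),
    ])
    def test_rhs_linear_elimination(self, C, ke, expected):
        p = pk.OneCompartmentParams(Vd=15.0, ke=ke, dose=300.0)
        assert pk.onecomp_rhs(C, 0.0, p) == pytest.approx(expected)

    @pytest.mark.parametrize("dose,Vd,expected", [
        (300.0, 15.0, 20.0), (0.0, 15.0, 0.0), (300.0, 10.0, 30.0)])
    def test_initial_condition(self, dose, Vd, expected):
        p = pk.OneCompartmentParams(Vd=Vd, ke=KE6, dose=dose)
        assert pk.onecomp_initial(p) == pytest.approx(expected)

    @pytest.mark.parametrize("t,expected", [
        (0.0, 20.0), (6.0, 10.0), (24.0, 1.25)])
    def test_closed_form_half_lives(self, t, expected):
        p = pk.OneCompartmentParams(Vd=15.0, ke=KE6, dose=300.0)
        assert pk.onecomp_closed_form(t, p) == pytest.approx(expected)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            pk.OneCompartmentParams(Vd=-1.0, ke=0.1, dose=300.0)
        with pytest.raises(ValueError):
            pk.OneCompartmentParams(Vd=15.0, ke=0.0, dose=300.0)
        p = pk.OneCompartmentParams(Vd=15.0, ke=0.1, dose=300.0)
        with pytest.raises(ValueError):
            pk.onecomp_closed_form(-1.0, p)
        with pytest.raises(ValueError):
            pk.onecomp_rhs(np.nan, 0.0, p)

    def test_numeric_solve_matches_closed_form(self):
        p = pk.OneCompartmentParams(Vd=15.0, ke=KE6, dose=300.0)
        times = np.array([0.5, 1.0, 2.0, 6.0, 12.0, 24.0])
        sol = solve_ivp(lambda t, y: pk.onecomp_rhs(y, t, p), (0.0, 24.0),
                        [pk.onecomp_initial(p)], t_eval=times,
                        rtol=1e-11, atol=1e-13)
        np.testing.assert_allclose(sol.y[0], pk.onecomp_closed_form(times, p),
                                   rtol=1e-8)


@pytest.fixture(scope="module")
def reference_setup():
    phys = pk.scale_physiology(70.0)
    est = pk.MPBPKEstimands(CLp=0.0115, sigma1=0.8378, sigma2=0.7529)
    inf = pk.InfusionSchedule(dose=70.0, T_inf=1.5)
    return phys, est, inf


class TestMPBPK:
    def test_empty_system_stays_empty_after_infusion(self, reference_setup):
        phys, est, inf = reference_setup
        d = pk.mpbpk_rhs(np.zeros(4), 10.0, phys, est, inf)
        np.testing.assert_array_equal(d, 0.0)

    def test_mass_balance_random_states(self, reference_setup, rng):
        # volume-weighted derivative sum equals input minus plasma clearance
        phys, est, inf = reference_setup
        vols = np.array([phys.V_plasma, phys.V_tight, phys.V_leaky,
                         phys.V_lymph])
        for t in (0.5, 10.0):
            inp = inf.dose / inf.T_inf if t <= inf.T_inf else 0.0
            for _ in range(20):
                state = rng.uniform(0.0, 30.0, 4)
                d = pk.mpbpk_rhs(state, t, phys, est, inf)
                assert float(vols @ d) == pytest.approx(
                    inp - est.CLp * state[0], rel=1e-12, abs=1e-12)

    def test_single_evaluation_hand_computed(self, reference_setup):
        # unit plasma concentration, empty peripheral compartments
        phys, est, inf = reference_setup
        d = pk.mpbpk_rhs(np.array([1.0, 0.0, 0.0, 0.0]), 10.0, phys, est, inf)
        exp_p = -(phys.L1 * (1 - est.sigma1) + phys.L2 * (1 - est.sigma2)
                  + est.CLp) / phys.V_plasma
        assert d[0] == pytest.approx(exp_p)
        assert d[1] == pytest.approx(phys.L1 * (1 - est.sigma1) / phys.V_tight)
        assert d[2] == pytest.approx(phys.L2 * (1 - est.sigma2) / phys.V_leaky)
        assert d[3] == pytest.approx(0.0)

    def test_eig_solver_matches_time_stepping(self, reference_setup):
        phys, est, inf = reference_setup
        times = np.array([0.5, 1.5, 3.0, 24.0, 168.0, 2376.0])
        a = pk.mpbpk_solve(times, phys, est, inf, method="expm")
        b = pk.mpbpk_solve(times, phys, est, inf, method="ivp")
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-10)

    def test_total_amount_strictly_decreasing_post_infusion(self, reference_setup):
        phys, est, inf = reference_setup
        times = np.geomspace(2.0, 2376.0, 40)
        sol = pk.mpbpk_solve(times, phys, est, inf)
        vols = np.array([phys.V_plasma, phys.V_tight, phys.V_leaky,
                         phys.V_lymph])
        amount = sol @ vols
        assert np.all(np.diff(amount) < 0)

    def test_invariant_enforcement(self):
        with pytest.raises(ValueError):
            pk.MPBPKEstimands(CLp=0.01, sigma1=0.5, sigma2=0.7)  # order
        with pytest.raises(ValueError):
            pk.MPBPKEstimands(CLp=-0.01, sigma1=0.8, sigma2=0.7)


class TestPhysiologyScaling:
    def test_identity_at_reference_weight(self):
        ref = pk.load_reference_physiology()
        phys = pk.scale_physiology(ref["reference_weight"])
        assert phys.V_plasma == pytest.approx(ref["V_plasma"])
        assert phys.L == pytest.approx(ref["L_total"])

    def test_linearity_and_flow_partition(self):
        p70 = pk.scale_physiology(70.0)
        p140 = pk.scale_physiology(140.0)
        for name in ("V_plasma", "V_lymph", "V_tight", "V_leaky", "L"):
            assert getattr(p140, name) == pytest.approx(2 * getattr(p70, name))
        for bw in (50.0, 62.5, 75.0):
            p = pk.scale_physiology(bw)
            assert p.L1 + p.L2 == pytest.approx(p.L)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            pk.scale_physiology(0.0)


class TestConstrainReflection:
    def test_origin_maps_to_half_and_quarter(self):
        s1, s2 = pk.constrain_reflection(0.0, 0.0)
        assert s1 == pytest.approx(0.5)
        assert s2 == pytest.approx(0.25)

    def test_saturation(self):
        s1, s2 = pk.constrain_reflection(50.0, 50.0)
        assert s1 == pytest.approx(1.0, abs=1e-10)
        assert s2 == pytest.approx(s1, abs=1e-10)

    def test_ordering_holds_for_random_raws(self, rng):
        raw = rng.normal(scale=3.0, size=(1000, 2))
        s1, s2 = pk.constrain_reflection(raw[:, 0], raw[:, 1])
        assert np.all((0 < s2) & (s2 < s1) & (s1 < 1))

    @given(st.floats(-20, 20), st.floats(-20, 20), st.floats(0.01, 1.0))
    def test_monotone_in_each_argument(self, r1, r2, d):
        s1a, s2a = pk.constrain_reflection(r1, r2)
        s1b, _ = pk.constrain_reflection(r1 + d, r2)
        _, s2c = pk.constrain_reflection(r1, r2 + d)
        assert s1b > s1a
        assert s2c > s2a


def test_registry_round_trip_and_unknown_name():
    spec = pk.get_model("onecomp_iv_bolus")
    assert spec.n_states == 1
    spec2 = pk.get_model("mpbpk_mab")
    assert spec2.n_states == 4 and spec2.parameter_names[0] == "CLp"
    with pytest.raises(KeyError, match="mpbpk_mab"):
        pk.get_model("nonexistent")
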