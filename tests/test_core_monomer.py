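"""Unit and property tests for the monomeric-kinase dose-shift model."""

import numpy as np
import pytest

from rafresist.core_monomer import (
    MonomerSystem,
    fold_curve,
    fold_dose_implicit,
    fold_dose_linear,
    fold_dose_saturated,
    solve_reference_state,
)
from rafresist.errors import InvalidParameterError, RegimeError, RegimeWarning

from _oracles import monomer_mass_action_steady_state


def make_system(**overrides):
    params = dict(Kd=10.0, KS=100.0, kcat=1.0, kp=1.0, E0tot=50.0, Stot=100.0, I0=30.0)
    params.update(overrides)
    return MonomerSystem(**params)


class TestReferenceState:
    def test_closed_form_no_inhibitor_small_enzyme(self):
        # with no drug, negligible catalysis and E << S: E = E0tot/(1 + Stot/KS)
        sys = make_system(kcat=1e-9, E0tot=1.0, Stot=1000.0, KS=100.0)
        E, S = solve_reference_state(sys, 0.0)
        assert E == pytest.approx(1.0 / 11.0, rel=1e-3)
        assert S == pytest.approx(1000.0, rel=1e-3)

    def test_saturating_dose_drives_free_kinase_to_zero(self):
        sys = make_system()
        E, _ = solve_reference_state(sys, 1e12)
        assert E < 1e-9 * sys.E0tot

    def test_conservation_residuals(self):
        sys = make_system()
        E, S = solve_reference_state(sys, 30.0)
        inh = 1.0 + 30.0 / sys.Kd
        occ = 1.0 + sys.kcat / sys.kp + 30.0 / sys.Kd
        assert E * inh * (1.0 + S / sys.KS) == pytest.approx(sys.E0tot, rel=1e-10)
        assert S * (1.0 + E * occ / sys.KS) == pytest.approx(sys.Stot, rel=1e-10)
        assert 0 < E <= sys.E0tot and 0 < S <= sys.Stot

    def test_matches_mass_action_ode_oracle(self):
        sys = make_system()
        E, S = solve_reference_state(sys, 30.0)
        E_ode, S_ode = monomer_mass_action_steady_state(
            sys.Kd, sys.KS, sys.kcat, sys.kp, sys.E0tot, sys.Stot, 30.0
        )
        assert E == pytest.approx(E_ode, rel=1e-6)
        assert S == pytest.approx(S_ode, rel=1e-6)

    def test_mass_action_oracle_random_parameter_sets(self):
        rng = np.random.default_rng(20230802)
        for _ in range(50):
            Kd = 10.0 ** rng.uniform(0, 3)
            KS = 10.0 ** rng.uniform(0, 3)
            kcat = 10.0 ** rng.uniform(-1, 1)
            kp = 10.0 ** rng.uniform(-1, 1)
            E0tot = 10.0 ** rng.uniform(0, 2)
            Stot = 10.0 ** rng.uniform(1, 3)
            dose = rng.uniform(0.0, 5.0) * Kd
            sys = MonomerSystem(Kd=Kd, KS=KS, kcat=kcat, kp=kp,
                                E0tot=E0tot, Stot=Stot, I0=Kd)
            E, S = solve_reference_state(sys, dose)
            E_ode, S_ode = monomer_mass_action_steady_state(
                Kd, KS, kcat, kp, E0tot, Stot, dose
            )
            np.testing.assert_allclose([E, S], [E_ode, S_ode], rtol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            make_system(E0tot=-1.0)
        with pytest.raises(InvalidParameterError):
            solve_reference_state(make_system(), -5.0)
        with pytest.raises(InvalidParameterError):
            MonomerSystem(Kd=10, KS=100, kcat=1, kp=1, E0tot=1, Stot=10, I0=1,
                          kSp=1.0, kSn=50.0)  # KS != kSn/kSp


class TestFoldDoseImplicit:
    def test_identity_at_L_equal_one(self):
        assert fold_dose_implicit(make_system(), 1.0).F == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_L(self):
        sys = make_system()
        F = [fold_dose_implicit(sys, L).F for L in (1, 2, 4, 8, 100, 1e4)]
        assert all(b > a for a, b in zip(F, F[1:]))

    def test_linear_regime_agreement(self):
        sys = make_system(Kd=1.0, I0=100.0, E0tot=0.1, Stot=1000.0, KS=100.0)
        for L in (1.5, 2.0, 5.0):
            Fi = fold_dose_implicit(sys, L).F
            Fl = fold_dose_linear(sys, L).F
            assert abs(Fi - Fl) / Fi < 0.01

    def test_linear_equivalence_property(self):
        # whenever L*E0tot <= 0.01*Stot and I0/Kd >= 10 the closed form is
        # within 2% of the exact solve
        rng = np.random.default_rng(7)
        for _ in range(20):
            Stot = 10.0 ** rng.uniform(2, 3)
            E0tot = 10.0 ** rng.uniform(-2, -1)
            Kd = 10.0 ** rng.uniform(0, 1)
            I0 = Kd * 10.0 ** rng.uniform(1, 3)
            sys = MonomerSystem(Kd=Kd, KS=100.0, kcat=1.0, kp=1.0,
                                E0tot=E0tot, Stot=Stot, I0=I0)
            L = rng.uniform(1.0, 0.01 * Stot / E0tot)
            Fi = fold_dose_implicit(sys, L).F
            Fl = fold_dose_linear(sys, L).F
            assert abs(Fi - Fl) / Fi < 0.02

    def test_unreachable_flux_raises_regime_error(self):
        with pytest.raises(RegimeError):
            fold_dose_implicit(make_system(), 1e-9)


class TestFoldDoseLinear:
    def test_closed_form_values(self):
        sys = make_system(Kd=30.0, I0=30.0, E0tot=0.1, Stot=1000.0)  # I0/Kd = 1
        assert fold_dose_linear(sys, 1.0).F == pytest.approx(1.0)
        assert fold_dose_linear(sys, 2.0).F == pytest.approx(3.0)

    def test_dose_tracks_abundance_when_ic50_exceeds_kd(self):
        sys = make_system(Kd=0.03, I0=30.0, E0tot=0.1, Stot=1000.0)  # I0/Kd = 1000
        F = fold_dose_linear(sys, 10.0).F
        assert F == pytest.approx(10.009, abs=1e-3)
        assert abs(F - 10.0) < 0.01 * 10.0

    def test_warns_outside_regime(self):
        with pytest.warns(RegimeWarning):
            fold_dose_linear(make_system(E0tot=50.0, Stot=100.0), 2.0)


class TestFoldDoseSaturated:
    def test_agrees_with_implicit_deep_in_saturation(self):
        sys = make_system(Kd=10.0, I0=1000.0, E0tot=0.1, Stot=100.0, KS=100.0)
        L = 100.0 * sys.Stot / sys.E0tot
        Fi = fold_dose_implicit(sys, L).F
        Fs = fold_dose_saturated(sys, L).F
        assert abs(Fs - Fi) / Fi < 0.05

    def test_plateau_at_large_L(self):
        # dF/dL -> 0: further overexpression no longer requires large dose increases
        sys = make_system(Kd=10.0, I0=1000.0, E0tot=0.1, Stot=100.0)
        L_values = np.array([1e4, 1e5, 1e6, 1e7])
        F = np.array([fold_dose_implicit(sys, L).F for L in L_values])
        slopes = np.diff(F) / np.diff(L_values)
        assert all(b < a for a, b in zip(slopes, slopes[1:]))
        # elasticity dlnF/dlnL tends to zero
        assert slopes[-1] * L_values[-1] / F[-1] < 0.01

    def test_high_dose_limit_matches_printed_simplification(self):
        # I0 >> Kd: F -> (KS + Stot) / E0tot
        sys = make_system(Kd=0.01, I0=1e5, E0tot=0.1, Stot=100.0, KS=100.0)
        F = fold_dose_saturated(sys, 1e6).F
        assert F == pytest.approx((sys.KS + sys.Stot) / sys.E0tot, rel=0.01)

    def test_sympy_rederivation_of_closed_form(self):
        # solve the substrate-limited equal-flux condition symbolically and
        # compare with the implemented closed form at random parameters
        import sympy as sp

        L, F, Kd, KS, kcat, kp, E0, St, I0 = sp.symbols(
            "L F Kd KS kcat kp E0 St I0", positive=True
        )
        E0_free = E0 / ((I0 / Kd + 1) * (St / KS + 1))
        S_over = St / (1 + (L * E0 / KS) * (1 + kcat / kp + F * I0 / Kd))
        eq = sp.Eq(L * E0 * S_over, E0_free * St)
        F_sym = sp.solve(eq, F)[0]
        vals = {Kd: 10.0, KS: 100.0, kcat: 1.0, kp: 1.0, E0: 0.1, St: 100.0,
                I0: 1000.0, L: 1e5}
        sys = make_system(Kd=10.0, KS=100.0, kcat=1.0, kp=1.0, E0tot=0.1,
                          Stot=100.0, I0=1000.0)
        expected = float(F_sym.subs(vals))
        assert fold_dose_saturated(sys, 1e5).F == pytest.approx(expected, rel=1e-12)

    def test_warns_outside_regime_and_rejects_negative_F(self):
        sys = make_system(Kd=10.0, I0=1000.0, E0tot=0.1, Stot=100.0)
        with pytest.warns(RegimeWarning):
            fold_dose_saturated(sys, 100.0)  # L*E0tot = Stot/10
        # a phosphatase far slower than the kinase makes the product pool the
        # dominant substrate sink and the closed form turns negative
        pathological = make_system(kcat=1000.0, kp=1e-3, E0tot=50.0, Stot=100.0,
                                   I0=1.0)
        with pytest.warns(RegimeWarning):
            with pytest.raises(RegimeError):
                fold_dose_saturated(pathological, 1.5)


class TestCurveProperties:
    def test_substrate_reserve_ordering(self):
        # F(L) for Stot/E0tot = 10 never exceeds the curve for Stot/E0tot = 1000
        small = make_system(E0tot=1.0, Stot=10.0, I0=100.0)
        large = make_system(E0tot=1.0, Stot=1000.0, I0=100.0)
        for L in np.logspace(0, 4, 17):
            assert fold_dose_implicit(small, L).F <= fold_dose_implicit(large, L).F * (1 + 1e-9)

    def test_slope_decreases_beyond_saturation(self):
        sys = make_system(E0tot=1.0, Stot=10.0, I0=100.0)
        L_values = np.logspace(1.2, 4, 12)  # L*E0tot > Stot throughout
        F = np.array([fold_dose_implicit(sys, L).F for L in L_values])
        slopes = np.diff(F) / np.diff(L_values)
        assert all(b < a * (1 + 1e-9) for a, b in zip(slopes, slopes[1:]))

    def test_fold_curve_dataframe(self):
        df = fold_curve(make_system(), [1.0, 2.0, 4.0])
        assert list(df.columns) == ["L", "F", "regime"]
        assert df.F.is_monotonic_increasing
        assert set(df.regime) <= {"linear", "intermediate", "saturated"}
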