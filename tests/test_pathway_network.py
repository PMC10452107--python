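"""Tests for the rule-based pathway engine: toy oracles, invariants, counts."""

import itertools

import numpy as np
import pytest

from rafresist.dimer_kinase import DimerSystem, dimer_equilibrium
from rafresist.errors import InvalidParameterError, NetworkOverflowError
from rafresist.inhibitor_pharmacology import (
    InhibitorSpec,
    ThermodynamicFactors,
    closed_factors,
    preset_inhibitor,
    preset_pair,
)
from rafresist.pathway_network import (
    ModelConfig,
    Protomer,
    SimulationCondition,
    build_model,
    generate_network,
    initial_state,
    moiety_totals,
    observables,
    simulate_steady_state,
)
from rafresist.pathway_network.params import PathwayParameters


BINDING_ONLY = ModelConfig(include_ras=False, include_sos=False,
                           include_mek_erk=False, enable_feedback=False,
                           enable_activation_phos=False,
                           enable_inhibitory_phos=False)


def dimer_scheme_network(Rtot=100.0, kdim=640.0, kd_ref=10.0,
                         fa=1.0, g1a=1.0, phi=0.5):
    """The five-species dimer scheme expressed as rules (single isoform)."""
    cond = SimulationCondition(araf=0.0, braf=Rtot, craf=0.0, ras_total=0.0,
                               sos_total=0.0)
    spec = InhibitorSpec("toy", "I", Kd_ref=kd_ref)
    factors = closed_factors(fa=fa, g1a=g1a)
    # neutral interface multipliers and isoform selectivity: the toy protomer
    # is a generic kinase, not a specific RAF isoform
    params = PathwayParameters(kdim0=kdim, phi=phi, dimer_kd_mult={},
                               isoform_kd_penalty={})
    model = build_model(cond, [spec], factors, params=params,
                        config=BINDING_ONLY)
    return generate_network(model), cond


class TestNetworkGeneration:
    def test_dimer_scheme_has_exactly_five_species(self):
        net, _ = dimer_scheme_network()
        assert net.n_species == 5

    def test_hand_enumerated_single_isoform_network(self):
        # one RAF isoform, no inhibitor, no feedback: the species set is
        # enumerable by hand (monomer: ras x actP; dimers: unordered pairs)
        cond = SimulationCondition(araf=0.0, braf=0.0, craf=50.0)
        config = ModelConfig(enable_feedback=False, enable_inhibitory_phos=False)
        net = generate_network(build_model(cond, config=config))
        protomers = [Protomer("C", ras, 0, 0, 0, ap)
                     for ras in (0, 1) for ap in (0, 1)]
        expected = {("RASgdp",), ("RASgtp",), ("SOS", "cyt"), ("SOS", "mem")}
        expected |= {("MEK", n) for n in range(3)}
        expected |= {("ERK", n) for n in range(3)}
        expected |= {("RAFm", p) for p in protomers}
        expected |= {("RAFd",) + tuple(sorted(pair))
                     for pair in itertools.combinations_with_replacement(protomers, 2)}
        assert set(net.species) == expected
        assert net.n_species == 24

    def test_zero_abundance_isoform_generates_no_species(self):
        cond = SimulationCondition(araf=0.0)
        net = generate_network(build_model(cond))
        assert not any("RAF_A" in str(k)
                       for sp in net.species
                       for k in [tuple(m for m in [sp])]
                       if sp[0] in ("RAFm", "RAFd")
                       and any(p.iso == "A" for p in sp[1:]))

    def test_full_default_configuration_builds_and_reports_counts(self):
        s1, s2, factors = preset_pair("I", "II")
        net = generate_network(build_model(SimulationCondition(), [s1, s2],
                                           factors))
        assert net.n_species > 300
        assert net.n_reactions > 2000
        net.check_mass_balance()

    def test_species_cap_overflow_names_rule(self):
        s1, s2, factors = preset_pair("I", "II")
        with pytest.raises(NetworkOverflowError):
            generate_network(build_model(SimulationCondition(), [s1, s2],
                                         factors), species_cap=50)

    def test_inconsistent_factors_rejected(self):
        bad = ThermodynamicFactors(fa=0.5, g1a=2.0, g2a=3.0)
        with pytest.raises(InvalidParameterError):
            build_model(SimulationCondition(), [preset_inhibitor("I")[0]], bad)


class TestDimerSchemeOracle:
    @pytest.mark.parametrize("fa,g1a,dose", [(1.0, 1.0, 20.0),
                                             (0.1, 10.0, 5.0),
                                             (0.1, 200.0, 50.0)])
    def test_rule_engine_matches_dimer_kinase_equilibrium(self, fa, g1a, dose):
        # the thermodynamic factor conventions map as f = 1/fa, g = 1/g1a
        Rtot, kdim, kd_ref = 100.0, 640.0, 10.0
        net, cond = dimer_scheme_network(Rtot, kdim, kd_ref, fa, g1a)
        res = simulate_steady_state(net, cond.with_doses(dose1=dose))
        assert res.converged
        sys = DimerSystem(Rtot=Rtot, I=dose, Kdim=kdim, KdI=kd_ref,
                          f=1.0 / fa, g=1.0 / g1a)
        ref = dimer_equilibrium(sys)
        p0 = Protomer("B", 0, 0, 0, 0, 0)
        p1 = Protomer("B", 0, 1, 0, 0, 0)
        got = {
            "R": res.concentration(("RAFm", p0)),
            "RI": res.concentration(("RAFm", p1)),
            "RR": res.concentration(("RAFd", p0, p0)),
            "RRI": res.concentration(("RAFd",) + tuple(sorted((p0, p1)))),
            "IRRI": res.concentration(("RAFd", p1, p1)),
        }
        for name, expected in (("R", ref.R), ("RI", ref.RI), ("RR", ref.RR),
                               ("RRI", ref.RRI), ("IRRI", ref.IRRI)):
            assert got[name] == pytest.approx(expected, rel=1e-6, abs=1e-9), name

    def test_equilibrium_independent_of_phi(self):
        # binding-only network: phi redistributes kinetics, not equilibria
        results = []
        for phi in (0.0, 0.5, 1.0):
            net, cond = dimer_scheme_network(fa=0.2, g1a=5.0, phi=phi)
            res = simulate_steady_state(net, cond.with_doses(dose1=15.0))
            results.append(res.y[[net.index[sp] for sp in sorted(net.species)]])
        np.testing.assert_allclose(results[0], results[1], rtol=1e-6)
        np.testing.assert_allclose(results[0], results[2], rtol=1e-6)


class TestSteadyState:
    def test_moiety_conservation_along_trajectory(self):
        spec, factors = preset_inhibitor("II")
        cond = SimulationCondition(ras_status="mutant", dose1=20.0)
        net = generate_network(build_model(cond, [spec], factors))
        y0 = initial_state(net, cond)
        start = moiety_totals(net, y0)
        for hours in (0.1, 10.0):
            res = simulate_steady_state(net, cond, t_hours=hours, max_hours=hours)
            end = moiety_totals(net, res.y)
            for moiety, total in start.items():
                assert end[moiety] == pytest.approx(total, rel=1e-6), moiety

    def test_zero_inhibitor_state_independent_of_factors(self):
        cond = SimulationCondition(ras_status="mutant")
        spec_I, fac_I = preset_inhibitor("I")
        spec_Ih, fac_Ih = preset_inhibitor("I_half")
        obs = []
        for spec, fac in ((spec_I, fac_I), (spec_Ih, fac_Ih)):
            net = generate_network(build_model(cond, [spec], fac))
            res = simulate_steady_state(net, cond)
            obs.append(observables(res))
        assert obs[0]["ppERK"] == pytest.approx(obs[1]["ppERK"], rel=1e-6)
        assert obs[0]["dimer_total"] == pytest.approx(obs[1]["dimer_total"],
                                                      rel=1e-6)

    def test_all_kinase_rates_zero_gives_zero_pperk(self):
        params = PathwayParameters(k_mek=0.0)
        cond = SimulationCondition(ras_status="mutant")
        net = generate_network(build_model(cond, params=params))
        res = simulate_steady_state(net)
        obs = observables(res)
        assert obs["ppERK"] == pytest.approx(0.0, abs=1e-9)
        assert obs["ppMEK"] == pytest.approx(0.0, abs=1e-9)

    def test_observables_partition_dimers_and_conserve_erk(self):
        cond = SimulationCondition(araf=0.0, ras_status="mutant")
        net = generate_network(build_model(cond))
        res = simulate_steady_state(net)
        obs = observables(res)
        # no ARAF: every ARAF-containing dimer class is identically zero
        assert obs["dimer_AA"] == 0.0
        assert obs["dimer_AB"] == 0.0
        assert obs["dimer_AC"] == 0.0
        assert obs["dimer_total"] > 0.0
        totals = moiety_totals(net, res.y)
        assert totals["ERK"] == pytest.approx(cond.erk_total, rel=1e-6)

    def test_basal_pperk_positive_wild_type(self):
        net = generate_network(build_model(SimulationCondition()))
        res = simulate_steady_state(net)
        assert res.converged
        assert observables(res)["ppERK"] > 0.0


class TestRASCalibration:
    def test_wild_type_and_mutant_ras_gtp_levels(self):
        # wild-type low-RTK: ~25 nM; oncogenic RAS (GAP/10): ~250 nM
        for status, target in (("wild-type", 25.0), ("mutant", 250.0)):
            cond = SimulationCondition(ras_status=status)
            net = generate_network(build_model(cond))
            res = simulate_steady_state(net)
            assert res.converged
            assert observables(res)["RASGTP"] == pytest.approx(target, rel=0.2)
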