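"""EMU decomposition, steady-state and nonstationary simulation, oracle."""

import numpy as np
import pytest

from conftest import random_toy_case
from cellflux.emu import EMU, emu_decomposition
from cellflux.network import FluxMap, parse_network, packaged_network
from cellflux.simulate import (
    PoolSizeSet,
    SingularEMUSystem,
    brute_force_isotopomer_oracle,
    simulate_inst_mids,
    simulate_steady_state_mids,
)
from cellflux.tracers import TracerSpec, bernoulli_mid


class TestDecomposition:
    def test_simple_chain(self):
        net = parse_network("% unbalanced: A.x B.x\nR1: A.x (ab) -> B (ab)\nR2: B (ab) -> B.x (ab)")
        system = emu_decomposition(net, [("B", (1, 2))])
        assert EMU("B", (1, 2)) in system.producers
        assert EMU("A.x", (1, 2)) in system.inputs

    def test_condensation_sources_convolve(self):
        net = parse_network(
            """
% unbalanced: X.x Y.x Z.x
INX: X.x (ab) -> X (ab)
INY: Y.x (cd) -> Y (cd)
CND: X (ab) + Y (cd) -> Z (abcd)
OUT: Z (abcd) -> Z.x (abcd)
"""
        )
        system = emu_decomposition(net, [("Z", None)])
        terms = system.producers[EMU("Z", (1, 2, 3, 4))]
        conv = [t for t in terms if len(t.sources) == 2]
        assert conv, "condensation must produce a two-source term"
        srcs = {s.metabolite for s in conv[0].sources}
        assert srcs == {"X", "Y"}

    def test_full_network_measured_fragments_reachable(self, lf_network, measured_fragments):
        system = emu_decomposition(lf_network, measured_fragments)
        assert len(system.observed) == 12
        # every observed fragment has producers resolved down to inputs
        for emu in system.observed:
            assert system.producers[emu]
        # tracer substrates appear among the reachable inputs
        input_mets = {e.metabolite for e in system.inputs}
        assert {"GLC.x", "GLN.x"} <= input_mets

    def test_oversized_fragment_rejected(self, lf_network):
        with pytest.raises(ValueError, match="outside"):
            emu_decomposition(lf_network, [("LAC", (1, 2, 3, 4))])


class TestSteadyState:
    def test_fully_labeled_glucose_gives_m3_pyruvate(self, toy_chain):
        fm = FluxMap(net={"GLUT": 1.0, "GLYC": 1.0, "PYROUT": 2.0})
        res = simulate_steady_state_mids(
            toy_chain, fm, [TracerSpec("GLC.x", (1, 2, 3, 4, 5, 6))], observed=[("PYR", None)]
        )
        assert np.allclose(res.mid("PYR"), [0, 0, 0, 1], atol=1e-12)

    def test_tracer_mixture_is_linear(self, toy_chain):
        fm = FluxMap(net={"GLUT": 1.0, "GLYC": 1.0, "PYROUT": 2.0})
        res = simulate_steady_state_mids(
            toy_chain, fm,
            [TracerSpec("GLC.x", (1, 2, 3, 4, 5, 6), fraction=0.5)],
            observed=[("PYR", None)],
        )
        assert np.allclose(res.mid("PYR"), [0.5, 0, 0, 0.5], atol=1e-12)

    def test_toy_tca_matches_oracle(self, toy_tca):
        net, fm = toy_tca
        tracers = [TracerSpec("AcCoA.x", (1, 2), fraction=0.6)]
        obs = [("CIT", None), ("AKG", None), ("MAL", None)]
        emu = simulate_steady_state_mids(net, fm, tracers, observed=obs)
        orc = brute_force_isotopomer_oracle(net, fm, tracers, observed=obs, max_total_carbons=32)
        for met, _ in obs:
            assert np.max(np.abs(emu.mid(met) - orc.mid(met))) < 1e-8

    def test_outputs_on_simplex(self, lf_network, measured_fragments):
        from cellflux.network import fluxmap_from_table, packaged_flux_table, free_flux_parameterization

        fm = free_flux_parameterization(lf_network).project(
            fluxmap_from_table(packaged_flux_table("lf_21"))
        )
        res = simulate_steady_state_mids(
            lf_network, fm, [TracerSpec("GLC.x", (1, 2))], observed=measured_fragments
        )
        for met, _ in measured_fragments:
            mid = res.mid(met)
            assert np.all(mid >= -1e-9)
            assert mid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_throughput_emu_raises(self):
        net = parse_network(
            "% unbalanced: A.x B.x\nIN: A.x (a) -> M (a)\nOUT: M (a) -> B.x (a)"
        )
        fm = FluxMap(net={"IN": 0.0, "OUT": 0.0})
        with pytest.raises(SingularEMUSystem):
            simulate_steady_state_mids(net, fm, [], observed=[("M", None)])

    @pytest.mark.parametrize("seed", range(10))
    def test_random_networks_match_oracle(self, seed):
        net, flux, tracers, observed = random_toy_case(seed)
        emu = simulate_steady_state_mids(net, flux, tracers, observed=observed)
        orc = brute_force_isotopomer_oracle(net, flux, tracers, observed=observed)
        for met, _ in observed:
            assert np.max(np.abs(emu.mid(met) - orc.mid(met))) < 1e-8

    def test_symmetric_orientation_convention_irrelevant(self):
        # reversing the stored orientation of the symmetric molecule leaves
        # downstream MIDs unchanged
        base = """
% unbalanced: S.x P.x
% symmetric: F
IN: S.x (abcd) -> M (abcd)
TOF: M (abcd) -> F ({F})
FRM: F (abcd) -> N (abcd)
OUT: N (abcd) -> P.x (abcd)
"""
        fm = FluxMap(net={"IN": 1.0, "TOF": 1.0, "FRM": 1.0, "OUT": 1.0})
        tr = [TracerSpec("S.x", (1,))]
        res1 = simulate_steady_state_mids(
            parse_network(base.format(F="abcd")), fm, tr, observed=[("N", (1,)), ("N", None)]
        )
        res2 = simulate_steady_state_mids(
            parse_network(base.format(F="dcba")), fm, tr, observed=[("N", (1,)), ("N", None)]
        )
        assert np.allclose(res1.mid("N", (1,)), res2.mid("N", (1,)), atol=1e-12)


class TestOracle:
    def test_unlabeled_tracers_give_all_m0(self, toy_tca):
        net, fm = toy_tca
        res = brute_force_isotopomer_oracle(net, fm, [], max_total_carbons=32)
        for emu, mid in res.mids.items():
            assert mid[0] == pytest.approx(1.0, abs=1e-12)

    def test_condensation_product_is_convolution(self):
        net = parse_network(
            """
% unbalanced: X.x Y.x Z.x
INX: X.x (ab) -> X (ab)
INY: Y.x (cd) -> Y (cd)
CND: X (ab) + Y (cd) -> Z (abcd)
OUT: Z (abcd) -> Z.x (abcd)
"""
        )
        fm = FluxMap(net={"INX": 1.0, "INY": 1.0, "CND": 1.0, "OUT": 1.0})
        tr = [TracerSpec("X.x", (1,), fraction=0.7), TracerSpec("Y.x", (1, 2), fraction=0.3)]
        res = brute_force_isotopomer_oracle(net, fm, tr, observed=[("Z", None)])
        x = 0.7 * bernoulli_mid(np.array([1.0, 0.0])) + 0.3 * bernoulli_mid(np.zeros(2))
        y = 0.3 * bernoulli_mid(np.ones(2)) + 0.7 * bernoulli_mid(np.zeros(2))
        assert np.allclose(res.mid("Z"), np.convolve(x, y), atol=1e-12)

    def test_refuses_oversized_networks(self, lf_network):
        fm = FluxMap(net={rid: 1.0 for rid in lf_network.reaction_ids})
        with pytest.raises(ValueError, match="oracle limited"):
            brute_force_isotopomer_oracle(lf_network, fm, [])


class TestNonstationary:
    def test_single_pool_closed_form(self):
        net = parse_network("% unbalanced: S.x P.x\nIN: S.x (a) -> S (a)\nOUT: S (a) -> P.x (a)")
        fm = FluxMap(net={"IN": 3.0, "OUT": 3.0})
        t = np.linspace(0, 2, 9)
        res = simulate_inst_mids(
            net, fm, PoolSizeSet(default=5.0), [TracerSpec("S.x", (1,))], t,
            observed=[("S", None)],
        )
        expected = 1 - np.exp(-3.0 * t / 5.0)
        assert np.max(np.abs(res.mid("S")[:, 1] - expected)) < 1e-7

    def test_converges_to_steady_state(self, toy_tca):
        net, fm = toy_tca
        tracers = [TracerSpec("AcCoA.x", (1, 2), fraction=0.6)]
        obs = [("CIT", None), ("MAL", None)]
        pools = PoolSizeSet(default=2.0)
        # slowest pool turnover ~ 2/0.2 = 10; run 25 turnovers
        inst = simulate_inst_mids(net, fm, pools, tracers, np.array([0.0, 250.0]), observed=obs)
        ss = simulate_steady_state_mids(net, fm, tracers, observed=obs)
        for met, _ in obs:
            assert np.max(np.abs(inst.mid(met)[-1] - ss.mid(met))) < 1e-6

    def test_pool_scaling_dilates_time(self, toy_tca):
        net, fm = toy_tca
        tracers = [TracerSpec("AcCoA.x", (1, 2))]
        obs = [("CIT", None)]
        r1 = simulate_inst_mids(
            net, fm, PoolSizeSet(default=1.0), tracers, np.array([0.0, 3.0]), observed=obs
        )
        r10 = simulate_inst_mids(
            net, fm, PoolSizeSet(default=10.0), tracers, np.array([0.0, 30.0]), observed=obs
        )
        assert np.max(np.abs(r1.mid("CIT")[1] - r10.mid("CIT")[1])) < 1e-6

    def test_trajectories_stay_on_simplex(self, toy_tca):
        net, fm = toy_tca
        res = simulate_inst_mids(
            net, fm, PoolSizeSet(default=1.0),
            [TracerSpec("AcCoA.x", (1, 2))], np.linspace(0, 20, 11),
            observed=[("CIT", None)],
        )
        traj = res.mid("CIT")
        assert np.all(traj >= -1e-8)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-7)

    def test_negative_times_rejected(self, toy_tca):
        net, fm = toy_tca
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_inst_mids(
                net, fm, PoolSizeSet(), [TracerSpec("AcCoA.x", (1,))],
                np.array([-1.0, 1.0]), observed=[("CIT", None)],
            )


class TestTracerImpurity:
    def test_full_purity_fully_labels(self):
        mid = bernoulli_mid(np.ones(6))
        assert mid[-1] == pytest.approx(1.0)

    def test_uniform_glucose_purity(self):
        from cellflux.tracers import position_probabilities

        t = TracerSpec("GLC.x", (1, 2, 3, 4, 5, 6), purity=0.99)
        mid = bernoulli_mid(position_probabilities(t, 6))
        assert mid[6] == pytest.approx(0.99**6, rel=1e-12)

    def test_two_position_purity(self):
        from cellflux.tracers import position_probabilities

        t = TracerSpec("GLC.x", (1, 2), purity=0.99)
        mid = bernoulli_mid(position_probabilities(t, 6))
        assert mid[2] == pytest.approx(0.9801, rel=1e-12)
        assert mid[1] == pytest.approx(2 * 0.99 * 0.01, rel=1e-12)
        assert mid[0] == pytest.approx(0.01**2, rel=1e-12)
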