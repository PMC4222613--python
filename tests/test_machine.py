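"""Gated-machine construction, one-way fluxes and coupling diagnostics."""

import math
from fractions import Fraction

import networkx as nx
import pytest

import mfptnet as M
from mfptnet import generators as G
from mfptnet.machine import (
    GateSystem,
    _augment_with_star,
    build_machine_network,
    coupling_and_efficiency,
    decompose_mfpt,
    equilibrium_occupation,
    gate_rates,
    one_way_flux,
    select_gate,
    unit_probability,
)


def _path_system(**kw):
    g = nx.path_graph(6)
    defaults = dict(gate1_prime=0, gate1_dprime=5, gate2_prime=2, gate2_dprime=3,
                    tau1=10.0, tau2=1000.0, betaA1=2.0, betaA2=0.0)
    defaults.update(kw)
    return GateSystem(graph=g, **defaults)


class TestGateSystemValidation:
    def test_duplicate_gates_rejected(self):
        with pytest.raises(M.ValidationError):
            _path_system(gate2_prime=0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(M.ValidationError):
            _path_system(tau1=0.0)

    def test_gate_outside_graph_rejected(self):
        with pytest.raises(M.ValidationError):
            _path_system(gate2_dprime=99)


class TestEquilibriumAndUnitProbability:
    def test_degree_occupation_path(self):
        peq = equilibrium_occupation(nx.path_graph(4))
        assert peq == {0: Fraction(1, 6), 1: Fraction(1, 3),
                       2: Fraction(1, 3), 3: Fraction(1, 6)}
        assert sum(peq.values()) == 1

    def test_unit_probability_balanced_case(self):
        # tau * p_eq = 1 gives p = 1/2
        assert unit_probability(2.0, 0.5) == pytest.approx(0.5)

    def test_unit_probability_tree_leaf(self):
        # a 200-node tree has degree sum 398; a leaf has occupation 1/398
        p = unit_probability(40.0, Fraction(1, 398))
        assert p == pytest.approx(40 / 438)
        assert round(p, 3) == 0.091

    def test_gate_rates_detailed_balance_symmetric(self):
        vp, vm = gate_rates(0.1, 5.0, 0.0, 0.25, 0.25)
        assert vp == pytest.approx(vm)
        vp2, vm2 = gate_rates(0.1, 5.0, 3.0, 0.25, 0.25)
        assert vm2 == pytest.approx(vp2 * math.exp(-3.0))


class TestGateSelection:
    def test_fastest_external_transition_wins(self):
        sys_ = _path_system()  # tau1 << tau2 and betaA1 > 0: "+1" is fastest
        gate, p = select_gate(sys_)
        assert gate == sys_.gate1_dprime
        peq = equilibrium_occupation(sys_.graph)
        assert p == pytest.approx(unit_probability(sys_.tau1, peq[gate]))

    def test_explicit_override(self):
        sys_ = _path_system(selected_gate=2)
        gate, p = select_gate(sys_)
        assert gate == 2
        peq = equilibrium_occupation(sys_.graph)
        assert p == pytest.approx(unit_probability(sys_.tau2, peq[2]))


class TestBuildMachineNetwork:
    def test_probabilities_close_at_every_node(self):
        sys_ = _path_system()
        net = build_machine_network(sys_)
        for l in range(net.n_nodes):
            assert math.fsum(float(e.u) for e in net.edges[l]) == pytest.approx(
                1.0, abs=1e-12
            )
            assert all(e.tau == 1 for e in net.edges[l])

    def test_selected_gate_has_no_waiting(self):
        sys_ = _path_system()
        net = build_machine_network(sys_)
        gate, _ = select_gate(sys_)
        assert all(e.target != gate for e in net.edges[gate][:-1])
        # the deficit went into the last (external) edge, not a self-loop
        assert net.edges[gate][-1].target != gate

    def test_internal_edges_carry_p_over_k(self):
        sys_ = _path_system()
        net = build_machine_network(sys_)
        _, p = select_gate(sys_)
        # node 1 is internal (no gate transitions), degree 2
        internal = [e for e in net.edges[1] if e.target != 1]
        assert [e.target for e in internal] == [0, 2]
        assert all(float(e.u) == pytest.approx(p / 2) for e in internal)

    def test_too_fast_external_transition_rejected(self):
        with pytest.raises(M.ValidationError, match="> 1"):
            build_machine_network(_path_system(tau2=0.001, selected_gate=5))


class TestAugmentedNetworks:
    def test_star_absorbs_redirected_edge(self):
        sys_ = _path_system()
        net = build_machine_network(sys_)
        aug, star = _augment_with_star(net, sys_.gate1_dprime, sys_.gate1_prime)
        assert star == net.n_nodes
        assert aug.edges[star] == []
        targets = [e.target for e in aug.edges[sys_.gate1_dprime]]
        assert star in targets and sys_.gate1_prime not in targets

    def test_missing_edge_rejected(self):
        sys_ = _path_system()
        net = build_machine_network(sys_)
        with pytest.raises(M.ValidationError):
            _augment_with_star(net, 1, 4)


class TestFluxIdentities:
    @pytest.fixture()
    def driven(self):
        sys_ = G.gated_tree(n=40, seed=3, tau1=20, tau2=20, betaA1=8, betaA2=0)
        return sys_, build_machine_network(sys_)

    def test_decomposition_identity(self, driven):
        sys_, net = driven
        total_direct = 1.0 / one_way_flux(net, sys_.gate1_dprime, sys_.gate1_prime,
                                          method="linear")
        internal, gate_term, total = decompose_mfpt(
            net, sys_.gate1_dprime, sys_.gate1_prime, method="linear"
        )
        assert total == pytest.approx(total_direct, rel=1e-9)
        assert internal > 0 and gate_term > 0

    def test_net_flux_equals_stationary_current(self, driven):
        sys_, net = driven
        Jp = one_way_flux(net, sys_.gate1_dprime, sys_.gate1_prime, method="linear")
        Jm = one_way_flux(net, sys_.gate1_prime, sys_.gate1_dprime, method="linear")
        p_st = M.stationary_solve(M.to_rates(net))
        v_fwd = next(float(e.u) for e in net.edges[sys_.gate1_dprime]
                     if e.target == sys_.gate1_prime)
        v_bwd = next(float(e.u) for e in net.edges[sys_.gate1_prime]
                     if e.target == sys_.gate1_dprime)
        current = v_fwd * float(p_st[sys_.gate1_dprime]) - \
            v_bwd * float(p_st[sys_.gate1_prime])
        assert Jp - Jm == pytest.approx(current, rel=1e-8)

    def test_hill_matches_linear_flux(self, driven):
        sys_, net = driven
        a = one_way_flux(net, sys_.gate2_dprime, sys_.gate2_prime, method="hill")
        b = one_way_flux(net, sys_.gate2_dprime, sys_.gate2_prime, method="linear")
        assert a == pytest.approx(b, rel=1e-9)


class TestCouplingAndEfficiency:
    def test_zero_net_input_flux_rejected(self):
        with pytest.raises(M.ValidationError):
            coupling_and_efficiency(1.0, 1.0, 0.5, 0.2, 4.0, 2.0)

    def test_efficiency_formula(self):
        eps, eta = coupling_and_efficiency(3.0, 1.0, 0.2, 1.2, 4.0, 2.0)
        assert eps == pytest.approx(-0.5)
        assert eta == pytest.approx(-(-1.0 * 2.0) / (2.0 * 4.0))

    def test_zero_output_force_gives_undefined_efficiency(self):
        eps, eta = coupling_and_efficiency(3.0, 1.0, 2.0, 0.5, 4.0, 0.0)
        assert eta is None
        assert eps == pytest.approx(0.75)


class TestMachineFluxes:
    def test_driven_machine_positive_coupling(self):
        sys_ = G.gated_tree(n=40, seed=3, tau1=20, tau2=20, betaA1=8, betaA2=0)
        res = M.machine_fluxes(sys_, method="hill")
        assert all(f > 0 for f in (res.J_plus_1, res.J_minus_1,
                                   res.J_plus_2, res.J_minus_2))
        assert res.J1 > 0  # the input reaction is driven forward
        assert 0 < res.epsilon <= 1  # output flux cannot exceed input flux
        assert res.eta is None  # betaA2 = 0: no output force, eta undefined
        assert set(res.mfpts) == {"+1", "-1", "+2", "-2"}

    def test_undriven_machine_has_no_net_flux(self):
        sys_ = G.gated_tree(n=30, seed=1, tau1=15, tau2=15, betaA1=0, betaA2=0)
        res = M.machine_fluxes(sys_, method="linear")
        assert res.J_plus_1 == pytest.approx(res.J_minus_1, rel=1e-9)
        assert res.J_plus_2 == pytest.approx(res.J_minus_2, rel=1e-9)

    def test_linear_and_hill_agree(self):
        sys_ = G.gated_tree(n=30, seed=2, tau1=25, tau2=25, betaA1=6, betaA2=0)
        a = M.machine_fluxes(sys_, method="hill")
        b = M.machine_fluxes(sys_, method="linear")
        for label in a.mfpts:
            assert a.mfpts[label] == pytest.approx(b.mfpts[label], rel=1e-8)
        assert a.epsilon == pytest.approx(b.epsilon, rel=1e-8)
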