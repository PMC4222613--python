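"""Coupled-enzyme machine: gated conformational networks and reaction fluxes.

A protein enzyme catalysing two coupled reactions is modelled as a network
of conformational substates (undirected support, node degrees ``k_l``) with
four distinguished *gate* nodes: reaction ``l`` (l = 1: free-energy
donating, l = 2: accepting) enters at gate ``l'`` and exits at gate
``l''``.  Internal hops occur with probability ``p / k_l`` per neighbour;
the external (chemical) transitions between the gates of reaction ``l``
carry probabilities

    v_plus_l  = p / (tau_l * p_eq(l'')),          (forward, exit from l'')
    v_minus_l = p * exp(-beta*A_l) / (tau_l * p_eq(l')),  (backward, exit from l')

where ``tau_l`` is the external transition time, ``beta*A_l`` the
dimensionless chemical force (the exp factor breaks detailed balance), and
``p_eq(l) = k_l / sum k`` the equilibrium occupation.  The unit probability
``p`` is fixed by requiring ``p + v = 1`` at the gate with the highest
external transition probability:  p = 1 / (1 + (tau_l * p_eq(l))^-1).
Every other node's probability deficit becomes a waiting self-loop; all
local times are 1 (time counted in walker steps).

One-way reaction fluxes follow from MFPTs on augmented networks: redirect
the chosen external transition to a fresh absorbing node ``*`` and take the
reciprocal MFPT from the opposite gate to ``*``.  The degree of coupling is
eps = J2 / J1 of the net fluxes; the efficiency eta = -J2 A2 / (J1 A1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx

from . import hill as _hill
from .dynamics import mfpt_linear, stationary_solve, to_rates
from .montecarlo import MCConfig, mfpt_mc
from .netio import Edge, MfptQuery, StochasticNetwork, ValidationError


@dataclass
class GateSystem:
    """Conformational network plus the four reaction gates and driving terms.

    ``gate1_prime``/``gate1_dprime`` are the gates (1', 1'') of the donating
    reaction, ``gate2_prime``/``gate2_dprime`` those (2', 2'') of the
    accepting one.  ``tau1``/``tau2`` are the external transition times (in
    walker steps) and ``betaA1``/``betaA2`` the dimensionless forces.
    """

    graph: nx.Graph
    gate1_prime: int
    gate1_dprime: int
    gate2_prime: int
    gate2_dprime: int
    tau1: float
    tau2: float
    betaA1: float
    betaA2: float
    selected_gate: int | None = None  # override for the p + v = 1 gate

    def __post_init__(self):
        gates = self.gates()
        if len(set(gates)) != 4:
            raise ValidationError("the four gates must be distinct nodes")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValidationError("external transition times must be positive")
        for g in gates:
            if g not in self.graph:
                raise ValidationError(f"gate {g} is not a network node")

    def gates(self) -> tuple[int, int, int, int]:
        return (self.gate1_prime, self.gate1_dprime,
                self.gate2_prime, self.gate2_dprime)


@dataclass
class FluxResult:
    """One-way and net reaction fluxes with coupling diagnostics.

    ``mfpts`` maps flux labels ("+1", "-1", "+2", "-2") to the underlying
    one-way MFPTs; eta is None when undefined (zero output force).
    """

    J_plus_1: float
    J_minus_1: float
    J_plus_2: float
    J_minus_2: float
    epsilon: float
    eta: float | None
    mfpts: dict[str, float]

    @property
    def J1(self) -> float:
        return self.J_plus_1 - self.J_minus_1

    @property
    def J2(self) -> float:
        return self.J_plus_2 - self.J_minus_2


def equilibrium_occupation(graph: nx.Graph) -> dict[int, Fraction]:
    """Degree-proportional equilibrium occupation p_eq(l) = k_l / sum k."""
    ksum = sum(d for _, d in graph.degree())
    if ksum == 0:
        raise ValidationError("network has no edges")
    return {l: Fraction(d, ksum) for l, d in graph.degree()}


def unit_probability(tau_l: float, p_gate_eq) -> float:
    """Internal unit probability p = 1 / (1 + (tau_l * p_eq)^-1).

    Fixes the elementary machine time scale so that at the selected gate
    internal plus external probabilities sum exactly to one.
    """
    x = float(tau_l) * float(p_gate_eq)
    if x <= 0:
        raise ValidationError("tau and gate occupation must be positive")
    return 1.0 / (1.0 + 1.0 / x)


def gate_rates(p, tau_l, betaA_l, p_fwd_gate_eq, p_bwd_gate_eq):
    """External transition probabilities (v_plus, v_minus) of reaction l.

    ``p_fwd_gate_eq`` is the equilibrium occupation of the forward exit gate
    l'' and ``p_bwd_gate_eq`` that of the backward exit gate l'.
    """
    v_plus = float(p) / (float(tau_l) * float(p_fwd_gate_eq))
    v_minus = float(p) * math.exp(-float(betaA_l)) / (
        float(tau_l) * float(p_bwd_gate_eq)
    )
    return v_plus, v_minus


def _external_transitions(sys: GateSystem, peq, p=1.0):
    """The four external transitions as (source, target, probability-factor).

    With ``p = 1`` the probabilities double as the selection score for the
    p + v = 1 gate (the score ordering does not depend on p).
    """
    v1p, v1m = gate_rates(p, sys.tau1, sys.betaA1,
                          peq[sys.gate1_dprime], peq[sys.gate1_prime])
    v2p, v2m = gate_rates(p, sys.tau2, sys.betaA2,
                          peq[sys.gate2_dprime], peq[sys.gate2_prime])
    return [
        ("+1", sys.gate1_dprime, sys.gate1_prime, v1p),
        ("-1", sys.gate1_prime, sys.gate1_dprime, v1m),
        ("+2", sys.gate2_dprime, sys.gate2_prime, v2p),
        ("-2", sys.gate2_prime, sys.gate2_dprime, v2m),
    ]


def select_gate(sys: GateSystem) -> tuple[int, float]:
    """Pick the p + v = 1 gate and the resulting unit probability p.

    The gate is the exit node of the external transition with the highest
    probability; among ties the node with the smallest equilibrium
    occupation wins.  An explicit ``selected_gate`` on the system overrides.
    """
    peq = equilibrium_occupation(sys.graph)
    if sys.selected_gate is not None:
        gate = sys.selected_gate
    else:
        scored = _external_transitions(sys, peq, p=1.0)
        best = max(scored, key=lambda rec: (rec[3], -peq[rec[1]]))
        gate = best[1]
    tau = sys.tau1 if gate in (sys.gate1_prime, sys.gate1_dprime) else sys.tau2
    return gate, unit_probability(tau, peq[gate])


def build_machine_network(sys: GateSystem) -> StochasticNetwork:
    """Assemble the full stochastic network of the gated machine.

    Internal edges carry probability p/k_l, the four gate nodes get their
    external transitions, and each node's deficit from 1 becomes a waiting
    self-loop; all local times are 1.  At the selected gate the waiting
    probability is exactly zero by construction.
    """
    nodes = sorted(sys.graph.nodes)
    if nodes != list(range(len(nodes))):
        raise ValidationError("machine network nodes must be labelled 0..N-1")
    peq = equilibrium_occupation(sys.graph)
    gate, p = select_gate(sys)
    ext = _external_transitions(sys, peq, p=p)
    edges: list[list[Edge]] = []
    for l in nodes:
        k = sys.graph.degree(l)
        out = [Edge(nb, p / k, 1) for nb in sorted(sys.graph.neighbors(l))]
        for _, src, dst, v in ext:
            if src == l:
                out.append(Edge(dst, v, 1))
        total = math.fsum(float(e.u) for e in out)
        if total > 1 + 1e-12:
            raise ValidationError(
                f"node {l}: probabilities sum to {total} > 1 "
                "(external transition times too small for this gate choice)"
            )
        wait = 1.0 - total
        if l == gate or abs(wait) < 1e-12:
            # enforce exact closure at the selected gate
            deficit = 1.0 - math.fsum(float(e.u) for e in out[:-1])
            out[-1] = Edge(out[-1].target, deficit, out[-1].tau)
        else:
            out.append(Edge(l, wait, 1))
        edges.append(out)
    return StochasticNetwork(n_nodes=len(nodes), edges=edges)


def _augment_with_star(net: StochasticNetwork, from_gate: int, to_gate: int):
    """Redirect the edge from_gate -> to_gate to a fresh absorbing node ``*``.

    Returns the augmented network and the id of ``*`` (= old N).  The
    redirected transition keeps its probability and local time.
    """
    star = net.n_nodes
    edges = [list(out) for out in net.edges]
    hit = False
    for i, e in enumerate(edges[from_gate]):
        if e.target == to_gate:
            edges[from_gate][i] = Edge(star, e.u, e.tau)
            hit = True
            break
    if not hit:
        raise ValidationError(f"no edge {from_gate} -> {to_gate} to redirect")
    edges.append([])  # * is absorbing
    return StochasticNetwork(n_nodes=star + 1, edges=edges), star


def _mfpt(net, query, method, mc_config):
    if method == "hill":
        return _hill.mfpt_hill(net, query)
    if method == "linear":
        return mfpt_linear(net, query)
    if method == "montecarlo":
        if mc_config is None:
            raise ValueError("montecarlo method needs an MCConfig")
        return mfpt_mc(net, query, mc_config).value
    raise ValueError(f"unknown method {method!r}")


def one_way_flux(
    net: StochasticNetwork,
    from_gate: int,
    to_gate: int,
    method: str = "hill",
    mc_config: MCConfig | None = None,
) -> float:
    """One-way stationary flux through the directed link from_gate -> to_gate.

    Builds the augmented network with the absorbing node ``*`` replacing
    that transition's target and returns the reciprocal MFPT from the
    opposite gate (``to_gate``) to ``*``.
    """
    aug, star = _augment_with_star(net, from_gate, to_gate)
    tau = _mfpt(aug, MfptQuery(to_gate, {star}), method, mc_config)
    return 1.0 / float(tau)


def decompose_mfpt(
    net: StochasticNetwork,
    from_gate: int,
    to_gate: int,
    method: str = "hill",
    mc_config: MCConfig | None = None,
) -> tuple[float, float, float]:
    """Split the one-way MFPT into an internal and a gate-kinetics term.

    On the network where the from_gate -> ``*`` link is folded back into a
    waiting self-loop on from_gate, the total MFPT to ``*`` decomposes as

        tau(to_gate -> *) = tau(to_gate -> from_gate) + 1 / (v * p_st(from_gate))

    with ``v`` the redirected transition's probability and ``p_st`` the
    stationary occupation of from_gate on that same folded network.
    Returns (internal_mfpt, gate_term, total).
    """
    v = None
    edges = [list(out) for out in net.edges]
    for i, e in enumerate(edges[from_gate]):
        if e.target == to_gate:
            v = float(e.u)
            edges[from_gate][i] = Edge(from_gate, e.u, e.tau)  # fold into waiting
            break
    if v is None:
        raise ValidationError(f"no edge {from_gate} -> {to_gate} to redirect")
    folded = StochasticNetwork(n_nodes=net.n_nodes, edges=edges)
    internal = float(_mfpt(folded, MfptQuery(to_gate, {from_gate}), method, mc_config))
    p_st = stationary_solve(to_rates(folded))
    gate_term = 1.0 / (v * float(p_st[from_gate]))
    return internal, gate_term, internal + gate_term


def coupling_and_efficiency(
    J_plus_1: float, J_minus_1: float, J_plus_2: float, J_minus_2: float,
    betaA1: float, betaA2: float,
) -> tuple[float, float | None]:
    """Degree of coupling eps = J2/J1 and efficiency eta = -J2 A2 / (J1 A1).

    eta is None (undefined, not zero) when the output force betaA2 is 0.
    """
    J1 = J_plus_1 - J_minus_1
    J2 = J_plus_2 - J_minus_2
    if J1 == 0:
        raise ValidationError("net input flux J1 is zero; coupling undefined")
    eps = J2 / J1
    eta = None
    if betaA2 != 0 and betaA1 != 0:
        eta = -(J2 * betaA2) / (J1 * betaA1)
    return eps, eta


def machine_fluxes(
    sys: GateSystem,
    method: str = "hill",
    mc_config: MCConfig | None = None,
) -> FluxResult:
    """Full pipeline: build the machine network and compute all four fluxes.

    The four one-way fluxes come from the four augmented-network MFPTs
    (forward fluxes redirect l'' -> l', backward ones l' -> l'').
    """
    net = build_machine_network(sys)
    pairs = {
        "+1": (sys.gate1_dprime, sys.gate1_prime),
        "-1": (sys.gate1_prime, sys.gate1_dprime),
        "+2": (sys.gate2_dprime, sys.gate2_prime),
        "-2": (sys.gate2_prime, sys.gate2_dprime),
    }
    mfpts = {}
    flux = {}
    for label, (src, dst) in pairs.items():
        aug, star = _augment_with_star(net, src, dst)
        tau = float(_mfpt(aug, MfptQuery(dst, {star}), method, mc_config))
        mfpts[label] = tau
        flux[label] = 1.0 / tau
    if flux["+1"] == flux["-1"]:  # detailed balance: no net input flux
        eps, eta = math.nan, None
    else:
        eps, eta = coupling_and_efficiency(
            flux["+1"], flux["-1"], flux["+2"], flux["-2"], sys.betaA1, sys.betaA2
        )
    return FluxResult(
        J_plus_1=flux["+1"], J_minus_1=flux["-1"],
        J_plus_2=flux["+2"], J_minus_2=flux["-2"],
        epsilon=eps, eta=eta, mfpts=mfpts,
    )
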