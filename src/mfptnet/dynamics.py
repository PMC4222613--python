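"""Rate-picture conversion and exact linear-algebra references.

A discrete-time network with per-edge probabilities ``u`` and local times
``tau`` maps onto a continuous-time Markov jump process with transition
probabilities per unit time

    w[l' <- l] = u[l' <- l] / s_l,      s_l = sum_e tau_e * u_e over node l,

where the mean step time ``s_l`` runs over *all* outgoing edges including
self-loops (waiting counts toward residence time, but generates no rate
edge).  Both pictures share the same mean first-passage times; this module
provides the direct dense-linear-algebra solutions used as the reference
against which the combinatorial and Monte Carlo solvers are checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .netio import (
    NOT_ACCESSIBLE,
    MfptQuery,
    StochasticNetwork,
    ValidationError,
)

#: residual threshold for stationary solutions
STATIONARY_RESIDUAL = 1e-10


@dataclass
class RateNetwork:
    """Per-edge transition probabilities per unit time (no self-loop rates).

    ``edges`` is a list of ``(source, target, w)`` with ``w >= 0`` in units of
    1/time, aggregated over parallel edges.
    """

    n_nodes: int
    edges: list[tuple[int, int, object]]  # w is float or Fraction

    def rate_matrix(self) -> np.ndarray:
        """Dense matrix ``W[i, j]`` = total rate from node ``i`` to node ``j``."""
        W = np.zeros((self.n_nodes, self.n_nodes))
        for s, t, w in self.edges:
            W[s, t] += float(w)
        return W

    def successors(self, l: int) -> set[int]:
        return {t for s, t, w in self.edges if s == l and float(w) > 0}


def mean_step_time(net: StochasticNetwork, node: int) -> float:
    """Mean time per step of node ``node``: sum of tau*u over all its edges."""
    out = net.edges[node]
    if out and all(
        isinstance(e.u, (int, Fraction)) and isinstance(e.tau, (int, Fraction))
        for e in out
    ):
        return sum(Fraction(e.tau) * Fraction(e.u) for e in out)
    return math.fsum(float(e.tau) * float(e.u) for e in out)


def to_rates(net: StochasticNetwork, exact: bool = False) -> RateNetwork:
    """Convert a (u, tau) network to transition probabilities per unit time.

    Every node with outgoing edges must have a positive mean step time
    (at least one traversed edge with nonzero local time); a node with
    ``s_l = 0`` is incompatible with the rate picture and raises.
    Self-loops contribute to ``s_l`` but produce no rate edge.
    """
    edges: list[tuple[int, int, object]] = []
    for l in range(net.n_nodes):
        out = net.edges[l]
        if not out:
            continue  # absorbing node: no rates out
        s = mean_step_time(net, l)
        if float(s) <= 0:
            raise ValidationError(
                f"node {l}: mean step time is zero (all local times vanish); "
                "the rate picture is undefined — use Monte Carlo"
            )
        agg: dict[int, object] = {}
        for e in out:
            if e.target == l:
                continue
            if exact:
                w = Fraction(e.u) / Fraction(s)
            else:
                w = float(e.u) / float(s)
            agg[e.target] = agg.get(e.target, 0) + w
        edges.extend((l, t, w) for t, w in agg.items())
    return RateNetwork(n_nodes=net.n_nodes, edges=edges)


def _closed_classes(rates: RateNetwork) -> list[set[int]]:
    """Strongly connected components with no edge leaving them."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(rates.n_nodes))
    g.add_edges_from((s, t) for s, t, w in rates.edges if float(w) > 0)
    cond = nx.condensation(g)
    return [
        set(cond.nodes[c]["members"])
        for c in cond.nodes
        if cond.out_degree(c) == 0
    ]


def stationary_solve(rates: RateNetwork) -> np.ndarray:
    """Stationary occupation probabilities of the master equation.

    Solves ``sum_l' (w[l <- l'] p_l' - w[l' <- l] p_l) = 0`` with
    ``sum p = 1`` by a dense direct method.  Requires a unique closed
    communicating class; raises otherwise.  Nodes outside the closed class
    (transient) receive probability 0.
    """
    closed = _closed_classes(rates)
    if len(closed) != 1:
        raise ValidationError(
            f"stationary distribution not unique: {len(closed)} closed classes"
        )
    n = rates.n_nodes
    W = rates.rate_matrix()
    # generator: d p / dt = A p with A[l, l'] = w[l <- l'] - delta * total exit
    A = W.T.copy()
    np.fill_diagonal(A, A.diagonal() - W.sum(axis=1))
    # replace one balance row by normalization
    A[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    p = np.linalg.solve(A, b)
    p = np.where(np.abs(p) < 1e-15, 0.0, p)
    resid = W.T @ p - W.sum(axis=1) * p
    scale = max(1.0, float(np.abs(W).max()))
    if np.max(np.abs(resid)) > STATIONARY_RESIDUAL * scale:
        raise ValidationError("stationary solve failed the residual check")
    return p


def reachable_set(net: StochasticNetwork, targets: set[int]) -> set[int]:
    """Nodes from which some target can be reached along positive-probability edges."""
    preds: dict[int, set[int]] = {l: set() for l in range(net.n_nodes)}
    for l in range(net.n_nodes):
        for t in net.successors(l):
            preds[t].add(l)
    seen = set(targets)
    stack = list(targets)
    while stack:
        v = stack.pop()
        for u in preds[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _forward_set(net: StochasticNetwork, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for t in net.successors(v):
            if t not in seen:
                seen.add(t)
                stack.append(t)
    return seen


def mfpt_linear(net: StochasticNetwork, query: MfptQuery):
    """First-step-analysis MFPT: the exact reference solver.

    Solves ``t_l = s_l + sum_{l' not final} u[l' <- l] t_l'`` with ``t = 0``
    on the final set, by dense linear algebra.  Returns the time for the
    query's initial node, ``math.inf`` when the finals are reachable but the
    walk can also be trapped away from them (diverging expectation), or
    :data:`NOT_ACCESSIBLE` when no path exists.
    """
    finals = set(query.finals)
    if query.initial in finals:
        return 0.0
    can_reach = reachable_set(net, finals)
    if query.initial not in can_reach:
        return NOT_ACCESSIBLE
    fwd = _forward_set(net, query.initial)
    if not fwd <= can_reach:
        return math.inf  # positive probability of never arriving
    unknown = sorted((fwd - finals))
    idx = {l: i for i, l in enumerate(unknown)}
    m = len(unknown)
    A = np.eye(m)
    b = np.empty(m)
    for l in unknown:
        i = idx[l]
        b[i] = float(mean_step_time(net, l))
        for e in net.edges[l]:
            if e.target not in finals and float(e.u) > 0:
                A[i, idx[e.target]] -= float(e.u)
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValidationError("singular first-step system") from exc
    return float(t[idx[query.initial]])
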