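"""Combinatorial maximal-tree (Hill) solver for stationary states and MFPTs.

The mean first-passage time from an initial node to a final set equals the
reciprocal one-way stationary flux into the finals on the *modified* network
in which every transition entering the final set is redirected back to the
initial node and the final nodes are eliminated.  The stationary occupation
probabilities of the modified network are obtained combinatorially: each
maximal (spanning) tree of its undirected support, directed toward a root
``l``, contributes the product of its edge rates as a weight ``W_l``; then

    p_l_st = W_l / sum_n W_n,       J = sum w(into finals) * p_st(source),
    MFPT = 1 / J.

Tree subsets are generated in lexicographic order of edge indices.  The
method is exact but combinatorial: beyond a configurable candidate-subset
budget it refuses and advises the Monte Carlo solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterator

from .dynamics import RateNetwork, _forward_set, reachable_set, to_rates
from .netio import NOT_ACCESSIBLE, MfptQuery, StochasticNetwork, ValidationError

#: default cap on C(E, N'-1) candidate edge subsets
DEFAULT_TREE_BUDGET = 10**7


class CombinatorialBlowupError(RuntimeError):
    """Tree enumeration would exceed the candidate budget (use Monte Carlo)."""


@dataclass
class ModifiedGraph:
    """Rate network after redirecting into-final edges to the initial node.

    ``nodes`` lists the surviving original node ids; ``rate`` maps ordered
    original-id pairs to aggregated rates (parallel edges summed, no
    self-loops); ``redirected`` records each original into-final edge
    ``(source, final, rate)`` for the flux bookkeeping.
    """

    nodes: list[int]
    rate: dict[tuple[int, int], object]
    redirected: list[tuple[int, int, object]]
    initial: int

    def support_edges(self) -> list[tuple[int, int]]:
        """Undirected support, one edge per unordered pair, lexicographic."""
        pairs = {(min(a, b), max(a, b)) for (a, b) in self.rate}
        return sorted(pairs)

    def restricted_to_reachable(self) -> "ModifiedGraph":
        """Subgraph on nodes reachable from the initial node."""
        succ: dict[int, set[int]] = {n: set() for n in self.nodes}
        for (a, b), w in self.rate.items():
            if float(w) > 0:
                succ[a].add(b)
        seen = {self.initial}
        stack = [self.initial]
        while stack:
            v = stack.pop()
            for t in succ[v]:
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        if seen == set(self.nodes):
            return self
        return ModifiedGraph(
            nodes=sorted(seen),
            rate={k: w for k, w in self.rate.items() if k[0] in seen and k[1] in seen},
            redirected=[r for r in self.redirected if r[0] in seen],
            initial=self.initial,
        )


def build_modified_graph(
    rates: RateNetwork, initial: int, finals: set[int]
) -> ModifiedGraph:
    """Redirect every edge entering ``finals`` to ``initial``; drop the finals.

    The initial node must not be final, and at most N-2 finals are allowed
    (the modified graph needs at least two nodes).  Edges between two final
    nodes disappear (walkers are absorbed at first contact); a redirected
    edge whose source is the initial node itself stays out of the graph (it
    would be a self-loop) but is kept in the flux bookkeeping.
    """
    finals = set(finals)
    if initial in finals:
        raise ValidationError(
            "Hill method: the final state must differ from the initial state"
        )
    if len(finals) > rates.n_nodes - 2:
        raise ValidationError(
            f"Hill method: number of final states ({len(finals)}) cannot exceed "
            f"N-2 = {rates.n_nodes - 2}"
        )
    rate: dict[tuple[int, int], object] = {}
    redirected: list[tuple[int, int, object]] = []
    for s, t, w in rates.edges:
        if float(w) == 0:
            continue
        if s in finals:
            continue  # outgoing edges of finals are eliminated
        if t in finals:
            redirected.append((s, t, w))
            if s != initial:  # a redirected self-loop carries no rate
                key = (s, initial)
                rate[key] = rate.get(key, 0) + w
        else:
            key = (s, t)
            rate[key] = rate.get(key, 0) + w
    nodes = [n for n in range(rates.n_nodes) if n not in finals]
    return ModifiedGraph(nodes=nodes, rate=rate, redirected=redirected, initial=initial)


def enumerate_maximal_trees(
    graph: ModifiedGraph, budget: int = DEFAULT_TREE_BUDGET
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield the maximal (spanning) trees of the undirected support.

    Each tree is a tuple of support edges; subsets are scanned in
    lexicographic order of edge indices and filtered for spanning-tree
    structure.  Raises :class:`CombinatorialBlowupError` when the candidate
    count C(E, N'-1) exceeds ``budget``.
    """
    edges = graph.support_edges()
    m = len(graph.nodes)
    k = m - 1
    if k < 0:
        return
    if k == 0:
        yield ()
        return
    if len(edges) < k:
        return
    n_candidates = math.comb(len(edges), k)
    if n_candidates > budget:
        raise CombinatorialBlowupError(
            f"{n_candidates} candidate edge subsets exceed the enumeration budget "
            f"({budget}); for knotted networks the Monte Carlo method is the "
            "logical choice"
        )
    index = {n: i for i, n in enumerate(graph.nodes)}
    for subset in combinations(edges, k):
        parent = list(range(m))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(index[a]), find(index[b])
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            yield subset


def _tree_root_weights(graph: ModifiedGraph, tree, rate_of, one, accum) -> None:
    """Add this directed tree's weight toward every root into ``accum``.

    Rooted once, then re-rooted along tree edges: moving the root from ``u``
    to its neighbour ``v`` swaps the factor for edge {u, v} from
    rate(v -> u) to rate(u -> v).  Zero factors are counted separately so
    the running product never divides by zero.
    """
    adj: dict[int, list[int]] = {n: [] for n in graph.nodes}
    for a, b in tree:
        adj[a].append(b)
        adj[b].append(a)
    root = graph.nodes[0]
    parent = {root: None}
    order = [root]
    for v in order:
        for nb in adj[v]:
            if nb not in parent:
                parent[nb] = v
                order.append(nb)
    prod = one
    zeros = 0
    for v in order[1:]:
        w = rate_of(v, parent[v])
        if w == 0:
            zeros += 1
        else:
            prod = prod * w
    state = {root: (prod, zeros)}
    for v in order[1:]:
        u = parent[v]
        prod_u, z_u = state[u]
        w_down = rate_of(v, u)  # factor present when u side is root
        w_up = rate_of(u, v)  # factor once v becomes the root
        if w_down == 0:
            z_u -= 1
        else:
            prod_u = prod_u / w_down
        if w_up == 0:
            z_u += 1
        else:
            prod_u = prod_u * w_up
        state[v] = (prod_u, z_u)
    for n, (p, z) in state.items():
        if z == 0:
            accum[n] = accum.get(n, one * 0) + p


def hill_stationary(
    graph: ModifiedGraph,
    exact: bool = False,
    budget: int = DEFAULT_TREE_BUDGET,
) -> dict[int, float]:
    """Stationary occupation probabilities by maximal-tree summation.

    Requires a connected support reachable from every node (restrict the
    graph first if needed).  In exact mode all rates must be rationals and
    the result is returned as :class:`fractions.Fraction` values summing to
    exactly 1; the default float mode rescales rates by their geometric mean
    before forming tree-weight products to avoid under/overflow.
    """
    if exact:
        rate = {k: Fraction(w) for k, w in graph.rate.items()}
        one: object = Fraction(1)
    else:
        pos = [float(w) for w in graph.rate.values() if float(w) > 0]
        scale = math.exp(math.fsum(math.log(x) for x in pos) / len(pos)) if pos else 1.0
        rate = {k: float(w) / scale for k, w in graph.rate.items()}
        one = 1.0

    def rate_of(src: int, dst: int):
        return rate.get((src, dst), one * 0)

    accum: dict[int, object] = {}
    n_trees = 0
    for tree in enumerate_maximal_trees(graph, budget=budget):
        n_trees += 1
        _tree_root_weights(graph, tree, rate_of, one, accum)
    total = sum(accum.values(), one * 0)
    if n_trees == 0 or total == 0:
        raise ValidationError(
            "no spanning structure with positive rates (graph disconnected?)"
        )
    zero = one * 0
    return {n: accum.get(n, zero) / total for n in graph.nodes}


def mfpt_hill(
    net: StochasticNetwork,
    query: MfptQuery,
    exact: bool = False,
    budget: int = DEFAULT_TREE_BUDGET,
):
    """MFPT by the combinatorial method: reciprocal one-way stationary flux.

    Returns a time, ``math.inf`` for reachable-but-trapping queries, or
    ``NOT_ACCESSIBLE`` when no path exists.  In exact mode all probabilities
    and times must be rationals and the answer is a Fraction.
    """
    finals = set(query.finals)
    rates = to_rates(net, exact=exact)
    mg = build_modified_graph(rates, query.initial, finals)
    can_reach = reachable_set(net, finals)
    if query.initial not in can_reach:
        return NOT_ACCESSIBLE
    if not _forward_set(net, query.initial) <= can_reach:
        return math.inf
    mg = mg.restricted_to_reachable()
    p = hill_stationary(mg, exact=exact, budget=budget)
    kept = set(mg.nodes)
    zero = Fraction(0) if exact else 0.0
    flux = sum((w * p[s] for s, _t, w in mg.redirected if s in kept), zero)
    if flux == 0:  # pragma: no cover - excluded by the reachability checks
        return NOT_ACCESSIBLE
    return 1 / flux if exact else 1.0 / float(flux)


def stationary_hill(
    net: StochasticNetwork, exact: bool = False, budget: int = DEFAULT_TREE_BUDGET
) -> dict[int, float]:
    """Maximal-tree stationary distribution of an *unmodified* network."""
    rates = to_rates(net, exact=exact)
    rate: dict[tuple[int, int], object] = {}
    for s, t, w in rates.edges:
        if float(w) > 0:
            rate[(s, t)] = rate.get((s, t), 0) + w
    mg = ModifiedGraph(
        nodes=list(range(net.n_nodes)), rate=rate, redirected=[], initial=0
    )
    return hill_stationary(mg, exact=exact, budget=budget)
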