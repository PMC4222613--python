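"""Benchmark and example network generators.

Builds the network families used to validate the solvers — hypercubes,
Sierpinski gaskets, Bethe lattices, cycles, random trees and a fractal
scale-free tree — plus structural emulations of the worked examples: a
small irregular nine-node network with one cycle, waiting probabilities and
asymmetric local times, and a ~200-node gated tree for the coupled-enzyme
machine.  Topologies are undirected graphs; :func:`network_from_graph`
turns them into stochastic networks with uniform or random-rational
probabilities and unit or random local times.  All randomness is driven by
explicit seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np

from .machine import GateSystem
from .netio import Edge, StochasticNetwork

#: local-time choices (rationals, so exact Hill mode stays available)
RANDOM_TIMES = (Fraction(1, 10), Fraction(1, 2), Fraction(1), Fraction(2), Fraction(5))


@dataclass
class FixtureSpec:
    """A reproducible network recipe: family, size parameters and modes."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    prob_mode: str = "uniform"       # "uniform" | "random-rational"
    time_mode: str = "unit"          # "unit" | "random"
    self_loops: bool = False


# ---------------------------------------------------------------------------
# topologies


def square_graph() -> nx.Graph:
    return nx.cycle_graph(4)


def cycle_graph(n: int) -> nx.Graph:
    if n < 3:
        raise ValueError("cycle needs n >= 3")
    return nx.cycle_graph(n)


def hypercube_graph(dim: int) -> nx.Graph:
    """d-dimensional hypercube: 2^d nodes, d * 2^(d-1) edges."""
    if dim < 1:
        raise ValueError("hypercube dimension must be >= 1")
    g = nx.hypercube_graph(dim)
    return nx.convert_node_labels_to_integers(g, ordering="sorted")


def sierpinski_graph(order: int) -> nx.Graph:
    """Sierpinski gasket of the given order (order 0 is a triangle)."""
    if order < 0:
        raise ValueError("gasket order must be >= 0")
    s = 2**order
    tris = [((0, 0), (s, 0), (0, s))]
    for _ in range(order):
        nxt = []
        for a, b, c in tris:
            mab = ((a[0] + b[0]) // 2, (a[1] + b[1]) // 2)
            mbc = ((b[0] + c[0]) // 2, (b[1] + c[1]) // 2)
            mca = ((c[0] + a[0]) // 2, (c[1] + a[1]) // 2)
            nxt += [(a, mab, mca), (mab, b, mbc), (mca, mbc, c)]
        tris = nxt
    g = nx.Graph()
    for a, b, c in tris:
        g.add_edges_from([(a, b), (b, c), (c, a)])
    return nx.convert_node_labels_to_integers(g, ordering="sorted")


def bethe_graph(coordination: int, shells: int) -> nx.Graph:
    """Bethe lattice: root of degree z, every interior node degree z."""
    if coordination < 2 or shells < 1:
        raise ValueError("need coordination >= 2 and shells >= 1")
    g = nx.Graph()
    g.add_node(0)
    frontier = [0]
    nxt_id = 1
    for shell in range(shells):
        new_frontier = []
        for node in frontier:
            n_children = coordination if shell == 0 else coordination - 1
            for _ in range(n_children):
                g.add_edge(node, nxt_id)
                new_frontier.append(nxt_id)
                nxt_id += 1
        frontier = new_frontier
    return g


def random_tree_graph(n: int, seed: int = 0) -> nx.Graph:
    if n < 2:
        raise ValueError("tree needs n >= 2")
    return nx.random_labeled_tree(n, seed=seed)


def fractal_scale_free_tree(n: int, seed: int = 0, repulsion: float = 2.0) -> nx.Graph:
    """Tree with heavy-tailed degrees and hub repulsion.

    Growth by preferential attachment, except that with odds ``repulsion``
    to 1 the new leaf is deflected from the degree-selected node to one of
    its neighbours, which keeps the emerging hubs from linking directly to
    each other (the deflected mass grows the hubs' periphery instead).
    """
    if n < 2:
        raise ValueError("tree needs n >= 2")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_edge(0, 1)
    for new in range(2, n):
        degs = np.array([g.degree(v) for v in range(new)], dtype=float)
        v = int(rng.choice(new, p=degs / degs.sum()))
        if rng.random() < repulsion / (1.0 + repulsion):
            nbrs = sorted(g.neighbors(v))
            v = int(nbrs[rng.integers(len(nbrs))])
        g.add_edge(v, new)
    return g


_FAMILIES = {
    "square": lambda p: square_graph(),
    "cycle": lambda p: cycle_graph(p["n"]),
    "hypercube": lambda p: hypercube_graph(p["dim"]),
    "sierpinski": lambda p: sierpinski_graph(p["order"]),
    "bethe": lambda p: bethe_graph(p["coordination"], p["shells"]),
    "random_tree": lambda p: random_tree_graph(p["n"], p.get("seed", 0)),
    "fractal_scale_free_tree": lambda p: fractal_scale_free_tree(
        p["n"], p.get("seed", 0), p.get("repulsion", 2.0)
    ),
}


# ---------------------------------------------------------------------------
# graph -> stochastic network


def _random_rational_split(rng: np.random.Generator, k: int) -> list[Fraction]:
    weights = [int(rng.integers(1, 10)) for _ in range(k)]
    total = sum(weights)
    return [Fraction(w, total) for w in weights]


def network_from_graph(
    g: nx.Graph,
    prob_mode: str = "uniform",
    time_mode: str = "unit",
    seed: int = 0,
    self_loops: bool = False,
) -> StochasticNetwork:
    """Stochastic network on an undirected topology.

    Every undirected edge yields one outgoing edge per endpoint (so
    probabilities and times may be direction-asymmetric).  ``uniform``
    probabilities are 1/k; ``random-rational`` draws exact rationals summing
    to 1.  ``self_loops=True`` adds a waiting transition to roughly a third
    of the nodes (random-rational mode only makes them meaningful).
    """
    nodes = sorted(g.nodes)
    if nodes != list(range(len(nodes))):
        g = nx.convert_node_labels_to_integers(g, ordering="sorted")
        nodes = sorted(g.nodes)
    rng = np.random.default_rng(seed)
    edges: list[list[Edge]] = []
    for l in nodes:
        targets = sorted(g.neighbors(l))
        if self_loops and rng.random() < 1 / 3:
            targets = targets + [l]
        k = len(targets)
        if k == 0:
            edges.append([])
            continue
        if prob_mode == "uniform":
            probs = [Fraction(1, k)] * k
        elif prob_mode == "random-rational":
            probs = _random_rational_split(rng, k)
        else:
            raise ValueError(f"unknown probability mode {prob_mode!r}")
        if time_mode == "unit":
            times = [Fraction(1)] * k
        elif time_mode == "random":
            times = [RANDOM_TIMES[rng.integers(len(RANDOM_TIMES))] for _ in range(k)]
        else:
            raise ValueError(f"unknown time mode {time_mode!r}")
        edges.append([Edge(t, u, tau) for t, u, tau in zip(targets, probs, times)])
    return StochasticNetwork(n_nodes=len(nodes), edges=edges)


def generate(spec: FixtureSpec) -> StochasticNetwork:
    """Build the network described by a :class:`FixtureSpec`."""
    if spec.family == "figure1_style":
        return figure1_style(spec.seed)
    if spec.family not in _FAMILIES:
        raise ValueError(f"unknown family {spec.family!r}")
    params = dict(spec.params)
    params.setdefault("seed", spec.seed)
    g = _FAMILIES[spec.family](params)
    return network_from_graph(
        g, prob_mode=spec.prob_mode, time_mode=spec.time_mode,
        seed=spec.seed, self_loops=spec.self_loops,
    )


def random_network(
    n: int, seed: int = 0, extra_edges: int | None = None, self_loops: bool = True
) -> StochasticNetwork:
    """Small random connected network with rational probabilities and times.

    A random tree plus ``extra_edges`` random chords (default: up to n//2,
    allowing cycles), random-rational exit probabilities, random local times
    and optional waiting self-loops — the stress-test family on which the
    combinatorial, Monte Carlo and linear solvers are compared.
    """
    rng = np.random.default_rng(seed)
    g = random_tree_graph(n, seed=seed)
    n_extra = extra_edges if extra_edges is not None else int(rng.integers(0, n // 2 + 1))
    for _ in range(n_extra):
        a, b = int(rng.integers(n)), int(rng.integers(n))
        if a != b:
            g.add_edge(a, b)
    return network_from_graph(
        g, prob_mode="random-rational", time_mode="random",
        seed=seed + 1, self_loops=self_loops,
    )


def figure1_style(seed: int = 0) -> StochasticNetwork:
    """Small irregular network: nine nodes, nine edges, one cycle.

    Structural emulation of the worked basic example — a tree plus one
    chord (a single independent cycle), at least one waiting self-loop, and
    asymmetric rational probabilities and local times.
    """
    rng = np.random.default_rng(seed)
    g = random_tree_graph(9, seed=seed)
    while True:  # one chord closing a cycle
        a, b = int(rng.integers(9)), int(rng.integers(9))
        if a != b and not g.has_edge(a, b):
            g.add_edge(a, b)
            break
    loop_node = int(rng.integers(9))
    edges: list[list[Edge]] = []
    for l in range(9):
        targets = sorted(g.neighbors(l))
        if l == loop_node:
            targets = targets + [l]
        probs = _random_rational_split(rng, len(targets))
        times = [RANDOM_TIMES[rng.integers(len(RANDOM_TIMES))] for _ in targets]
        edges.append([Edge(t, u, tau) for t, u, tau in zip(targets, probs, times)])
    return StochasticNetwork(n_nodes=9, edges=edges)


def gated_tree(
    n: int = 200,
    seed: int = 0,
    tau1: float = 40.0,
    tau2: float = 40.0,
    betaA1: float = 10.0,
    betaA2: float = 0.0,
    scale_free: bool = True,
) -> GateSystem:
    """Gated conformational tree emulating the coupled-enzyme example.

    A fractal scale-free tree (or plain random tree) whose four gates are
    leaves placed the way the tightly-coupled machine needs them: reaction
    1's gates are the two most distant leaves (ends of the backbone path),
    and reaction 2's gates are leaves hanging close to that backbone with
    well-separated attachment points — the forward-exit gate 2'' toward the
    1' end, the entry gate 2' toward the 1'' end — so the driven transport
    from 1' to 1'' passes through the reaction-2 link and the two net
    fluxes become comparable.  Defaults follow the worked example: N = 200,
    tau = 40, betaA1 = 10, betaA2 = 0.
    """
    g = (fractal_scale_free_tree(n, seed=seed) if scale_free
         else random_tree_graph(n, seed=seed))
    leaves = [v for v in g.nodes if g.degree(v) == 1]
    dist = dict(nx.all_pairs_shortest_path_length(g))
    _, g1p, g1pp = max(
        (dist[a][b], a, b) for i, a in enumerate(leaves) for b in leaves[i + 1:]
    )
    backbone = nx.shortest_path(g, g1p, g1pp)
    pos = {v: i for i, v in enumerate(backbone)}
    # each candidate leaf projects onto the backbone node it is closest to
    proj: dict[int, tuple[int, int]] = {}
    for x in leaves:
        if x in (g1p, g1pp):
            continue
        off, at = min((dist[x][v], pos[v]) for v in backbone)
        proj[x] = (at, off)
    best = max(
        ((proj[y][0] - proj[x][0]) - 2 * (proj[x][1] + proj[y][1]), x, y)
        for x in proj for y in proj
        if x != y and proj[y][0] > proj[x][0]
    )
    _, g2pp, g2p = best
    return GateSystem(
        graph=g,
        gate1_prime=g1p, gate1_dprime=g1pp,
        gate2_prime=g2p, gate2_dprime=g2pp,
        tau1=tau1, tau2=tau2, betaA1=betaA1, betaA2=betaA2,
    )
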