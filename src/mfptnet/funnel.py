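"""Docking binding-funnel networks and favourable-path extraction.

A binding funnel is a network of docked conformational states, each carrying
an energy score and similarity measures to the native complex: fraction of
native contacts (fnat), interface RMSD (IRMSD) and ligand RMSD (LRMSD),
classified by the CAPRI criteria into high / medium / acceptable /
incorrect.  Transition probabilities between adjacent states follow the
energy landscape: moving downhill has raw weight 1, moving uphill by
``dE`` has weight ``exp(-dE)``; transitions into states with LRMSD above a
cutoff (default 6 A) are forbidden, rows are normalized, and edges below a
pruning threshold (default 1e-6) are removed.  Favourable paths between
states are shortest paths on a graph whose edge weights are pairwise MFPTs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .netio import NOT_ACCESSIBLE, Edge, StochasticNetwork, ValidationError

CAPRI_CLASSES = ("incorrect", "acceptable", "medium", "high")

#: missing-value tokens accepted in MFPT matrix files
_MISSING = {"-", "NA", "nan", "inf", "Inf"}


def capri_classify(fnat: float, lrmsd: float, irmsd: float) -> str:
    """CAPRI quality class of a docked pose, evaluated high -> incorrect.

    high:        fnat >= 0.5 and (LRMSD <= 1 or IRMSD <= 1)
    medium:      (fnat >= 0.5 and LRMSD > 1 and IRMSD > 1) or
                 (0.3 <= fnat < 0.5 and (LRMSD <= 5 or IRMSD <= 2))
    acceptable:  (fnat >= 0.3 and LRMSD > 5 and IRMSD > 2) or
                 (0.1 <= fnat < 0.3 and (LRMSD <= 10 or IRMSD <= 4))
    incorrect:   everything else (fnat < 0.1, or LRMSD > 10 and IRMSD > 4)
    """
    if fnat >= 0.5 and (lrmsd <= 1 or irmsd <= 1):
        return "high"
    if (fnat >= 0.5 and lrmsd > 1 and irmsd > 1) or (
        0.3 <= fnat < 0.5 and (lrmsd <= 5 or irmsd <= 2)
    ):
        return "medium"
    if (fnat >= 0.3 and lrmsd > 5 and irmsd > 2) or (
        0.1 <= fnat < 0.3 and (lrmsd <= 10 or irmsd <= 4)
    ):
        return "acceptable"
    return "incorrect"


@dataclass
class FunnelState:
    """One docked conformational state with its quality metadata."""

    id: int
    energy: float
    lrmsd: float
    irmsd: float
    fnat: float
    fnonnat: float

    def __post_init__(self):
        if not (0 <= self.fnat <= 1):
            raise ValidationError(f"state {self.id}: fnat {self.fnat} outside [0, 1]")
        if self.lrmsd < 0 or self.irmsd < 0:
            raise ValidationError(f"state {self.id}: negative RMSD")

    @property
    def capri_class(self) -> str:
        return capri_classify(self.fnat, self.lrmsd, self.irmsd)

    @property
    def label(self) -> str:
        """Short class-letter label, e.g. ``M21`` for a medium-quality state 21."""
        letter = {"high": "H", "medium": "M", "acceptable": "A", "incorrect": "I"}
        return f"{letter[self.capri_class]}{self.id}"


def load_states(path_or_buf) -> list[FunnelState]:
    """Read a tab/whitespace-separated state table.

    Columns: id, energy, lrmsd, irmsd, fnat, fnonnat (header optional).
    """
    df = pd.read_csv(path_or_buf, sep=r"\s+", comment="#", header=None,
                     names=["id", "energy", "lrmsd", "irmsd", "fnat", "fnonnat"])
    if isinstance(df.iloc[0]["id"], str):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    return [
        FunnelState(int(r.id), float(r.energy), float(r.lrmsd), float(r.irmsd),
                    float(r.fnat), float(r.fnonnat))
        for r in df.itertuples()
    ]


def assign_transition_probabilities(
    states: Sequence[FunnelState],
    adjacency: Iterable[tuple[int, int]],
    lrmsd_cutoff: float = 6.0,
    prune: float = 1e-6,
    block_outgoing: bool = False,
) -> StochasticNetwork:
    """Build the funnel's stochastic network from energies and adjacency.

    Per state ``l`` and neighbour ``m``: raw weight 1 when ``E_l > E_m``
    (downhill), else ``exp(-(E_m - E_l))``.  Transitions *into* states with
    LRMSD above the cutoff get weight 0 (``block_outgoing=True`` blocks
    transitions out of such states instead — the rule's direction in the
    original protocol is ambiguous).  Rows are normalized, edges below
    ``prune`` removed, and the row re-normalized; all local times are 1.
    A state left without outgoing edges becomes an absorbing dead end.
    """
    by_id = {s.id: s for s in states}
    n = max(by_id) + 1
    if set(by_id) != set(range(n)):
        raise ValidationError("state ids must be 0..N-1 without gaps")
    nbrs: dict[int, set[int]] = {l: set() for l in range(n)}
    for a, b in adjacency:
        nbrs[a].add(b)
        nbrs[b].add(a)
    edges: list[list[Edge]] = []
    for l in range(n):
        raw: list[tuple[int, float]] = []
        for m in sorted(nbrs[l]):
            if block_outgoing:
                blocked = by_id[l].lrmsd > lrmsd_cutoff
            else:
                blocked = by_id[m].lrmsd > lrmsd_cutoff
            if blocked:
                continue
            dE = by_id[m].energy - by_id[l].energy
            raw.append((m, 1.0 if dE < 0 else math.exp(-dE)))
        total = math.fsum(w for _, w in raw)
        if total > 0:
            kept = [(m, w / total) for m, w in raw if w / total >= prune]
            total2 = math.fsum(w for _, w in kept)
            raw = [(m, w / total2) for m, w in kept] if kept else []
        else:
            raw = []
        edges.append([Edge(m, u, 1) for m, u in raw])
    return StochasticNetwork(n_nodes=n, edges=edges)


def mfpt_weighted_graph(mfpt_matrix: Mapping | pd.DataFrame) -> nx.DiGraph:
    """Directed graph with edge (i, j) weighted by a finite MFPT(i -> j).

    ``mfpt_matrix`` is a square DataFrame (index = source, columns = target)
    or a mapping ``{(i, j): time}``; missing / NaN / infinite entries give no
    edge.  Negative weights are rejected.
    """
    g = nx.DiGraph()
    if isinstance(mfpt_matrix, pd.DataFrame):
        items = (
            ((int(i), int(j)), mfpt_matrix.at[i, j])
            for i in mfpt_matrix.index
            for j in mfpt_matrix.columns
        )
    else:
        items = (((int(i), int(j)), v) for (i, j), v in mfpt_matrix.items())
    for (i, j), v in items:
        g.add_node(i)
        g.add_node(j)
        if v is None or v is NOT_ACCESSIBLE:
            continue
        v = float(v)
        if math.isnan(v) or math.isinf(v):
            continue
        if v < 0:
            raise ValidationError(f"negative MFPT weight on edge {i} -> {j}")
        if i != j:
            g.add_edge(i, j, weight=v)
    return g


def load_mfpt_matrix(path_or_buf) -> nx.DiGraph:
    """Read a whitespace-delimited square MFPT table with missing tokens."""
    rows = []
    text = (
        path_or_buf.read() if hasattr(path_or_buf, "read")
        else open(path_or_buf).read()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([
            math.nan if tok in _MISSING else float(tok) for tok in line.split()
        ])
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise ValidationError("MFPT matrix is not square")
    df = pd.DataFrame(rows, index=range(n), columns=range(n))
    return mfpt_weighted_graph(df)


def shortest_path(graph: nx.DiGraph, source: int, target: int):
    """Minimal-total-MFPT path by Dijkstra with lexicographic tie-break.

    Returns ``(path, total_weight)`` where the total is the exact sum of the
    path's edge weights, or ``(None, NOT_ACCESSIBLE)`` when the target is
    unreachable.  Among equal-cost paths the lexicographically smallest node
    sequence is returned.
    """
    for _u, _v, w in graph.edges(data="weight"):
        if w < 0:
            raise ValidationError("Dijkstra requires positive weights")
    if source not in graph or target not in graph:
        return None, NOT_ACCESSIBLE
    # distances from every node to the target, on the reversed graph
    try:
        dist_to_target = nx.single_source_dijkstra_path_length(
            graph.reverse(copy=False), target
        )
    except nx.NodeNotFound:  # pragma: no cover
        return None, NOT_ACCESSIBLE
    if source not in dist_to_target:
        return None, NOT_ACCESSIBLE
    # walk forward, always taking the smallest neighbour on a shortest path
    path = [source]
    node = source
    total = 0.0
    while node != target:
        best = None
        for nb in sorted(graph.successors(node)):
            if nb not in dist_to_target:
                continue
            w = graph[node][nb]["weight"]
            if math.isclose(w + dist_to_target[nb], dist_to_target[node],
                            rel_tol=1e-12, abs_tol=1e-12):
                best = (nb, w)
                break
        if best is None:  # pragma: no cover - defensive
            raise ValidationError("shortest-path reconstruction failed")
        node, w = best
        total += w
        path.append(node)
    return path, total
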