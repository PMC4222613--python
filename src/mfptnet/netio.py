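"""Plain-text network formats and the core network data model.

Networks of discrete states are described by per-node adjacency lines.  Two
dialects exist:

*basic*
    ``NODE <id> <neighbour> <neighbour> ...`` — each listed neighbour
    occurrence carries transition probability ``1/k`` (``k`` = number of
    listed tokens) and local time 1.  Repeating the node's own id encodes a
    waiting (self-transition) probability.

*advanced*
    ``NODE <id> <neighbour> <prob> <time> ...`` — explicit per-edge
    transition probability and local time; probabilities may be decimals or
    common fractions (``1/3``) and must sum to 1 on every line.

Control keywords: ``WALK n`` (walkers per simulation), ``SIMU n`` (number of
simulations), ``MFPT i f [f ...]`` (a query from ``i`` to the final set),
``INFO free text`` (copied verbatim to output files).  Lines starting with
``#`` and blank lines are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence, Union

Number = Union[int, float, Fraction]

#: Per-node decimal probability-sum tolerance; exact rationals must sum to 1
#: exactly.
PROB_SUM_TOL = 1e-9


class _NotAccessible:
    """Sentinel for queries whose final set cannot be reached."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "NOT_ACCESSIBLE"


NOT_ACCESSIBLE = _NotAccessible()

#: Literal output string for unreachable queries.
NOT_ACCESSIBLE_TEXT = "Infinity (not accessible)"


class FormatError(ValueError):
    """Malformed input text (bad token, bad node ordering, unknown keyword)."""


class ValidationError(ValueError):
    """Structurally parsable input violating a network invariant."""


@dataclass(frozen=True)
class Edge:
    """One outgoing transition: target node, probability ``u``, local time ``tau``."""

    target: int
    u: Number
    tau: Number

    def is_self_loop(self, source: int) -> bool:
        return self.target == source


@dataclass
class StochasticNetwork:
    """A discrete-time stochastic network.

    ``edges[l]`` lists the outgoing transitions of node ``l`` in file order.
    Self-loops (waiting probabilities), parallel edges, directed/asymmetric
    edges and disconnected components are all allowed.  Per node the
    probabilities must sum to one (exactly for rationals, within
    :data:`PROB_SUM_TOL` for decimals) and all local times must be >= 0.
    """

    n_nodes: int
    edges: list[list[Edge]]

    def __post_init__(self):
        if self.n_nodes <= 0:
            raise ValidationError("network must have at least one node")
        if len(self.edges) != self.n_nodes:
            raise ValidationError(
                f"edge list has {len(self.edges)} entries for {self.n_nodes} nodes"
            )
        for l, out in enumerate(self.edges):
            self._validate_node(l, out)

    @staticmethod
    def _validate_node(l: int, out: Sequence[Edge]) -> None:
        if not out:
            return  # absorbing node (allowed; e.g. funnel dead ends, flux target *)
        for e in out:
            if not (0 <= float(e.u) <= 1):
                raise ValidationError(f"node {l}: probability {e.u} outside [0, 1]")
            if float(e.tau) < 0:
                raise ValidationError(f"node {l}: negative local time {e.tau}")
        if all(isinstance(e.u, (int, Fraction)) for e in out):
            total = sum(Fraction(e.u) for e in out)
            if total != 1:
                raise ValidationError(
                    f"node {l}: exact probabilities sum to {total}, not 1"
                )
        else:
            total = math.fsum(float(e.u) for e in out)
            if abs(total - 1.0) > PROB_SUM_TOL:
                raise ValidationError(
                    f"node {l}: probabilities sum to {total!r}, not 1"
                )

    def targets(self, l: int) -> list[int]:
        return [e.target for e in self.edges[l]]

    def successors(self, l: int) -> set[int]:
        return {e.target for e in self.edges[l] if float(e.u) > 0}


@dataclass
class MfptQuery:
    """An (initial node, final-node set) MFPT request."""

    initial: int
    finals: frozenset[int]

    def __init__(self, initial: int, finals: Iterable[int]):
        self.initial = int(initial)
        self.finals = frozenset(int(f) for f in finals)
        if not self.finals:
            raise ValidationError("query needs at least one final state")


@dataclass
class RunSpec:
    """Run-control keywords attached to a network file plus CLI choices."""

    walkers: int | None = None
    simulations: int | None = None
    queries: list[MfptQuery] = field(default_factory=list)
    info: str = ""
    method: str | None = None        # "hill" | "montecarlo"
    input_format: str | None = None  # "basic" | "advanced"
    mode: str | None = None          # "all" | "selected"

    def require_mc_keywords(self) -> None:
        if self.walkers is None or self.simulations is None:
            raise ValidationError(
                "Monte Carlo runs need WALK and SIMU keywords in the input file"
            )


@dataclass
class MfptResult:
    """Answer to one MFPT query.

    ``value`` is a non-negative time, ``math.inf`` (reachable but expected
    time diverges), or the :data:`NOT_ACCESSIBLE` sentinel.  ``std`` is the
    standard deviation of per-simulation means, present only for Monte Carlo
    runs with more than one simulation.
    """

    initial: int
    finals: frozenset[int]
    value: object
    std: float | None = None
    per_sim_means: list[float] | None = None

    @property
    def accessible(self) -> bool:
        return self.value is not NOT_ACCESSIBLE


# ---------------------------------------------------------------------------
# token parsing


def parse_fraction(token: str) -> Number:
    """Parse an integer, decimal, or common fraction ``a/b`` token.

    Integers and fractions become exact :class:`fractions.Fraction` values
    (integers as plain ``int``); decimals stay floats at full precision.
    """
    token = token.strip()
    if "/" in token:
        parts = token.split("/")
        if len(parts) != 2:
            raise FormatError(f"malformed fraction token {token!r}")
        try:
            num, den = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"malformed fraction token {token!r}") from exc
        if den == 0:
            raise FormatError(f"zero denominator in token {token!r}")
        return Fraction(num, den)
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"malformed numeric token {token!r}") from exc


def _format_number(x: Number) -> str:
    if isinstance(x, Fraction):
        if x.denominator == 1:
            return str(x.numerator)
        return f"{x.numerator}/{x.denominator}"
    if isinstance(x, int):
        return str(x)
    return repr(float(x))


# ---------------------------------------------------------------------------
# network files


def _parse_node_line_basic(node_id: int, tokens: list[str], lineno: int) -> list[Edge]:
    if not tokens:
        raise FormatError(f"line {lineno}: NODE {node_id} lists no neighbours")
    try:
        neighbours = [int(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer neighbour id") from exc
    k = len(neighbours)
    return [Edge(nb, Fraction(1, k), 1) for nb in neighbours]


def _parse_node_line_advanced(
    node_id: int, tokens: list[str], lineno: int
) -> list[Edge]:
    if not tokens or len(tokens) % 3 != 0:
        raise FormatError(
            f"line {lineno}: NODE {node_id} needs (neighbour, probability, time) triplets"
        )
    out: list[Edge] = []
    for i in range(0, len(tokens), 3):
        try:
            nb = int(tokens[i])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer neighbour id {tokens[i]!r}") from exc
        u = parse_fraction(tokens[i + 1])
        tau = parse_fraction(tokens[i + 2])
        out.append(Edge(nb, u, tau))
    return out


_KEYWORDS = {"NODE", "WALK", "SIMU", "MFPT", "INFO"}


def parse_network(text: str, format: str = "basic") -> tuple[StochasticNetwork, RunSpec]:
    """Parse a network file in the *basic* or *advanced* dialect.

    Returns the network together with the run keywords found in the file.
    Node ids must start at 0 and increase without gaps; any violation of the
    probability-sum invariants raises :class:`ValidationError` naming the node.
    """
    if format not in ("basic", "advanced"):
        raise ValueError(f"unknown format {format!r}")
    spec = RunSpec(input_format=format)
    node_edges: list[list[Edge]] = []
    info_parts: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        kw = tokens[0].upper()
        if kw not in _KEYWORDS:
            raise FormatError(f"line {lineno}: unknown keyword {tokens[0]!r}")
        if kw == "NODE":
            if len(tokens) < 2:
                raise FormatError(f"line {lineno}: NODE without a node id")
            try:
                node_id = int(tokens[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad node id {tokens[1]!r}") from exc
            expected = len(node_edges)
            if node_id != expected:
                raise FormatError(
                    f"line {lineno}: node id {node_id} out of order "
                    f"(expected {expected}; ids must increase from 0 without gaps)"
                )
            parser = (
                _parse_node_line_basic if format == "basic" else _parse_node_line_advanced
            )
            node_edges.append(parser(node_id, tokens[2:], lineno))
        elif kw == "WALK":
            spec.walkers = _parse_positive_int(tokens, lineno, "WALK")
        elif kw == "SIMU":
            spec.simulations = _parse_positive_int(tokens, lineno, "SIMU")
        elif kw == "MFPT":
            if len(tokens) < 3:
                raise FormatError(f"line {lineno}: MFPT needs an initial and >=1 final id")
            try:
                ids = [int(t) for t in tokens[1:]]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer id in MFPT line") from exc
            spec.queries.append(MfptQuery(ids[0], ids[1:]))
        elif kw == "INFO":
            info_parts.append(line[len(tokens[0]):].strip())
    if not node_edges:
        raise FormatError("input contains no NODE lines")
    spec.info = "\n".join(info_parts)
    n = len(node_edges)
    for l, out in enumerate(node_edges):
        for e in out:
            if not (0 <= e.target < n):
                raise ValidationError(
                    f"node {l}: neighbour id {e.target} outside 0..{n - 1}"
                )
    net = StochasticNetwork(n_nodes=n, edges=node_edges)
    for q in spec.queries:
        _check_query_ids(net, q)
    return net, spec


def _check_query_ids(net: StochasticNetwork, q: MfptQuery) -> None:
    for i in {q.initial, *q.finals}:
        if not (0 <= i < net.n_nodes):
            raise ValidationError(f"query references node {i} outside the network")


def _parse_positive_int(tokens: list[str], lineno: int, kw: str) -> int:
    if len(tokens) != 2:
        raise FormatError(f"line {lineno}: {kw} takes exactly one integer")
    try:
        val = int(tokens[1])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: bad {kw} value {tokens[1]!r}") from exc
    if val < 1:
        raise FormatError(f"line {lineno}: {kw} must be >= 1")
    return val


def write_network(
    net: StochasticNetwork, spec: RunSpec | None = None, format: str = "advanced"
) -> str:
    """Serialize a network (plus optional keywords) back to text.

    Round-trip safe: ``parse_network(write_network(net, spec, fmt), fmt)``
    reproduces the network exactly, with common fractions kept as ``a/b``
    tokens.  Writing *basic* requires every node's edges to be expressible as
    equal shares ``1/k`` with unit times.
    """
    lines: list[str] = []
    if spec is not None and spec.info:
        for part in spec.info.splitlines():
            lines.append(f"INFO {part}")
    for l in range(net.n_nodes):
        out = net.edges[l]
        if format == "advanced":
            body = " ".join(
                f"{e.target} {_format_number(e.u)} {_format_number(e.tau)}" for e in out
            )
        elif format == "basic":
            body = " ".join(str(t) for t in _basic_tokens(l, out))
        else:
            raise ValueError(f"unknown format {format!r}")
        lines.append(f"NODE {l} {body}".rstrip())
    if spec is not None:
        if spec.walkers is not None:
            lines.append(f"WALK {spec.walkers}")
        if spec.simulations is not None:
            lines.append(f"SIMU {spec.simulations}")
        for q in spec.queries:
            finals = " ".join(str(f) for f in sorted(q.finals))
            lines.append(f"MFPT {q.initial} {finals}")
    return "\n".join(lines) + "\n"


def _basic_tokens(l: int, out: Sequence[Edge]) -> list[int]:
    k = len(out)
    for e in out:
        if Fraction(e.u) != Fraction(1, k) or Fraction(e.tau) != 1:
            raise ValidationError(
                f"node {l}: edges not expressible in the basic format "
                "(need equal probabilities 1/k and unit times)"
            )
    return [e.target for e in out]


# ---------------------------------------------------------------------------
# results


def write_results(results: Sequence[MfptResult], info: str = "") -> str:
    """Render MFPT results as a small plain-text table.

    One record per query: initial node, final set, value (or the literal
    ``"Infinity (not accessible)"``), and the standard deviation when
    available.  INFO text is copied verbatim into the header.
    """
    lines = ["# MFPT results"]
    for part in info.splitlines():
        lines.append(f"# INFO: {part}")
    for r in results:
        finals = ",".join(str(f) for f in sorted(r.finals))
        if not r.accessible:
            body = NOT_ACCESSIBLE_TEXT
        elif r.std is not None:
            body = f"{float(r.value):.6g} +/- {r.std:.6g}"
        else:
            body = f"{float(r.value):.6g}"
        lines.append(f"MFPT {r.initial} -> {{{finals}}} : {body}")
    return "\n".join(lines) + "\n"
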