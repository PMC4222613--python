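"""Monte Carlo estimation of mean first-passage times.

An ensemble of independent walkers starts at the initial node with first
passage time 0.  Each step casts one uniform number on [0, 1); the outgoing
edge whose cumulative-probability interval contains the draw is taken (a
draw exactly on a boundary selects the latter interval), the edge's local
time is added (self-loops add their waiting time), and the walker moves.  A
walker stops on first arrival at any final node; when the initial node is
itself final the walker takes at least one step, so the estimate is a
return time.

Per simulation, first-passage times are averaged over walkers; across
simulations, the grand mean and the standard deviation of the
per-simulation means are reported.  Random numbers come from the Mersenne
Twister (mt19937) generator with a fixed, overridable seed.

The batch engine is vectorized over walkers but step-equivalent to the
scalar :func:`single_walk` loop (same per-step edge-selection rule).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .dynamics import reachable_set
from .netio import NOT_ACCESSIBLE, MfptQuery, MfptResult, StochasticNetwork

DEFAULT_SEED = 12345
_CHUNK = 1 << 21


class MaxStepsExceeded(RuntimeError):
    """A walker exceeded the step guard: astronomically slow or trapped."""


@dataclass
class MCConfig:
    """Walker-ensemble settings: WALK walkers per simulation, SIMU simulations."""

    walkers: int
    simulations: int = 1
    seed: int = DEFAULT_SEED
    max_steps: int = 10**9

    def __post_init__(self):
        if self.walkers < 1 or self.simulations < 1:
            raise ValueError("walkers and simulations must be >= 1")


def reachable(net: StochasticNetwork, initial: int, finals) -> bool:
    """True iff a directed positive-probability path of >= 1 step exists.

    For initial in finals this is the return-time reachability: some
    outgoing edge must lead to a node from which the final set is reachable.
    """
    finals = set(finals)
    back = reachable_set(net, finals)
    if initial in finals:
        return bool(net.successors(initial) & back)
    return initial in back


def single_walk(
    net: StochasticNetwork,
    initial: int,
    finals,
    rng: np.random.Generator,
    max_steps: int = 10**9,
) -> float:
    """One walker's first-passage time (scalar reference loop)."""
    finals = set(finals)
    cums = []
    for out in net.edges:
        c, acc = [], 0.0
        for e in out:
            acc += float(e.u)
            c.append(acc)
        cums.append(c)
    state = initial
    t = 0.0
    for _ in range(max_steps):
        out = net.edges[state]
        if not out:
            raise MaxStepsExceeded(f"walker absorbed in dead-end node {state}")
        r = rng.random()
        k = min(bisect_right(cums[state], r), len(out) - 1)
        t += float(out[k].tau)
        state = out[k].target
        if state in finals:
            return t
    raise MaxStepsExceeded(f"walker exceeded {max_steps} steps")


def _compile(net: StochasticNetwork):
    """Dense per-node cumulative-probability / target / time tables."""
    n = net.n_nodes
    maxdeg = max((len(out) for out in net.edges), default=1) or 1
    cum = np.full((n, maxdeg), 2.0)
    tgt = np.tile(np.arange(n, dtype=np.int64)[:, None], (1, maxdeg))
    tau = np.zeros((n, maxdeg))
    dead = np.zeros(n, dtype=bool)
    for l, out in enumerate(net.edges):
        if not out:
            dead[l] = True
            continue
        acc = 0.0
        for j, e in enumerate(out):
            acc += float(e.u)
            cum[l, j] = acc
            tgt[l, j] = e.target
            tau[l, j] = float(e.tau)
        cum[l, len(out) - 1] = np.inf  # clamp: last interval absorbs roundoff
    return cum, tgt, tau, dead


def _simulate_sum(compiled, initial, finals_mask, n_walkers, rng, max_steps):
    """Sum of first-passage times over ``n_walkers`` walkers."""
    cum, tgt, tau, dead = compiled
    total = 0.0
    remaining = n_walkers
    while remaining:
        chunk = min(remaining, _CHUNK)
        remaining -= chunk
        state = np.full(chunk, initial, dtype=np.int64)
        t = np.zeros(chunk)
        steps = 0
        while state.size:
            if steps >= max_steps:
                raise MaxStepsExceeded(
                    f"{state.size} walkers still active after {max_steps} steps"
                )
            if dead[state].any():
                raise MaxStepsExceeded(
                    "walkers absorbed in dead-end nodes outside the final set"
                )
            r = rng.random(state.size)
            k = (r[:, None] >= cum[state]).sum(axis=1)
            t += tau[state, k]
            state = tgt[state, k]
            steps += 1
            done = finals_mask[state]
            if done.any():
                total += float(t[done].sum())
                keep = ~done
                state = state[keep]
                t = t[keep]
    return total


def mfpt_mc(
    net: StochasticNetwork, query: MfptQuery, config: MCConfig
) -> MfptResult:
    """Monte Carlo MFPT with per-simulation error estimate.

    Unreachable queries return the NOT_ACCESSIBLE sentinel without
    simulating.  The standard deviation (sample std, ddof=1, of the
    per-simulation means) is attached when more than one simulation is run.
    """
    finals = set(query.finals)
    if not reachable(net, query.initial, finals):
        return MfptResult(query.initial, frozenset(finals), NOT_ACCESSIBLE)
    rng = np.random.Generator(np.random.MT19937(config.seed))
    compiled = _compile(net)
    finals_mask = np.zeros(net.n_nodes, dtype=bool)
    finals_mask[list(finals)] = True
    means = [
        _simulate_sum(compiled, query.initial, finals_mask, config.walkers, rng,
                      config.max_steps) / config.walkers
        for _ in range(config.simulations)
    ]
    value = float(np.mean(means))
    std = float(np.std(means, ddof=1)) if config.simulations > 1 else None
    return MfptResult(query.initial, frozenset(finals), value, std=std,
                      per_sim_means=means)
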