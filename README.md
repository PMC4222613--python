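# mfptnet

Mean first-passage times (MFPTs) on discrete stochastic networks, computed
two independent ways — exactly, by enumerating maximal (spanning) trees of
the network, and stochastically, by simulating ensembles of random walkers —
plus two applications built on top of MFPTs: stationary reaction fluxes of a
gated molecular machine, and favourable-path analysis of protein-docking
binding funnels.

## The scientific problem

Many systems in chemistry and biology are naturally described as a walker
hopping on a network of discrete states: conformational substates of a
protein, poses in a docking funnel, sites in a lattice. Each directed edge
`l → m` carries a transition probability `u(l→m)` (each node's outgoing
probabilities sum to 1; a self-loop models waiting) and a local time
`τ(l→m)`, the time cost of that hop. The **mean first-passage time** from an
initial node to a set of final nodes — the expected time until the walker
first arrives — is often the single most informative kinetic quantity: it
gives reaction rates, transport times and, through auxiliary constructions,
stationary fluxes.

Two solvers are provided:

- **Combinatorial (exact).** Transition probabilities and local times are
  converted to rates `w = u / s_l`, where `s_l` is the mean time per step at
  node `l`. The network is modified (edges into the final set are redirected
  to the initial node, final nodes removed), the stationary distribution of
  the modified network is computed as a sum over directed maximal trees, and
  the MFPT is the reciprocal of the stationary flux into the final set. The
  answer is exact up to floating-point rounding — or exactly rational with
  `exact=True`. Cost grows combinatorially: the solver refuses when
  `C(E, N−1)` exceeds 10⁷ subsets and suggests Monte Carlo.
- **Monte Carlo.** Ensembles of independent walkers are simulated with a
  seeded Mersenne Twister generator; per-simulation means give the estimate
  and its standard error. Vectorized over walkers; cost is independent of
  network cyclomatic complexity.

A third, internal reference — the first-step linear system, solved densely —
is used throughout the test suite as an oracle for both.

## Network file format

Two text formats. **Basic**: one line per node listing neighbour ids;
probabilities are uniform over the listed ids, all times are 1, and
repeating the node's own id creates waiting probability. **Advanced**: one
line per node with `target probability time` triplets; probabilities may be
exact fractions (`1/3`) or decimals. Keywords `WALK` (walkers per
simulation), `SIMU` (number of simulations), `MFPT initial final...`
(queries), and `INFO` (free text copied to the output) complete the file.

## Worked example

A 4-cycle `0–1–2–3` where the two hops through node 3 are slow (local time
2), written in the advanced format:

```
INFO square with a slow edge
NODE 0 1 1/2 1 3 1/2 2
NODE 1 0 1/2 1 2 1/2 1
NODE 2 1 1/2 1 3 1/2 1
NODE 3 0 1/2 2 2 1/2 1
WALK 100000
SIMU 4
MFPT 0 2
```

Exact solver (`METHOD 1`, advanced format `1`, selected queries `1`):

```
$ mfptnet demo.n demo.hill.out 1 1 1
$ cat demo.hill.out
# MFPT results
# INFO: square with a slow edge
MFPT 0 -> {2} : 5.5
```

Monte Carlo (`METHOD 0`), 4 simulations of 10⁵ walkers:

```
$ mfptnet demo.n demo.mc.out 0 1 1 --seed 12345
$ cat demo.mc.out
# MFPT results
# INFO: square with a slow edge
MFPT 0 -> {2} : 5.49593 +/- 0.0104589
```

The stochastic estimate agrees with the exact value 5.5 to within one
standard deviation of the simulation means. The same computation in Python:

```python
from mfptnet import MCConfig, MfptQuery, mfpt_hill, mfpt_mc, parse_network

net, spec = parse_network(open("demo.n").read(), "advanced")
q = MfptQuery(0, {2})
mfpt_hill(net, q)                                    # 5.5
mfpt_mc(net, q, MCConfig(walkers=100_000,
                         simulations=4, seed=12345)) # 5.49593 ± 0.01046
```

Unreachable targets report `Infinity (not accessible)`; reachable targets
whose expected time diverges (the walk can fall into a trap) report `inf`.

## Application: a gated molecular machine

`mfptnet machine` analyses an enzyme that couples a free-energy-donating
reaction (1) to an accepting one (2). The conformational network is a tree
whose four gate nodes carry the external (chemical) transitions; one-way
fluxes follow from MFPTs to an absorbing node spliced into each gate
transition, and the degree of coupling is `ε = J2/J1`. On the default
generated 200-node gated tree (gate time τ = 40, input force βA₁ = 10,
βA₂ = 0; unit probability p = 0.091 at the leaf gates):

```
$ mfptnet machine machine.cfg machine.out
machine analysis done (method=hill); epsilon=0.7407
$ cat machine.out
# one-way MFPTs, fluxes and coupling
mfpt +1 12253
mfpt -1 4.80749e+06
mfpt +2 423.405
mfpt -2 434.498
...
epsilon 0.740695
eta undefined
```

The machine is driven (the backward MFPT of reaction 1 is ~400× the
forward one) and tightly coupled (ε = 0.74); with zero output force the
efficiency η is undefined, not zero.

## Application: binding-funnel paths

`mfptnet funnel` classifies docked poses by the CAPRI criteria (high /
medium / acceptable / incorrect from fnat, LRMSD, IRMSD), builds a
transition network from the energy landscape (downhill hops weight 1,
uphill `exp(−ΔE)`, transitions into poses with LRMSD > 6 Å blocked, rows
normalized, edges below 10⁻⁶ pruned) and extracts favourable paths —
Dijkstra shortest paths on a graph whose edge weights are pairwise MFPTs.

## Benchmark generators

`mfptnet generate` writes fixture networks: hypercubes, Sierpinski gaskets,
Bethe lattices, cycles, random trees and fractal scale-free trees, with
uniform or random-rational probabilities and unit or random local times.

## Reproduction

All quantitative claims above are enforced by the test suite:

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end checks: three-way solver
agreement on 200 random networks, the < 0.2% exact-vs-Monte-Carlo bound on
benchmark families at 10⁷ walkers, the cycle closed form `MFPT = d(N−d)`,
the machine gate arithmetic (leaf occupation 1/398, p = 0.091), and the
application pipelines. The headline gate arithmetic can be recomputed
standalone:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
# {"t4": {"value": 0.091, "n": 200}}
```

See `docs/methods.md` for the model definitions, numerical choices and
known limitations.
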