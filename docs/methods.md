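# Methods

This note defines the model implemented by `mfptnet`, the conventions the
code follows, and the numerical choices that matter for reproducing its
results.

## Model

A stochastic network has `N` nodes. Each node `l` carries outgoing edges
`(l → m)` with transition probabilities `u(l→m) ≥ 0` summing to one over
`m` (a self-loop `u(l→l)` is a waiting probability) and local times
`τ(l→m) ≥ 0`, which may differ per edge and per direction. A walker at `l`
picks an edge with probability `u`, pays the edge's local time, and moves.
The mean first-passage time (MFPT) from an initial node to a final set is
the expected accumulated time until first arrival at any final node. When
the initial node belongs to the final set the quantity is a return time:
the walker must take at least one step.

### From probabilities to rates

The combinatorial and linear solvers work with rates per unit time

    w(l→m) = u(l→m) / s_l,      s_l = Σ_m u(l→m) · τ(l→m),

where the mean step time `s_l` sums over **all** outgoing edges including
self-loops; self-loops then produce no rate edge of their own (waiting is
absorbed into the time scale of the exits). The continuous-time chain with
rates `w` has the same MFPTs as the discrete local-time walk; the test
suite verifies this equivalence numerically by comparing all three solvers.
`s_l = 0` with outgoing probability is rejected.

### Combinatorial (maximal-tree) solver

To compute the MFPT from `i` to final set `F`:

1. **Modify the network**: every rate edge `(l → f)` with `f ∈ F` is
   redirected to `i` (parallel contributions to the same ordered pair are
   summed); the final nodes and their outgoing edges are removed. The
   computation is restricted to the closed communicating set reachable
   from `i` in the modified network. `|F| > N − 2` is rejected (the
   modified network needs at least two nodes).
2. **Stationary distribution by maximal trees**: undirected spanning trees
   of the modified support are enumerated as edge subsets of size `N′ − 1`
   in lexicographic order, filtered by a union–find acyclicity/spanning
   check. For each tree, its directed version toward every root `l` has
   weight `W_l = Π w(edges oriented toward l)`; a rerooting dynamic program
   computes all roots' weights in one pass, tracking zero factors by count
   so no division by zero occurs. Then `p_st(l) ∝ Σ_trees W_l`.
3. **Flux and MFPT**: the stationary flux into `F` is
   `J = Σ_redirected w(l→f) · p_st(l)` and `MFPT = 1/J`.

Numerical hygiene: rates are rescaled by their geometric mean before the
tree products (a 200-factor product of O(0.03) rates would underflow), and
an `exact=True` mode runs the whole computation in `fractions.Fraction`.
The enumeration refuses to start when `C(E, N′−1) > 10⁷` and raises a
`CombinatorialBlowupError` recommending Monte Carlo.

### Monte Carlo solver

Each step draws one uniform number in `[0, 1)`; the edge whose
cumulative-probability interval contains the draw is taken, with a draw
exactly on a boundary selecting the latter interval. The engine is
vectorized over walkers (chunks of 2²¹) and uses the Mersenne Twister
generator with a fixed, overridable seed (default 12345), so runs are
bit-reproducible. Per simulation, first-passage times are averaged over
walkers; the reported value is the mean of the per-simulation means and the
reported error their sample standard deviation (ddof = 1, requires ≥ 2
simulations). A `max_steps` guard raises rather than looping forever;
walkers reaching a node with no outgoing edges outside the final set raise
as well.

### Accessibility semantics

Three distinct outcomes: a finite MFPT; `inf` for targets that are
reachable but whose expected time diverges (the walk can escape into a
region from which the final set is unreachable); and the
`NOT_ACCESSIBLE` sentinel (printed as `Infinity (not accessible)`) when no
directed path exists at all. Monte Carlo detects inaccessibility by graph
reachability before simulating.

## Applications

### Gated machine (coupled reactions)

An enzyme network is an undirected conformational graph with degrees `k_l`
and equilibrium occupations `p_eq(l) = k_l / Σk`. Reaction `l ∈ {1, 2}`
enters at gate `l′` and exits at gate `l″`. Internal hops have probability
`p / k_l` per neighbour; external transitions have

    v+_l = p / (τ_l · p_eq(l″)),
    v−_l = p · exp(−βA_l) / (τ_l · p_eq(l′)),

where `βA_l` is the dimensionless driving force. The unit probability `p`
is fixed by requiring probability closure `p + v = 1` at the gate whose
external transition is fastest: `p = 1 / (1 + (τ_l · p_eq)^{-1})`. All
other nodes' deficits become waiting self-loops; all local times are 1.

One-way fluxes come from MFPTs on augmented networks: redirect the chosen
external transition to a fresh absorbing node `*`; then
`J = 1 / MFPT(opposite gate → *)`. The decomposition

    τ(l′ → *) = τ(l′ → l″) + 1 / (v · p_st(l″))

(on the network with the redirected edge folded into a waiting self-loop)
separates internal search from gate kinetics; the test suite enforces it
to 10⁻⁶ relative. Degree of coupling `ε = J2/J1`; efficiency
`η = −J2·A2 / (J1·A1)`, undefined (`None`) when either force is zero. At
exact detailed balance (`J1 = 0`) ε is reported as NaN.

### Binding funnel

Docked poses carry energies and similarity metrics (fnat, LRMSD, IRMSD)
classified by the CAPRI clauses, evaluated high → medium → acceptable →
incorrect. Transition probabilities on the pose adjacency follow the
energy landscape: downhill raw weight 1, uphill `exp(−ΔE)`; transitions
*into* poses with LRMSD above the cutoff (default 6 Å) are forbidden (the
opposite direction is available as `block_outgoing=True`, since the rule's
direction is ambiguous in the source protocol); rows are normalized, edges
below 10⁻⁶ pruned, and re-normalized. Favourable paths are Dijkstra
shortest paths on a directed graph weighted by pairwise MFPTs, with a
lexicographic tie-break among equal-cost paths (implemented as
reverse-graph distances plus greedy smallest-successor reconstruction).

## Generators and emulation scope

The benchmark families (hypercubes, Sierpinski gaskets, Bethe lattices,
cycles, random trees, fractal scale-free trees) are generated exactly.
The two worked applications ship as **structural emulations**, not copies
of the original inputs, which are not redistributable here: a 9-node,
9-edge, one-cycle network with waiting and asymmetric rational weights,
and a 200-node gated tree whose reaction-2 gates hang close to the
backbone between the reaction-1 gates (2″ toward the 1′ end, 2′ toward the
1″ end), reproducing the tightly-coupled regime (ε ≈ 0.74 at the default
parameters) and the gate arithmetic (leaf occupation 1/398, p = 0.091 at
τ = 40). Pipeline behaviour — identities, method agreement, orderings —
is asserted; exact published figures that depend on the withheld inputs
are not.

## Statistical testing conventions

Monte Carlo checks compare the estimate to the exact solver in units of
the estimated standard error `std/√S` over `S` simulations. For a single
fixture this is a t-statistic with `S − 1` degrees of freedom, so a strict
3-SE gate applied across hundreds of independent fixtures would fail
spuriously on a few. Ensemble tests therefore require at least 97% of
fixtures within 3 SE **and** all within 6 SE; single-fixture checks use
3 SE with fixed seeds chosen a priori. Deterministic-passage fixtures
(zero variance) are required to match exactly.

## Limitations

- The tree enumeration is exponential; beyond `C(E, N−1) = 10⁷` subsets
  use Monte Carlo (the refusal is explicit, never silent).
- Return times (initial ∈ finals) are Monte Carlo only; the combinatorial
  construction requires initial ∉ finals.
- The linear oracle solves dense systems; it is a test/reference device,
  not the production path for large networks.
- Efficiency η is reported only when both driving forces are nonzero.
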