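# Methods

## Model and definitions

A metabolic network is an m × n stoichiometric matrix S with flux
bounds a ≤ v ≤ b (mmol·gDW⁻¹·h⁻¹ by convention; units are not
enforced) and a linear objective f.  Upper bounds must be positive and
a reaction is irreversible exactly when its lower bound is
nonnegative.  A *flux mode* is a nonzero p with S p = 0 and pⱼ ≥ 0
wherever aⱼ ≥ 0; it is *elementary* when no other mode's support is a
proper subset of its support.  A mode *conforms* to a distribution v
when pⱼ > 0 implies vⱼ > 0 and pⱼ < 0 implies vⱼ < 0 — conformance is
what makes a decomposition biologically readable (no mode runs a
reaction the distribution doesn't, or backwards), and it also delivers
irreversibility for free: if v is feasible then vⱼ ≥ 0 on irreversible
reactions, so a conforming p inherits the sign.

## The decomposition loop

Given a steady-state v, the loop is: select a pivot jₖ in the residual
support; solve the minimum-support MILP (README) for a conforming mode
through the pivot; weight it by wₖ = min_{j∈R(p)} vⱼ/pⱼ; subtract and
repeat.  Why this works:

- *Elementarity.*  The MILP minimizes the number of active indicator
  variables; any conforming mode with strictly smaller support inside
  R(p) would be feasible with lower cost, so the optimum's support is
  minimal among conforming modes — elementary within the conforming
  set, checked in the suite against exhaustive enumeration.
- *Termination.*  All ratios vⱼ/pⱼ on R(p) are positive by
  conformance; subtracting the minimum-ratio multiple zeroes the
  arg-min entry while keeping every other sign, so |R(v)| drops by at
  least 1 per iteration and the loop runs at most |R(v)| times.
- *Non-uniqueness.*  Any pivot in the support yields a valid
  decomposition.  The max-|vⱼ| default avoids extracting many modes of
  negligible weight (the pivot flux upper-bounds the mode's
  contribution); a min-index rule is provided and the suite checks both
  give fully valid results.

## Parameters and numerical choices

- `eps_zero` (default 1e-9): absolute support threshold on
  residuals scaled by max(1, ‖v‖∞).  After each subtraction, residual
  entries below `eps_zero·max(1, ‖v‖∞)` are snapped to exactly zero so
  floating-point dust cannot spawn spurious iterations or corrupt
  pivot choice.
- `big_m` (default 1e4): the indicator constraints scale each active
  flux into [1, M], so M caps the max/min flux ratio *within one
  mode*, not the absolute flux scale.  After each solve the mode is
  rescaled to min active flux 1; if its largest flux then sits within
  1e-6·M of M, M is doubled and the MILP re-solved (at most 5
  retries) — a too-small M would silently truncate wide-dynamic-range
  modes.  The rescaling matters: the MILP's optimum scale is free in
  [1, M] and the solver may return a vertex touching M even when the
  mode's dynamic range is tiny.
- Integrality: indicators are read as active when > 0.5; the HiGHS
  integrality tolerance (~1e-6) is far below that margin.
- Pivot ties break to the lowest reaction index, making runs
  reproducible across solvers.  When the MILP itself has several
  minimum-support optima, whichever the backend returns is accepted;
  all validity checks are solver-independent.
- Mode normalization for reporting defaults to max-abs-one;
  pivot-one (mode scaled so the pivot reaction carries 1, the
  convention for per-uptake plots) and raw are available.  Weights are
  rescaled so Σ wₖ p⁽ᵏ⁾ = v holds under any normalization.
- Steady-state tolerance 1e-8 relative and bound tolerance 1e-9 sit
  above double-precision LP solver defaults; reconstruction is asserted
  at 1e-6 relative.

Degenerate inputs: v = 0 returns an empty decomposition; a
non-steady-state v or negative flux on an irreversible reaction is
rejected before any MILP is built; an infeasible MILP mid-run raises an
error carrying the partial decomposition.

## Balancing measured fluxes

Measured flux tables rarely satisfy S v = 0 exactly.  `balance_fluxes`
orthogonally projects onto null(S) (plain least squares; linear,
idempotent, non-expansive), then clips to the bounds only when clipping
preserves the steady state.  No sign preservation is guaranteed — a
small measured flux on an irreversible reaction can project slightly
negative — so balancing is a convenience preprocessing step, not part
of the decomposition guarantee.

## Characterization and subset reduction

With modes as columns of P, substituting v = P w (w ≥ 0) into the FBA
problem gives a small LP over weights whose optimum can never exceed
the full FBA optimum; equality at relative tolerance 1e-6 defines
*sufficiency* of the mode set.  `minimal_supporting_subset` greedily
removes columns — in ascending order of the maximum weight each column
carries across the model family's optima, so rarely-used modes go
first — keeping a column out only if sufficiency survives for every
family variant; the result is verified minimal (removing any remaining
column breaks sufficiency somewhere) but is not unique, and minimality,
not identity, is the contract.  Sufficiency is operationalized as
objective equality rather than full flux-vector reproduction; positive
lower bounds (e.g. maintenance-energy floors) are kept verbatim, so an
infeasible restricted LP legitimately signals an insufficient set.
`sweep_characterization` re-solves the weight LP along a list of
(reaction, upper-bound) points, producing the table a stacked
mode-weight plot is drawn from.

## Oracles

`enumerate_efms_bruteforce` visits reaction subsets in increasing
cardinality and accepts T as an EFM support when null(S[:,T]) is
one-dimensional with no zero entry on T, some sign of the direction
satisfies irreversibility, and no accepted support is a strict subset
of T.  Supports with a ≥ 2-dimensional restricted null space are
rejected: a zero can then be forced at any position, so a strictly
smaller support mode exists.  All-reversible supports emit the mode in
both directions.  Cost is exponential by construction; a guard refuses
networks above `max_n` = 14 reactions.  The enumerator is itself
cross-checked in the suite against an independent method (splitting
reversible reactions and enumerating minimal positive rays of the split
network).

`qp_decompose` reproduces the classical two-stage baseline: minimize
‖w‖₂² subject to P w = v, w ≥ 0.  It is solved exactly, not
iteratively: feasibility is certified by an LP first, then the equality
constraints are eliminated through null(P) (the least-squares min-norm
particular solution is orthogonal to it) and the remaining
least-distance problem is solved by the Lawson–Hanson LDP-to-NNLS
transformation.  Solutions are verified to ‖Pw − v‖∞ ≤ 1e-8 and
w ≥ −1e-10.

## Synthetic data

The fixture library covers the method's distinct regimes with
hand-enumerated EFM counts: a linear chain (1 EFM), a two-branch
diamond with binding branch capacities (2), a fully reversible 3-cycle
whose two EFMs are the cycle's two directions, a reversible branch
whose unique mode carries negative flux, and a dual-demand network
whose two sinks carry positive lower bounds (a growth and a maintenance
demand, echoing the biomass/NGAM structure of genome-scale models) so
that no single EFM is feasible alone.  Random networks (≤ 14 reactions
so the oracle stays applicable) draw integer stoichiometries in
{−2..2} around one uptake and one excretion exchange, make internal
reactions reversible with probability 0.25, and are regenerated until
the steady-state cone carries flux through the excretion reaction.
Synthetic flux distributions are positive combinations of k enumerated
EFMs with weights Uniform(0.5, 2.0) — steady-state by construction,
ratios benign relative to the default big-M — restricted to pairwise
sign-compatible mode samples so the generating combination is itself a
valid decomposition.

What passing on this data does and does not show: the generators
exercise reversibility, binding bounds, negative conformance, and
multi-mode recovery, but the networks are tiny, integer-stoichiometric
and noise-free.  Genome-scale behavior (LP degeneracy at scale,
near-zero numerical flux dust in solver output, thermodynamically
implausible cycles) is only partially represented — the eps-snapping
and big-M retry logic address the numerical part, and the suite's
problem sizes (networks of 6–12 reactions, 50 random instances, 100
recovery seeds) were chosen to keep exhaustive oracle enumeration
cheap while covering every code path.

## Known limitations

- No canonical decomposition is selected among the non-unique
  possibilities; reproducibility is promised per solver and seed only.
- Alternate FBA optima are not enumerated or canonicalized; the
  solver's vertex is decomposed as returned.
- The brute-force oracle is exponential and hard-guarded at 14
  reactions; it exists for validation, not production enumeration.
- Gene–protein–reaction rules, compartments and constraint groups are
  ignored on SBML input; only stoichiometry, FBC bounds and the active
  objective are read.
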