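# Methods

## Model and detection conditions

The package works on stoichiometric networks `N = N⁺ − N⁻` with
irreversible reactions (reversible ones are split into forward and
backward copies; blocked reactions — those with zero flux in every
feasible steady state — are removed, together with any metabolites they
orphan, because a positive steady state is a prerequisite of
everything that follows). Kinetics are mass action throughout:
`v_i = θ_i ∏_j x_j^{N⁻_ji}`, with zero-order boundary imports allowed
(empty substrate set, `v_i = θ_i`). Exchange pseudo-reactions are
treated exactly this way; it is the one modelling commitment the
formalism needs for open networks and it is stated here rather than
hidden in code.

A metabolite `x_i` is detected as having a structurally constrained
concentration from the ODE of a witness `x_j` when

1. every reaction on one side of the witness ODE has at least one
   partner *lacking one substrate molecule* of `x_i` (substrate columns
   equal except one fewer unit in row `i`),
2. the union of those partners is mutually fully coupled, and
3. the other side of the ODE is mutually fully coupled,

where coupling is the transitive merge of structural couplings
(constant flux ratio over the bounded flux cone, certified by a
Charnes–Cooper transformed fractional LP) and kinetic couplings
(identical `N⁻` columns, ratio `θ_l/θ_k`, valid off steady state).
Case II applies the lack condition to the witness's consumers, Case I
to its producers; both are scanned, and the witness search is
restricted to metabolites adjacent to the reactions consuming `x_i`
(provably lossless: condition 1 forces `x_i` into the substrate sets
of the relevant reactions, which makes the witness a neighbour — the
test suite checks this equivalence against an unrestricted scan).

Each hit yields a certificate carrying the ODE sides, the lack sets,
a canonical representative pair (the relevant flux ratio), and the
relevant rate constants. The steady-state identity

`x_i = (σ_num/σ_den)(v_num/v_den)`

is then evaluated per certificate; ranges over a flux set are obtained
by optimizing jointly over the set and over the admissible choices of
one lack partner per reaction (capped at 64 combinations, with a
warning when truncated — certificates beyond that size have not
occurred in practice). Multi-witness ranges are intersected as
lower = max of lowers, upper = min of uppers; a crossed interval is
kept and flagged infeasible, since it certifies the absence of a
positive steady state rather than being an error.

Coupling coefficients are carried symbolically as monomials
`c · ∏ θ_r^{e_r}` so that kinetic couplings work with or without
numeric rate constants, and so the *relevant* rate constants of a
certificate can be read off after cancellation (a partner chain
through a kinetically coupled class cancels the intermediate θs).

## Numerical choices

* Coupling equality: relative 1e−6 with absolute floor 1e−9 (the
  literature states none); LPs solved with HiGHS. Structural-coupling
  candidates are pre-filtered on a dozen sampled vertices of the flux
  space, then every surviving pair is certified by the exact fractional
  program; transitively implied pairs are not re-solved.
* ODE integration: LSODA with the analytic mass-action Jacobian,
  rtol 1e−9 / atol 1e−12, doubling time windows; steady state declared
  at max_j |dx_j/dt| ≤ tol·max(1, x_j) with default tol 1e−8. Tests
  that verify the exact certificate identity integrate to 1e−11, since
  the oracle must be converged well past the 1e−6 comparison
  tolerance. Divergence is caught by a concentration guard.
* Flux-ratio programs: the minimal-flux floor ε = 1e−7 is applied to
  all lower bounds when conditions demand strictly positive flux; in
  the ratio-at-optimum program the objective-pinning constraint is
  t-scaled by default (the un-scaled variant is retained as
  `mode="literal"` for replication), and the optimum is pinned within
  |obj − z*| ≤ 1e−6·max(1, |z*|) to absorb degeneracy. The total-flux
  term of the weighted objective sums over all reactions, including
  the ATP reaction. Weight presets (1, 0.01), (0.1, 1) and
  (0.001, 1000) cover the reproduced experimental settings.
* MOMA: the strictly convex projection is solved with SLSQP (analytic
  gradient); solutions are accepted only if `Nv = 0` holds to 1e−6
  relative. Knocking out an unsplit reversible reaction zeroes both
  halves. Because a projected flux need not be exactly mass-action
  consistent, certificates of the same metabolite can disagree
  slightly; the per-metabolite knockout concentration is the median of
  the defined certificate values, and vanishing relevant fluxes are
  reported as undefined rather than zero.
* Fold-change bins: twelve half-open log2 bins, (−∞,−2.5], then 0.5
  steps to (2.5, ∞) — symmetric in up/down regulation and fully
  configurable. No published bin-level number is asserted against this
  default, as the published scheme's edges are not machine-readable.
* Missing rate constants: substitution operates per certificate on the
  ratios appearing in that certificate's σ_den — by one (all constants
  equal), or the mean or median of the ratios still known in the same
  equation, falling back to one when nothing is known. Removal in the
  robustness experiment happens at the rate-constant level, so a
  constant shared by several certificates disappears from all of them
  at once.

## Synthetic data

The generator plants motifs whose SCC status is provable, then adds
background: chains (import → A → B → export; both metabolites SCC),
shared-substrate hubs (one metabolite drained by two kinetically
coupled branches), and the two-armed second-order motif of the worked
example (hub SCC from both arm ODEs). Background is a random linear
pathway with shortcut reactions, which keeps every reaction unblocked
by construction. Rate constants are drawn log-uniformly over two
decades centred on 1 — wide enough to make substitution schemes hurt,
narrow enough that stiff integration stays cheap at desk scale — and
initial concentrations uniformly from [0.5, 2] mmol/gDW. Ensembles
perturb all initial concentrations independently by 1, 5, 10 or 20%
with symmetric random signs (a single-metabolite mode is available).
Planted motifs are re-verified through the full detection pipeline at
generation time.

What this emulates — and what it does not: the ensembles reproduce the
protocol of simulating many steady states from displaced initial
conditions, but the networks are small and modular, their couplings
shallow, and their rate constants far less skewed than measured
enzyme-level constants. Passing tests therefore demonstrate the
correctness of the detection conditions, the exactness of the
certificate identity, and the qualitative behaviour of the robustness
and calibration protocols; they do not demonstrate genome-scale
performance, which additionally depends on model curation and on the
choice of flux objective.

## Problem sizes used

The shipped validation runs 50 generated networks × 10 perturbed
initials for the identity check, and 20 networks × 5 removals (pooled
to 100 removals per fraction and scheme) for the rate-constant
robustness experiment; these sizes give stable medians while keeping a
full run in the tens of seconds on one core.

## Known limitations

* Only order-one differences are handled; reactions differing by more
  than one molecule of the target would lead to a polynomial fixed
  point equation and are out of scope.
* Michaelis–Menten or other enzyme-form kinetics are not rewritten
  into elementary mass-action steps.
* Flux predictions inherit the biases of the chosen LP objective; the
  calibration path inherits measurement noise multiplicatively.
* Predictions whose relevant fluxes differ by more than six orders of
  magnitude are flagged numerically unstable (threshold configurable).
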