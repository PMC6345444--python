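# sccnet

Structurally constrained metabolite concentrations in mass-action
metabolic networks.

## The problem

Constraint-based models predict steady-state *fluxes* from network
stoichiometry, but say nothing about metabolite *concentrations*
without kinetic parameters that are unknown at genome scale. For a
special class of metabolites, however, the concentration is pinned down
by network structure alone plus a handful of rate-constant ratios and a
single flux ratio. `sccnet` detects these metabolites — said to have a
**structurally constrained concentration (SCC)** — and turns flux
information into concentration predictions.

Under mass action, the rate of reaction *i* is
`v_i = θ_i · ∏_j x_j^{N⁻_ji}`, with `N = N⁺ − N⁻` the usual split of
the stoichiometric matrix. Two ingredients drive the method:

* **Full coupling.** Reactions can be fully coupled *structurally*
  (their ratio is fixed by `Nv = 0`, detected by a Charnes–Cooper
  transformed linear-fractional program) or *kinetically* (identical
  substrate columns of `N⁻`, so `v_l/v_k = θ_l/θ_k` at any state).
* **The lack relation.** Reaction `k` *lacks one substrate molecule* of
  `X_i` versus reaction `l` when their substrate columns differ by
  exactly one unit in row `i`. Then `v_l = x_i (θ_l/θ_k) v_k`
  identically.

If, for some witness metabolite `X_j`, every reaction on one side of
its ODE admits such a lack partner, the partners are mutually coupled,
and the other side is mutually coupled, then at any positive steady
state

```
x_i = (σ_num / σ_den) · (v_num / v_den)
```

where the σ constants depend only on stoichiometry, coupling
coefficients and a few *relevant* rate-constant ratios, and
`v_num/v_den` is a single *relevant flux ratio*. Optimizing the
right-hand side over a flux set `F` gives concentration bounds, and the
intersection over all witness ODEs gives the final range (an empty
intersection certifies that no positive steady state exists). When rate
constants are unknown, the σ ratio can instead be calibrated from one
measured reference condition and carried to unseen conditions.

## Worked example

The built-in seven-reaction demonstration network has a hub metabolite
B fed by an import R1 and drained by a second-order export R2, two
second-order arms R3 (→A) and R5 (→C), and a first-order export R7.
R3 and R5 share their substrate column; R7 lacks one B versus R2, R3
and R5.

```python
import numpy as np
from sccnet import *
from sccnet.examples import demo_network, demo_theta

net = demo_network()
cr = merge_couplings(structural_couplings(net), kinetic_couplings(net))
certs = find_scc(net, cr)
for c in certs:
    print(c.target, "from ODE of", c.witness, "ratio",
          "%s/%s" % c.ratio_pair, "thetas", c.relevant_thetas)

theta = demo_theta(theta1=1.0)
ss = integrate_to_steady_state(net, theta, np.ones(3))
for c in certs:
    s = sigma_pair(c, theta, cr, net)
    print("predicted", point_concentration(c, s, ss.flux_map()),
          "simulated", ss.concentration_map()["B"])
```

prints

```
B from ODE of A ratio R4/R7 thetas ('R3', 'R7')
B from ODE of C ratio R6/R7 thetas ('R5', 'R7')
predicted 0.4073141104290566 simulated 0.4073141056401706
predicted 0.4073141060911017 simulated 0.4073141056401706
```

B is the sole SCC metabolite; both witness ODEs recover the simulated
steady-state concentration — here via `x_B = (2θ7/θ3)(v4/v7)` and
`x_B = (2θ7/θ5)(v6/v7)` — from fluxes alone, to the accuracy at which
the simulation has converged, without integrating anything.

The same machinery is exposed on the command line:

```sh
scc examples --out fixtures
scc detect --model fixtures/demo.tsv --out results
# -> 1 SCC metabolite(s), 2 certificate(s)
```

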