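# Methods

## Characters and the dependency completion

Each taxon carries three three-valued scorings (present / absent /
unknown) for tympanic membrane (TM), tympanic annulus (TA) and columella
(CO). The completion operator applies the four lateral–medial implications
(CO absent ⇒ TA, TM absent; TA absent ⇒ TM absent; TM present ⇒ TA, CO
present; TA present ⇒ CO present) as forward rules that fire only from
*known* antecedents: unknowns are filled, known states are never changed,
and the operator is idempotent. TA absent deliberately leaves CO untouched
because the columella can occur without an annulus. Rows whose known
states contradict a rule are rejected and reported with line numbers
rather than silently repaired. Binary extraction uses 0 = absent,
1 = present, `?` = unknown throughout the package.

Taxon reconciliation at the pipeline level: scored taxa missing from the
tree are dropped with a warning; tree tips without a scoring enter every
analysis as `?` (ambiguous, state set {0, 1} / partial likelihood (1, 1)).
Dropping such tips instead is possible by pruning first; ambiguity was
chosen as the default because it uses the tree's full branch-length
information without asserting data that do not exist.

## Parsimony

Unordered binary parsimony with unit costs, computed by the Sankoff
recursion over all children of a node, so multifurcations are handled
natively and never resolved arbitrarily (resolution would change the
change counts). MPR node state sets come from combining subtree
(down-pass) costs with rest-of-tree (up-pass) costs: state `s` belongs to
node `v`'s set iff `down(v,s) + up(v,s)` equals the global minimum.

Directional counts are inherently ambiguous across MPRs. The extremes are
computed exactly with lexicographic cost pairs `(changes, losses)` or
`(changes, gains)` — the integer-exact version of pricing the disfavoured
direction at `1 + ε`, `ε → 0⁺` — giving `min losses` and `min gains` over
MPRs; the maxima follow from `gains + losses = length` in every MPR. A
published "lost at least N times" claim corresponds to the `min losses`
bound, and `count_independent_losses` reports exactly that, together with
the loss edges of a deterministic loss-minimal MPR traceback (nested
all-absent clades therefore count once). The summary also reports
unambiguous changes: edges whose endpoint state sets are disjoint
singletons, i.e. changes shared by every MPR.

## Mk model

Two states, gain rate `q01`, loss rate `q10`, transition probabilities in
closed form (`P(t) = Π + e^{-(q01+q10)t}(I − Π)`), which is exact and
cheaper than a generic matrix exponential; zero-length branches get the
identity matrix and are retained as read — the package never edits the
input tree's branch lengths. The pruning pass rescales partial likelihoods
at every node (log-accumulated), so likelihoods of large trees do not
underflow.

Root priors: flat (default), stationary, or fixed to a state. Flat is the
default for ER fitting and reconstruction; under ER flat and stationary
coincide, so the choice only matters for ARD and Dollo, where the prior is
part of the scenario definition.

Fitting maximizes the log-likelihood on the log-rate scale with L-BFGS-B
from the fixed multistart grid {1e-3, 1e-2, 0.1, 1, 10} × (tree height)⁻¹,
bounded to rates in [1e-9, 1e4]; the procedure is deterministic. A
constant character has its optimum at the zero-rate boundary and is
flagged (`boundary=True`) rather than treated as an error. AIC is
`2k − 2ℓ` with k = 1 (ER, Dollo) or 2 (ARD); ties rank the
fewer-parameter model first.

## Stochastic mapping

Histories are sampled in two exact stages. Joint node states: tipward
pruning partials, then rootward sampling of each node conditional on its
sampled parent and the data beneath it; this is vectorized across maps, so
10,000 maps on a few hundred tips take seconds. Branch paths: conditional
on the two endpoint states, the number of subordinated jumps is drawn from
its exact distribution under uniformization (rate Ω = max(q01, q10), jump
chain R = I + Q/Ω) and jump states are filled in by backward conditioning;
uniformization terminates by construction, avoiding the stalling of
rejection sampling on long branches with unlikely endpoints.

For batched change *counts* the path distribution simplifies: under equal
rates the change process is Poisson(q·t) restricted to the parity implied
by the endpoints, and under Dollo the count is determined by the endpoints
(1 for a present→absent edge, else 0); both are sampled vectorized. Since
changes on a two-state path strictly alternate, the split of a count into
gains and losses is a function of the count and the parent state. General
asymmetric rate matrices fall back to per-map uniformization. The two
samplers target the same distribution; the tests check the single-branch
event-count distribution against a discretized-chain oracle and the joint
node-state sampler against exhaustive enumeration (χ² at 10⁵ draws).

Counting rule: with threshold τ (default 0.5), a node is *called* for a
state only when the across-map frequency of that state strictly exceeds
τ; an edge contributes one gain or loss when both endpoints are called for
opposite states, and edges touching an uncalled node contribute nothing.
A node at exactly 50% support is uncalled. Counts are over edges only; the
root's own state never adds a change. Mean per-map event counts are
reported alongside as a smoother, threshold-free summary.

Scenarios: (1) `er_unconstrained` — ER rate fitted with a flat root prior,
maps sampled under the same; (2) `er_root_eared` — the *same* ER rate with
the root prior fixed to "present" (the rate is not re-estimated under the
constraint by default, since the constraint is on the ancestor, not the
process; `refit_rate=True` refits it); (3) `dollo` — gain rate exactly 0
(not a small positive number: "no regains" is absolute), loss rate refit
by ML with the root fixed "present". Data impossible under a scenario's
constraints (e.g. Dollo with an absent-fixed root and present tips) raise
an explicit impossibility error. One root seed drives everything; per-run
results are bit-identical across repeats.

## Synthetic data

`yule_tree` draws pure-birth trees (dendropy's birth–death simulator with
extinction 0), relabelled t1..tN; `simulate_mk` runs the forward chain
along every edge recording the full true history, so estimators can be
scored against truth. `simulate_dependent_triple` generates TM/TA/CO rows
that satisfy the dependency *by construction*: CO evolves under its own
rates, TA and TM evolve latent presence under lateral rates and are masked
to absent wherever their medial gate is absent. This gating scheme was
chosen over a joint 8-state chain for transparency; it reproduces the
observable dependency pattern but not any co-evolution of rates between
structures, so tests passing on these data say nothing about correlated
evolution in real scorings. Real data also differ in having non-ultrametric
signal, unresolved nodes and missing scorings clustered by literature
coverage; the pipeline accepts all of these but the generator does not
emulate them (polytomy handling is exercised with explicit test trees).

## Problem sizes and tolerances

Exhaustive-enumeration checks run on 200 random instances of ≤ 5 tips
(likelihood, tolerance 1e-10) and ≤ 6 tips (parsimony, exact equality),
sizes at which enumeration is still a complete oracle. Monte-Carlo
consistency between mapping posteriors and marginal probabilities is
checked at 10,000 maps on a 50-tip instance (max deviation < 0.02,
roughly three binomial standard errors at p = 0.5). ER rate recovery uses
20 replicates of 300-tip Yule trees at a true rate of 0.3 per unit tree
height — slow enough that the character is conserved, fast enough that
changes occur — with a 25% median relative-error criterion. The
acceptance script runs the full pipeline at 239 tips, matching the focal
clade size of the reference amphibian phylogeny, with loss-biased
defaults (CO gain 0.5/height, loss 1.5/height; lateral 0.5 and 1.0)
reflecting a radiation in which ear loss is common.

## Known limitations

* Binary characters only; no ordered or multi-state generalization.
* One fixed tree; no integration over phylogenetic uncertainty.
* No correlated-evolution (joint) model of the three structures — they
  are analysed independently, with the dependency enforced at the coding
  stage only.
* No ascertainment-bias correction; rate estimates assume the character
  was not selected for being variable.
* The independent-loss bound is a parsimony statement; where gains and
  losses are equally parsimonious the bound can be 0 even when losses
  certainly occurred under a loss-biased process.
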