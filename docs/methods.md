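# Methods

## Model class and semantics

`unitselect` works on discrete Bayesian networks and structural causal
models.  An SCM is a BN whose internal (endogenous) CPTs are *functional*
(all entries 0/1, encoding structural equations), with all randomness in
the root (exogenous) priors.  The joint is the product of root priors on
instantiations consistent with every equation, and zero elsewhere.
Functional-CPT detection rounds at 1e-12; all probabilistic comparisons
elsewhere use an absolute tolerance of 1e-9 (CPT row normalization, oracle
agreement, score equality).  State declaration order is semantic: it fixes
odometer order in serialization and every argmax tie-break (first state
wins), which makes all solvers bit-reproducible.

## Counterfactuals on parallel-worlds models

A query Pr(out₁ under do₁, out₂ under do₂ | evidence) is evaluated on a
joined model with up to three worlds sharing all exogenous roots: world 0
carries the real-world evidence, worlds 1 and 2 carry the two intervention
arms, with intervened copies mutilated.  The construction drops any world
it does not need — world 0 when the evidence mentions no endogenous
variable, an arm world when that arm is empty — because dropped worlds
marginalize out exactly; a flag forces the full triplet.  An intervened
*root* gets a world-local clamped copy while the other worlds keep the
shared node, which preserves the do-semantics (the intervention overrides
the exogenous draw in its world only).  Conditioning on a zero-probability
event raises rather than returning 0, since a silent 0/0 usually signals a
mis-specified model.

## Objective models and Reverse-MAP

The objective model joins one parallel-worlds model per component through
the shared unit variables and adds a mixture root `H` as a parent of every
outcome copy.  Weights are normalized into H's prior (`θ(hᵢ) = wᵢ/Σw`) and
scores are rescaled by `Σw` on output; the normalization cancels inside
the conditional `Pr′(e1|u,e2)`, so the argmax is invariant under positive
scaling of the weights — the package therefore accepts arbitrary
non-negative weights rather than requiring them to sum to one, and rejects
the all-zero weight vector.  Root units are shared as single nodes.
Internal (endogenous) units get per-component real-world copies tied
together by one auxiliary equality child per unit variable (state "eq"
with probability 1 iff all parent copies agree), clamped in `e2`; the
first component's copy serves as the query target.  Components with
evidence keep their real world; evidence-free components use the twin
optimization.

Units `u` with `Pr(u, e2) = 0` score 0 and are thereby excluded from the
argmax (a unit whose conditioning event is impossible offers no measurable
benefit); if `Pr(e2)` itself is zero the whole query is undefined and an
error is raised.

## Variable elimination

`RMAP_VE` runs the two sum passes along the identical constrained minfill
order.  To keep the pass-to-pass factor correspondence purely structural,
the second pass replaces each `e1` indicator with an all-ones factor over
the same variable instead of omitting it: both passes then manipulate
factor lists of identical scopes, the residual sets match pairwise by
position, and the pairwise quotient with `0/0 = 0` is well defined (a
pass-1 residual is entrywise dominated by its pass-2 partner, so the
support condition holds exactly).  Division is performed once after both
passes complete, not interleaved.  Argmax decoding walks the max-pass
witnesses backwards; a unit never mentioned by a residual factor defaults
to its first state.  An exhaustive mode materializes the full per-unit
score table when the unit space has at most 4096 instantiations.

Width computation simulates factor scopes (clusters) rather than running
graph elimination, so evidence indicators and the mixture CPT scopes are
counted exactly as elimination will see them.  Minfill breaks ties by
declaration order.  In lifted orders, equality-clamp nodes are placed just
before `H` (the lifting construction predates the clamp nodes; placing the
clamps with `H` keeps them out of the unit suffix while adding at most
their scope to one cluster).

## Circuit compilation

Compilation records the VE computation symbolically: eliminating `V`
builds, per reduced-scope instantiation, the sum `Σᵥ λᵥ·nᵥ` over all
states of `V` — a smooth decision node — with CPT entries as parameter
nodes and multiplications as (flattened) product nodes.  Under a
unit-constrained order no unit-decision sum ends up below a non-unit one
and every indicator attaches at a decision node of its variable, the two
structural conditions for linear-time MAP; determinism after projection on
the units then follows and is additionally verified empirically on small
unit spaces.  Zero parameters are kept as explicit nodes rather than
constant-folded: folding zero branches would break structural smoothness
and the checkable decision form, and at the problem sizes this package
targets the size savings are not worth losing the invariant.  Parameter
nodes are never merged, so a circuit structure supports arbitrary
reparametrization; dividing two parametrizations elementwise (0/0 = 0,
support condition enforced) yields the quotient distribution on the same
structure.  `RMAP_AC` is one bottom-up pass with visit counters asserted
at 1 per node.

Where the VE and circuit routes could disagree on exactly tied optima
after floating-point accumulation in different operation orders, the tests
accept any returned unit whose brute-force score attains the optimum and
require exact argmax agreement whenever the optimum is unique.

## Learning pipeline

`fit_bn` is maximum likelihood with uniform (add-c) smoothing; the
smoothing constant defaults to 1 and is recorded in the pipeline output.
`binarize` median-splits numeric columns (strictly-greater maps to state
1), passes 0/1 columns through, and reports the thresholds so they can be
re-applied.  `bn_to_scm` replaces each internal CPT by a functional table
driven by one fresh root per variable, whose states are the intervals cut
out of (0,1] by the union of the row-wise cumulative sums (cutpoints
merged at 1e-12): marginalizing the root recovers every CPT row exactly,
and sharing a single partition across rows keeps the root's state count
minimal for an inverse-CDF construction.

## Synthetic benchmark generator

The generator emulates the structure of SCMs used in counterfactual
reasoning: a random DAG over `n0` binary nodes (each non-first node draws
its parent count uniformly from {1..min(p, predecessors)}, default
p = 6, parents uniformly without replacement), then one fresh, unique
binary root parent per internal node; internal equations are random
deterministic functions of all parents and root priors are symmetric
Dirichlet.  Unit variables are drawn from the added roots first, so they
are *external* (removing them leaves the DAG connected) and the instances
are provably hard for constrained elimination; only a requested unit
fraction exceeding the added-root count falls back to original roots.
The default benefit weights (0.6, 0.2, 0.15, 0.05) form a generic profile
dominated by responders while keeping all four response types active, so
generated objectives rarely tie.  Everything is seed-deterministic.

What the generator does not emulate: non-binary state spaces, soft
(stochastic) structural equations, selection bias in the data pipeline,
and real-data discretization error.  Passing tests therefore certify the
*inference* machinery exactly, but say nothing about the adequacy of a
learned SCM for a real system — the case-study pipeline is validated by
generate-then-fit recovery and solver agreement, not by external data.

## Problem sizes and verification

The randomized verification corpus uses 200 instances with initial DAGs of
3–5 nodes (5–9 SCM variables, at most 3 binary units) so that the
brute-force enumerator remains an independent oracle at negligible cost;
treewidth-bound checks run on 100 instances, and the equality
`evaluate(circuit) = joint` is enumerated exhaustively on models of at
most 10 variables.  These sizes were chosen so the full suite documents
every claim end-to-end in well under a minute of solver time while the
asymptotic behaviour is covered by the structural width reports, which
need no inference runs.

## Known limitations

* Exact inference only: no pruning of barren nodes, no approximate or
  anytime modes; cost is exponential in the constrained width.
* Disjunctive or nested counterfactual expressions are out of scope; the
  objective class is the weighted-sum form above.
* Treatment, outcome and evidence variables must be endogenous; unit
  variables may not descend from treatments or outcomes.
* BIF import covers discrete networks with `table` or per-row probability
  blocks; export is JSON-only.
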