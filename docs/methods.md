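# Methods

This note documents the statistical model, the algorithmic choices and the
numerical conventions used throughout the package, plus what the synthetic
benchmark does and does not show.

## Model

A discrete Bayesian network over variables $X_1,\dots,X_n$ factorizes the
joint as $P(x) = \prod_i \theta_{i\,j(x)\,x_i}$, where $j(x)$ is the joint
state of node $i$'s parents. Parent configurations are encoded in mixed
radix over the declared parent order (first parent most significant,
0-based internally; reports are 0-based as well). With complete data the
likelihood separates per node and row, with sufficient statistics
$N_{ijk}$ and row sums $N_{ij}$; the ML estimate is $N_{ijk}/N_{ij}$
(uniform, and logged, for unobserved rows).

The posterior-mode estimate under a Dirichlet row prior with mean shape
$\theta^{\mathrm{prior}}_{ij\cdot}$ and total mass (equivalent sample
size) $\alpha_{ij}$ is the blend

$$\hat\theta_{ijk} = \frac{N_{ijk} + \alpha_{ij}\theta^{\mathrm{prior}}_{ijk}}{N_{ij}+\alpha_{ij}},$$

a convex combination of the data frequency and the prior shape with
weights $N_{ij}$ and $\alpha_{ij}$. Everything in the package is about
choosing the shape and the mass from expert constraints.

## Constraints

Three kinds, all linear in one node's CPT entries: range bounds on a
single entry; intra-distribution orderings between two states of one row;
cross-distribution (monotonic-influence) orderings of one state across two
parent configurations. Constraints are per node; cross-node statements are
rejected. All inequalities are treated as non-strict (strict inequalities
have no meaning for the LP/polytope machinery); the satisfaction tolerance
defaults to 1e-9. The simplex conditions (row sums one, entries in
[0, 1]) are always appended implicitly. If the constraint set is
infeasible the tool reports it and aborts — it never silently relaxes
expert input.

Feasibility is decided per node by a Chebyshev-center linear program in
the affine row-sum subspace (null-space parametrization, `scipy.linprog`
HiGHS); the center doubles as an interior starting point for sampling and
optimization.

## Prior elicitation

The prior shape is the coordinate-wise mean of points drawn uniformly from
the constraint polytope. Sampling is hit-and-run: propose an isotropic
Gaussian direction inside the row-sum null space, intersect the line with
the inequality system to get a chord, draw the next point uniformly on the
chord. Defaults: 100 burn-in steps from the Chebyshev center, thinning 10
between retained samples, 100 retained samples per node (configurable).
A diversity rule keeps consecutive retained samples at least $\tau = 0.1$
apart in Euclidean norm; candidates closer than $\tau$ to the previous
retained point are rejected and the walk continues. If no $\tau$-separated
candidate is found after 50 attempts, $\tau$ is halved (at most 10 times,
then dropped), so very small polytopes still sample. The diversity
rejection mildly re-weights the chain toward the polytope boundary; on a
1-D polytope of width 0.4 the effect is below Kolmogorov–Smirnov
detectability at 500 samples, and it cannot move the mean outside the
polytope, so the elicited prior always satisfies the constraints
(convexity). Rows without constraints are sampled over the bare simplex
through the same code path and come out near-uniform.

Constant-objective LP re-solves were considered for sampling and rejected:
LP solvers return vertices, which biases the mean toward extreme shapes
and interacts badly with the diversity rule; hit-and-run targets the
uniform distribution on the polytope directly. (This also explains why the
package's elicited priors for sparse constraint sets are milder than
hand-picked near-vertex shapes: with only a few orderings, the polytope
mean is far from 0/1.) A vertex-flavored alternative can be emulated by
raising $\tau$.

## ESS bounds and selection

Substituting the blend into a constraint gives a condition on
$\alpha_{ij}$:

* range and intra constraints: linear, solved as interval conditions;
* cross constraints: after tying the two configurations' ESS together
  ($\alpha_{ij_1}=\alpha_{ij_2}=\alpha$), a quadratic
  $a\alpha^2+b\alpha+c\le 0$ with $a = p_{j_1k}-p_{j_2k}$,
  $b = N_{ij_1k}-N_{ij_2k}+N_{ij_2}p_{j_1k}-N_{ij_1}p_{j_2k}$,
  $c = N_{ij_2}N_{ij_1k}-N_{ij_1}N_{ij_2k}$, solved in closed form with
  all leading-coefficient sign cases enumerated (comparisons at 1e-12).

Each bound op reports the interval of admissible $\alpha$, flagged
*persistent* when every larger $\alpha$ also satisfies the constraint (the
usual case: prior shape consistent with the constraint, data against it —
then the bound is the familiar closed-form threshold). When the prior
shape itself contradicts an ordering the condition may hold only on a
bounded window ($a>0$ quadratic) or never (unsatisfiable); both are
flagged rather than hidden, and the post-hoc pass below is the guard. The
effective bound of a configuration is the maximum over all bounds naming
it (a cross constraint contributes to both of its configurations).

Selection: a **global** ESS per node is chosen by cross-validation over
the integer grid 1..50 (configurable), scoring summed held-out
log-likelihood of the blend; 5 folds, seeded uniform split, leave-one-out
below 10 records, ties to the smallest candidate (minimal regularization).
**Local** ESS: unconstrained configurations inherit the global value;
constrained ones keep it when it clears their bound, otherwise they are
cross-validated over the grid starting at the bound's ceiling (or pinned
to the ceiling, with a warning, when it exceeds the grid — constraint
satisfaction is prioritized over likelihood). Because cross bounds are
derived under a tied ESS but selection may untie them, a final pass
re-checks every cross constraint on the actual estimates and jointly
escalates both configurations' ESS along the grid until the ordering holds
or the grid is exhausted (then a warning is raised and the violation
reported in the fit diagnostics).

## Baselines

ML and flat-prior MAP (shape $1/r_i$, ESS 1) are exact formulas.
Constrained ML maximizes the per-node log-likelihood over the constraint
polytope (SLSQP on the full node CPT, since cross constraints couple
rows; concave objective, interior start). The entropy baselines maximize
the summed row entropies subject to the constraints and a likelihood slab:
log-likelihood within `me_epsilon` (default 0.05 nats per record) of the
constrained maximum. This formulation is this package's own well-posed
reconstruction of the maximum-entropy family — its two limits are the
uniform CPT (loose slab) and constrained ML (tight slab) — and is intended
as a qualitative baseline, not a reproduction of any particular published
variant.

## Evaluation

Accuracy against a known truth is the joint KL divergence, computed by
factorization: $\sum_i \sum_j P^*(\mathrm{pa}_i = j) \sum_k
\theta^*_{ijk}\log(\theta^*_{ijk}/\hat\theta_{ijk})$, with the parent
marginals obtained by exact enumeration of the true joint (refused above
2×10⁶ outcomes; the benchmark networks have 32). An unweighted per-row
average is available as an option. A zero estimate against positive truth
yields +inf; every estimator except raw ML smooths, and benchmark ML is
floored at 1e-12 (flagged) so its KL is finite but appropriately large.
A sample-complexity reference value for ML learning —
$288\,n^2 2^k/\varepsilon^2 \cdot \ln^2(1+3n/\varepsilon)\cdot
\ln((1+3n/\varepsilon)/(\varepsilon\delta))$ — is reported alongside
benchmark results for context; the grouping of the final logarithm's
argument is ambiguous in the usual typesetting and the form above is the
one implemented.

## Synthetic benchmark

`make_test_network` draws a random DAG (each node takes up to 2 parents
from its predecessors) with CPT rows from a symmetric Dirichlet whose
concentration encodes the uniformity profile: 0.1 (strongly skewed), 0.5
(skewed), 5 (uniform), 50 (strongly uniform), or a per-row coin flip
between 0.1 and 50 ("combined"). Constraints are derived from the truth:
range bounds widen each entry by margins drawn from Uniform(0.15, 0.25)
("around 0.2"; the distribution is this package's choice), orderings are
emitted only where the true gap is ≥ 0.2, and at most 3 constraints per
node are kept by seeded subsampling — so generated constraints are always
truth-consistent. Constraint-sparsity grids subsample each node's pool as
a prefix of one seeded permutation, so the subsets nest.

Default study conditions: 5-node binary networks, ≤ 2 parents, N = 20
records, 100 replicates for full runs; the in-repo acceptance check uses
30 replicates with the `skewed` profile, sized so the whole suite runs in
well under a minute per benchmark while leaving the directional findings
(constraints reduce the constraint-adjusted estimator's KL; it dominates
ML at small N; flat-prior MAP wins narrowly at zero constraints) clearly
resolved. What the benchmark does **not** show: performance on the
published reference networks themselves (their CPTs are not reproducible
from the figures), behavior under misspecified or adversarial expert
constraints (generated constraints are always correct), incomplete data,
or non-binary cardinalities at scale.

## Worked-example caveats

The brain-tumor illustration is reproduced exactly where its inputs are
printed: the counts, the blend values, the range-bound 16 and the tied-ESS
cross bound 5.49 (two decimals). The other two printed per-configuration
bounds (5.92, 9.01) recompute to 5.90 and 9.00 from the two-decimal
printed priors — consistent with the source having used unrounded priors —
and are asserted only at that tolerance. The printed prior itself (0.99,
0.95, …) is more extreme than the mean of the polytope cut by the five
orderings alone; the elicitation here reproduces its qualitative
orderings, not its digits, and the printed global/local ESS values depend
on an unspecified fold protocol and are treated as illustrative.

## Constraint DSL

```yaml
constraints:
  - {type: range, node: C, parents: {BT: 1, IS: 1}, state: 1,
     lower: 0.6, upper: 1.0}
  - {type: intra, node: C, parents: {BT: 0, IS: 0},
     lesser_state: 1, greater_state: 0}
  - {type: cross, node: C, state: 1,
     lesser: {BT: 0, IS: 0}, greater: {BT: 1, IS: 1}}
```

States may be labels or indices; parent configurations name every parent.
Duplicates are dropped with a warning; unknown nodes/states and inverted
ranges are errors.
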