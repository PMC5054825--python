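# Methods

## Model and test

Two groups (D, C) with $n_1, n_2$ subjects are measured on the nodes of one
directed acyclic network each ($G^D, G^C$; usually the same structure). The
null hypothesis is that the two networks — node levels and directed edge
strengths jointly — do not differ.

The comparison works on the *merged structure*: union node set (size $K$),
union directed-edge set (size $M$), per-group presence flags. An element
absent from one group contributes zeros for that group (mean, variance,
coefficient and coefficient variance), so structure differences themselves
generate signal. Reversed pairs are two distinct union edges by default; in
`collapse_reversed` mode an $i \to j$ in one group and $j \to i$ in the
other share one slot and their own-orientation coefficients are compared
directly.

Node terms are squared Welch t statistics,
$U_k = (\bar x^D_k - \bar x^C_k)^2 / (s^{2D}_k/n_1 + s^{2C}_k/n_2)$.
Edge strengths are estimated per child by OLS of the child on its *full*
parent set plus an intercept — exactly the generative form of the linear
SEM below, so $\hat\beta$ is consistent for the structural coefficient, and
the intercept keeps pure mean shifts out of the edge terms. Edge terms
standardize by the sum of the two groups' OLS sampling variances,
$V_m = (\hat\beta^D_m - \hat\beta^C_m)^2 / (\widehat{Var}^D_m + \widehat{Var}^C_m)$,
mirroring the node term (a pooled-variance variant would also be defensible;
the summed form is used and the combiner accepts alternative term
functions). Totals: $NS = \sum U_k$, $ES = \sum V_m$, $NES = NS + ES$,
$WNES = \sum w_k U_k + ES$.

Degenerate denominators: $0/0 \mapsto 0$ (e.g. an element absent from both
sides of a slot after zero-fill), while a zero denominator with nonzero
numerator raises an error naming the element — a constant variable differing
in level between groups is a data pathology worth surfacing, not a finite
statistic.

### Weights

$r_k$ = descendant count of node $k$ (all nodes reachable downstream,
counted once) divided by the total descendant count; all zeros for an
edgeless graph. "Importance" via full descendant sets (rather than direct
children, available as `count_mode="children"`) reflects that a node's
perturbation propagates to everything downstream of it. Families:

| family   | $w_k$                | tuning | default |
|----------|----------------------|--------|---------|
| unit     | $1$                  | —      | —       |
| additive | $1 + K r_k / a$      | $a>0$  | $a=1$   |
| power    | $(1 + K r_k)^{1/b}$  | $b>0$  | $b=2$ typical |

Every family maps childless nodes to exactly 1, and smaller tuning
constants amplify the topological contribution. With $a = 1$ the additive
weight adds the node's descendant count divided by the mean descendant
count to the baseline 1. On the bundled 12-node cascade the vector is
$w = (4.88, 2.76, 2.06, 3.12, 1.71, 1.71, 2.06, 1.00, 1.35, 1.35, 1.00, 1.00)$
for X1..X12. When the two groups' structures differ, each group's relative
weights are computed on its own network and averaged, preserving group-swap
symmetry; with equal structures this is the ordinary single-network weight.

### RT

The aligned-rank test: optionally standardize each column over the pooled
sample (for panels mixing units), subtract the pooled per-column median,
rank each subject's $K$ aligned values (midranks on ties), and compare the
group mean rank vectors: $RT = \frac{n_1 n_2}{n_1+n_2}\,
\lVert \bar W^D - \bar W^C \rVert^2$. The leading scalar (and any positive
scaling) cancels in the permutation p-value. The unscaled Euclidean form is
used; a Mahalanobis variant with the pooled rank covariance is a possible
alternative reading and is deliberately not guessed at.

### Permutation test

p-value = #{permuted statistic ≥ observed} / B, with subjects reassigned
uniformly at random to the two groups at fixed sizes (B draws, sampled with
replacement from the arrangements; the observed arrangement is not
automatically included, so p = 0 is possible — a conservative
(count+1)/(B+1) mode exists). Every permutation re-runs the complete
pipeline, including the per-group edge regressions and presence/zero-fill
bookkeeping, on the relabeled split. All requested statistics are evaluated
on one shared permutation stream so their p-values are comparable.

Implementation note: for a fixed pooled matrix every per-group quantity is
a linear functional of the 0/1 membership mask, so the B recomputations
reduce to batched matrix products and stacked small solves
(`wnes._batch`); the batched path is asserted against the one-shot modular
pipeline in the test suite. Within-subject RT ranks are
permutation-invariant (the pooled median does not move), so they are
computed once. A joint run at $K = 12$, $M = 15$, $n = 200$, $B = 500$
takes ~20 ms.

## Simulator

Linear Gaussian SEM on a DAG: in topological order, node $=$ intercept
$\delta$ + $\sum \beta \cdot$ parent + $N(0, \sigma^2)$ noise. Exact implied
means/covariances are accumulated in topological order and serve as the
oracle for the sampler (sample covariance at $n = 10^5$ matches within
3 Monte-Carlo SEs per entry).

Defaults (the study conditions): $\beta = 0.5$ on every edge,
$\sigma^2 = 1$, $\delta = 0$. Under these, node variances stay $O(1)$ and
edge OLS is well-conditioned at $n = 100$ per group. Scenario effect sizes:
edge-coefficient delta $+0.3$; node mean shift $+0.4$, calibrated so the
leading statistic's power sits mid-range (0.5–0.9) at $n = 100$ per group,
where the ordinal power comparisons are informative rather than floor- or
ceiling-bound.

**Rectification.** After perturbing coefficients, walking the nodes in
topological order resets, for every node not explicitly mean-shifted by the
scenario, the intercept and error variance so the node's implied marginal
mean and variance equal baseline (Gaussianity makes the marginal
distribution identical, not just moment-matched). A scenario that pushes
more variance through a node's parents than its baseline marginal allows is
reported as infeasible, naming the node. Scenario I (pure mean shifts) is
deliberately not rectified: shifts propagate downstream but leave all
covariances untouched.

**Scenarios** on the 12-node fixture: I shifts X2 (+0.4); II adds 0.3 to
the X2→X5 coefficient (rectified, so only edge strengths differ); III = II
plus a +0.4 shift on X1 (the maximal-weight node, $w = 4.88$); IV = II plus
+0.4 on the childless X8 ($w = 1$); dir-I reverses X4→X6 in the control
group's structure keeping its coefficient; dir-II additionally collapses
the reversed pair in the analysis. Direction scenarios are not rectified
(the two endpoint nodes' equations are themselves the change under study).

**Fixtures.** The wiring of the motivating pathways is not public, so the
fixtures are synthetic stand-ins with the same node/edge counts: `upr12`, a
three-branch cascade (12 nodes, 15 edges, single root, depth ≥ 3, giving
heterogeneous weights from 1.00 to 4.88); `upr12_rev` with X4→X6 flipped;
`wnt35`, a seeded deterministic DAG (35 nodes, 79 edges, one backbone
parent per non-root plus extra forward edges, in-degree capped at 6 so
$n = 100$ per group supports every child regression). What the generator
emulates: jointly Gaussian, complete, independent-subject data generated
exactly by the model the edge estimator assumes. What it does not: heavy
tails, missingness, measurement error, correlated subjects, model
misspecification (nonlinear or feedback regulation), or unknown structure —
so passing calibration here shows correctness of the procedure under its
own assumptions, not robustness on real omics data.

## Monte-Carlo harness

`rejection_rate` simulates both groups per replicate (replicate $r$ uses
the stream seeded `seed + r` for data and permutations — reruns are
bit-identical), runs the joint permutation test, and reports per-statistic
rejection proportions with binomial SEs. Default scale 500 replicates × 500
permutations (SE ≈ 0.01 at the null); the full 1000 × 1000 design is a
parameter change. `type1_table` arranges null rates as statistic-blocks ×
sample sizes × networks; `power_curve` runs a named or custom scenario
across sample sizes with an optional plot.

## Findings the harness reproduces (and one it cannot)

At $\alpha = 0.05$ all five statistics hold their level on both fixtures.
Node-only change leaves ES at the level; rectified edge-only change leaves
NS at the level while ES responds; edge-plus-weighted-node change makes
WNES the most powerful of the five (the weight multiplies the shifted
node's term by 4.88).

In the collapsed-reversal scenario (dir-II) the four parametric statistics
find no power, as designed — their estimands coincide across groups — and
are in fact mildly conservative, because the permutation null mixes the two
covariance structures. The rank test RT also shows no power here, and this
is provable rather than accidental under the package's zero-mean Gaussian
conditions: every pairwise $P(X'_j > X'_k) = 1/2$ by symmetry, so the group
mean rank vectors share one expectation, and with equal group sizes the
covariance of $\bar W^D - \bar W^C$ equals $(\Sigma^D + \Sigma^C)/m$ under
both the observed split and permutation — the two distributions agree in
all matched moments. A rank-test advantage on pure direction reversal would
require asymmetries (e.g. nonzero structural means interacting with the
reversal without rectification) that simultaneously give NS power; the
harness therefore reports RT's behaviour in the direction scenarios without
being able to reproduce a genuine RT-only detection.

## Numerical and design choices

- OLS by normal equations; condition number of $X'X$ above $10^{12}$ is
  reported as collinearity naming the child; RSS clipped at 0;
  $\hat\sigma^2$ uses $n - p - 1$; node variances use $n - 1$.
- Sample-size guard: each child regression needs $n > p + 1$; groups need
  $n \ge 3$.
- Ties in RT use midranks.
- p-values compare with `>=` on raw floats; all statistics are continuous
  under the generator, so ties occur only for genuinely identical
  recomputations.
- Labels are exact-match case-sensitive strings; a cross-group collision
  differing only in case is rejected rather than harmonized.
- Seeds: every stochastic entry point takes an integer seed or a Generator;
  replicate streams derive as `seed + index`.

## Limitations

- Directed acyclic structures only; feedback loops invalidate the
  descendant-count weight and are rejected at validation.
- The network structure is an input, not learned; with many candidate
  networks, correct the resulting p-values (e.g. Bonferroni) downstream.
- Asymptotic null distributions are out of scope (network-specific);
  inference is permutation-only, so runtime scales with $B$.
- No missing-data handling, no robust/regularized edge estimation, no
  non-Gaussian error families in the simulator.
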