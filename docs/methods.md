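# Methods

## Model

A dynamic network is a sequence of `T` snapshots on a common set of `N`
nodes, with a presence mask `R_it` marking which nodes exist at which steps
(species not sampled in a season, individuals not yet tagged). Each node
follows a hidden Markov chain over `Q` groups — initial distribution `α`,
shared transition matrix `Π` — and, conditionally on the groups, each
observable dyad (both endpoints present; ordered pairs when directed;
`i = j` included only when self-loops are allowed) is drawn from a
zero-inflated categorical distribution

    P(Y_ijt = 0) = 1 − β_qlt,      P(Y_ijt = m) = β_qlt γ_qlt(m),  m = 1..M,

with `q, l` the groups of `i, j` at `t`. The two factors separate **sparsity**
(how often an edge exists between two groups) from **intensity** (how strong
it is when it exists), which is exactly how the block-pair summary tables are
read. `M = 1` collapses the second factor and gives a Bernoulli model.

Assumptions worth stating explicitly:

- chains are i.i.d. across nodes and time-homogeneous;
- dyads are independent given the memberships;
- a node absent at step `t` contributes nothing at `t` — its dyads are
  unobservable, not zero;
- between two consecutive *present* steps the chain makes exactly one `Π`
  transition, regardless of how long the absence gap is. (Alternatives —
  powering `Π` by the gap length, or re-drawing from `α` — are defensible;
  the single-step rule is the simplest contract and is what the simulator
  and the likelihood both implement, so inference is consistent with the
  generative process.)

### Identifiability

With memberships free to move between snapshots, group labels are only
comparable across time if something ties a group at `t` to "the same" group
at `t+1`. We therefore hold the within-group emission parameters `β_qq`
(and `γ_qq` when `M > 1`) constant over time, while off-diagonal parameters
may vary freely with `t`. The constraint binds both sparsity and intensity
on the diagonal; binding both is the conservative choice and is enforced in
the parameter container, the simulator, and the M-step alike.

## Variational inference

The exact posterior couples all `N` chains through the observed dyads. The
variational family is a product over nodes of Markov chains on each node's
present steps: cross-node coupling is severed, within-node temporal
dependence is kept. This yields:

- **E-step.** For node `i`, the emission message at step `t` for group `q`
  is the expected log-emission against all other present nodes,
  `log ρ_itq = Σ_j Σ_l τ_jtl log f(Y_ijt; Θ_qlt)` (both directions summed
  when directed; the self-loop adds `log f(Y_iit; Θ_qqt)`). Exact
  forward–backward along the node's present steps (initial `log α`,
  transitions `log Π`) then gives updated marginals `τ_i` and pairwise
  joints `ξ_i`. Nodes are swept in fixed index order (reproducibility), and
  because each node update is the exact coordinate maximizer given the
  others, every sweep increases the ELBO. Up to 5 sweeps are run per
  E-step, stopping early when the largest change in `τ` falls below 1e-4.
- **M-step.** Closed-form ratios of expected counts: `α` from first-present
  steps, `Π` from summed `ξ`, off-diagonal `β_qlt`/`γ_qlt` from per-step
  expected block counts, diagonal entries pooled over all steps. All
  ratios are smoothed additively with `ε = 1e-6` (numerator `+ε`,
  denominator `+Kε` for `K` cells), so parameters stay strictly positive
  even when a group empties out — empty groups are allowed and retained,
  making `Q` the *maximal* number of groups.
- **ELBO.** Expected complete log-likelihood plus the entropy of the
  variational chains. It is non-decreasing across iterations (the
  `ε`-smoothing perturbs the exact M-step argmax by a relatively negligible
  amount) and never exceeds the exact log marginal, which
  `exact_log_marginal` verifies by exhaustive enumeration on instances
  small enough to enumerate (≤ 2^20 configurations).

Convergence: relative ELBO change below 1e-6, at most 100 outer
iterations. Restarts: the first initialization clusters nodes by k-means on
the rows of the time-aggregated adjacency (in- and out-profiles
concatenated when directed) — aggregated structure is a strong, cheap
start; the remaining initializations are uniform random one-hot
memberships. Default 5 restarts, best final ELBO wins.

MAP membership trajectories come from a per-node Viterbi pass using the
converged emission messages, so reported paths respect the chain instead of
being pointwise argmaxes; ties break toward the lowest group index. Absent
node-steps are reported as group 0 throughout.

With `Q = 1` every quantity is diagonal, so the single `β` is pooled over
time and equals the pooled observed density; the ELBO then equals the exact
log marginal, which the tests assert.

## Choosing Q

**ICL** is the completed log-likelihood at the MAP memberships minus half
the number of free parameters per block times the log of that block's
effective sample size: `(Q−1)` initial probabilities against `N` chains,
`Q(Q−1)` transition parameters against the `N(T−1)` transitions, and the
emission parameters (off-diagonal: `Q(Q−1)·T·M`, halved for undirected
networks; diagonal: `Q·M`, time-pooled) against the number of observable
dyad-step observations. The selection *behaviour* — finding the planted
`Q` on simulated data — is the tested contract; the additive constants are
kept in one function (`icl_penalty`) so alternative conventions can be
swapped in.

**Elbow.** "The log-likelihood slope flattens" is formalized as the `Q`
maximizing the discrete second difference of the ELBO-vs-Q curve; interior
points only, ties to the smallest `Q`, invariant to adding a constant.

## Weight binning

Raw positive weights are pooled over *all* steps and dyads and split into
`M` equal-frequency bins (quantile thresholds, linear interpolation); a
weight equal to a threshold goes to the lower bin (deterministic and
order-independent), zeros stay zero. Pooling over time keeps category `m`
meaning the same intensity at every step; binning per step would make the
intensity tables incomparable across time. Whether to bin per step or
pooled, and whether thresholds should be strict tertiles, is a genuine
modelling choice for any given dataset; pooled equal-frequency is this
package's default reading.

## Synthetic scenarios

The simulator is first-class: it draws memberships and snapshots exactly
from the model above, and the documented scenarios set the scales at which
the method is meant to operate.

- `ants_like`: `N = 152`, `T = 10`, undirected, `M = 3` categories,
  `Q = 3`, everyone present. Within-group contact is dense and
  time-constant (β_qq between 0.75 and 0.9); one pair of groups is nearly
  disconnected (β = 0.08) and interacts only at low intensity, while the
  remaining cross-group connectivity is moderate with a mild seasonal
  wobble (±0.04). Chains stay put with probability 0.9.
- `foodweb_like`: `N = 26`, `T = 6`, binary, directed, self-loops,
  about 20% of node-steps absent. The block matrix is trophic: a top
  group eating everything including itself (cannibalism), an
  intermediate-predator group eating the prey groups but not the top one,
  a common-prey group, and a peripheral group interacting little.
- recovery settings used by tests and the acceptance script: three groups,
  `β_within = 0.4`, `β_between = 0.05`, `Π` diagonal 0.9, `N = 100`,
  `T = 10` (Bernoulli); and a multinomial variant with `N = 150`, `T = 5`,
  `β_within = 0.9`, `β_between = 0.6` and a distinct category profile per
  block pair — sized so that each off-diagonal cell-step carries on the
  order of 1500 present edges, putting the multinomial sampling error
  (~0.013 per proportion) comfortably inside the ±0.05 recovery contract.

What the generator emulates: block structure, sticky Markov membership
dynamics, zero-inflation, arrivals/departures. What it does not: degree
heterogeneity within groups, reciprocity beyond what blocks induce,
overdispersed weights, measurement error in edge detection, informative
(non-random) absence. Recovery results on these simulations therefore
certify the estimator under the model's own assumptions, not robustness to
their violation on field data.

At the small food-web scale (26 nodes, 6 snapshots, absences) membership
recovery is genuinely partial — time-averaged ARI around 0.5–0.8 across
seeds — which is a sample-size limit, not an optimization failure; the
colony-scale weighted scenario is recovered essentially perfectly.

## Numerical choices

- All randomness flows through integer seeds; derived seeds come from
  `numpy.random.SeedSequence` and stay below 2^31.
- Log-emissions of exactly-zero probabilities are floored at −1e30 inside
  E-step messages (only reachable with user-supplied boundary parameters;
  fitted parameters are strictly positive), while
  `complete_log_likelihood` returns a true −inf for zero-probability
  configurations.
- Undirected expected block counts are accumulated over ordered pairs,
  symmetrized, and halved, so each unordered dyad carries unit weight;
  self-loops are added to the diagonal cells with unit weight.
- Degenerate summary cells (no observable dyad, or no present edge) report
  NaN proportions rather than 0 — absence of evidence is not evidence of
  absence of structure.
- Viterbi and modal-group ties break toward the lowest index; argmax-first
  semantics make this deterministic.

## Limitations

- The mean-field factorization underestimates posterior uncertainty across
  nodes; `τ` should be read as a point-estimate companion, not a calibrated
  posterior.
- No standard errors or confidence intervals are provided.
- Gaussian/Poisson emissions, degree correction, covariates, and
  continuous-time event streams are out of scope; ordinal categories via
  binning are the supported weighted pathway.
- ICL constants follow one standard construction; other conventions shift
  absolute values but rarely the argmax on well-separated data.
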