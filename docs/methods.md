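# Methods

## The model

`mmirtree` fits item response tree (IRTree) models to 5-point rating
data in which extreme and midpoint response styles (ERS, MRS) may
contaminate the measurement of a substantive trait θ. A rating
Y ∈ {1,…,5} is decomposed into up to three binary decisions:

| node | decision | observed when |
|------|----------|---------------|
| 0 | disagreement (1–2 vs 3–5) | always |
| 1 | neutrality (3 vs 4–5) | Y ≥ 3 |
| 2 | extremity (1 vs 2, or 5 vs 4) | Y ≠ 3 |

Each node follows a two-parameter logistic model. With person traits
(θ, η_ers, η_mrs) and item parameters (α_θj, α_ers,j, α_mrs,j, β_0j,
β_1j, β_2j, and a global proportionality constant ω):

    P(node0 = 1) = σ(−α_θ θ − α_mrs η_mrs − β_0)
    P(node1 = 1) = σ(−α_θ θ + α_mrs η_mrs − β_1)
    P(node2 = 1) = σ(±ω α_θ θ + α_ers η_ers − β_2)

where σ is the logistic function (a probit link is available for the
deterministic probability functions), and the sign of the θ term at the
extremity node is − on the disagreement branch and + on the agreement
branch. The category probability is the product of node probabilities
along the tree path; nodes not traversed contribute no factor.

The mixture extension posits four latent classes that share α_θ and ω
but differ in which response styles are *used*: ERS only, MRS only,
both ("2RS"), or neither ("0RS"). Unused styles have their loadings
fixed to exactly 0; RS loadings and the node difficulties β are
class-specific. Traits are multivariate normal with zero means and unit
variances (identification) and a freely estimated, class-invariant
correlation matrix R. Class membership z_p has a categorical(π) prior
with π ~ Dirichlet(1,1,1,1); the hierarchical prior keeps structurally
absent classes essentially empty.

Single-class benchmark trees (`ers`, `mrs`, `2rs`, `0rs`) are the same
model with all respondents held in one class; they use the bivariate /
trivariate / univariate trait distribution their structure requires.

## Priors

* loadings: N(0, 2) truncated to (0, ∞)
* node difficulties: N(0, 2)
* ω: U(0, 2)
* trait correlations: element-wise U(−1, 1) restricted to positive
  definite matrices
* class proportions: Dirichlet(1, 1, 1, 1)

"N(0, 2)" is read as variance 2; the variance is a `PriorSpec` field.

## Estimation

All logistic Bernoulli nodes are augmented with Pólya-Gamma variables
(drawn exactly by Devroye's alternating-series method, implemented with
numba), which makes every conditional conjugate:

* person traits — trivariate normal per respondent;
* loadings — truncated normals; difficulties — normals;
* ω — normal truncated to (0, 2) under its uniform prior;
* z — categorical, computed marginally over the PG variables (a valid
  partially collapsed ordering: z and π are updated first, then PG
  variables are redrawn from their full conditional);
* π — Dirichlet; R — per-element random-walk Metropolis with
  rejection of non-positive-definite proposals and step-size adaptation
  confined to burn-in.

### Multimodality and the moves that address it

The four-component mixture posterior is severely multimodal at
moderate n: because the node difficulties are class-specific, *any*
stable partition of respondents lets each class's difficulties adapt to
its current members, creating self-reinforcing local modes in which two
classes have traded places. Two mechanisms make these modes sticky
under one-site Gibbs: a respondent's RS traits are informed only while
they sit in a class that uses them, so the conditional z-update
compares classes using stale traits; and the conditional likelihood at
point traits systematically favours trait-active classes (fitted traits
absorb binomial noise), penalising the 0RS class.

The sampler therefore adds, on top of the Gibbs scan:

1. **Joint refresh moves** (every sweep): for each respondent, propose
   a fresh class from Categorical(π) together with one or both RS
   traits drawn from their population conditional given the remaining
   traits. The proposal densities cancel against the prior, so the
   Hastings ratio is a pure likelihood ratio. These moves let a
   respondent change class *together with* traits consistent with the
   destination class, which one-site updates cannot do.

2. **Informed initialization** (per chain; initialization only, the
   transition kernel is untouched): a short single-class 2RS pilot fit
   supplies approximate traits and pooled item parameters; a warm-start
   loop alternates membership sorting by *marginal* class likelihoods
   (RS traits integrated out by per-person importance sampling, which
   removes the point-trait overfit bias) with specialisation of the
   class difficulties. Because permuted arrangements remain locally
   stable even under that criterion, a greedy search over the six
   pairwise class swaps follows: each candidate arrangement is adapted
   by a short trial Gibbs run and scored by the response-style-
   marginalised mixture log-likelihood — a deterministic 2-D
   Gauss–Hermite quadrature over the RS traits given each person's
   substantive trait, evaluated at the trial's posterior-mean state,
   plus a Laplace-style parsimony correction for each populated class's
   free RS loadings (without it, hosting a no-RS population in a
   loading-bearing class with loadings pinned near zero scores the same
   as the structurally correct class). The conditional deviance cannot
   play this role (it rewards noise absorption by fitted RS traits),
   Monte-Carlo marginal estimates carry class-asymmetric bias, and
   single end-state draws carry tens of nats of parameter noise; the
   quadrature-at-the-mean score avoids all three. Swaps involving an
   essentially empty class skip the trial and are compared
   deterministically on the same mean state (a trial would only add
   noise to a purely structural comparison). The best-scoring
   arrangement's end state starts the chain.

Two further devices were implemented, measured to be counterproductive
on simulated data, and removed: a Metropolis move swapping two classes'
memberships and difficulties wholesale (it relabels classes faster than
the refresh moves can sort them during early burn-in), and a burn-in
stage with class-specific parameters tied (it delays specialisation
and then crystallises whatever arbitrary partition exists at release).

With these moves, chains started from independent initializations reach
the same (correct, on simulated data) mode: 8/8 independent chains on
an equal-proportions dataset with n = 500, J = 20 agreed, with
per-class hit rates 0.82–0.95, matching the conditional oracle that
classifies with the true parameters.

### Convergence

The Gelman–Rubin statistic is computed for every stored scalar (item
parameters, ω, correlations, π, deviance) across chains; the default
flag threshold is 1.05 (a stricter 1.01 is a setting). Non-convergence
is flagged on the results object, never fatal.

## Model selection

DIC = D̄ + p_V with D̄ the posterior mean deviance and p_V half the
posterior variance of the deviance (sample variance, n−1 denominator).
The deviance is conditional on the sampled memberships and person
parameters, i.e. −2 log of the mixture likelihood evaluated at each
draw, which matches what a generic Gibbs engine monitors; a
marginal-over-z deviance (`IRTreeResults.marginal_dic()`) is provided
as a non-default alternative. Smaller DIC wins; comparisons require
fits of the same data.

## Classification

Posterior class probabilities are the proportions of pooled
post-burn-in iterations assigning a respondent to each class; modal
assignment takes the argmax (ties to the lowest class index). Hit rate
is the per-class proportion of respondents whose modal class equals
their generating class (undefined, not zero, for empty classes);
certainty is the mean posterior probability of the assigned class among
a class's members.

## The synthetic-data generator

`simulate.generate_condition` reproduces a fixed design: traits from
MVN with unit variances and correlations cor(θ, η_ers) = .20,
cor(θ, η_mrs) = .00, cor(η_ers, η_mrs) = −.40 (the printed source for
this matrix is ambiguous; these values are a documented reading exposed
as a parameter); α_θ ~ U(0.75, 1.75); ω = 0.50; α_ers ~ U(0.75, 1.25)
and α_mrs ~ U(0.50, 0.75) independently per using class; all β ~
U(−2, 2) independently per class; deterministic contiguous block
assignment of persons to classes with sizes round(n·π_c) (remainder to
the last class); multinomial responses from the class-selected category
probabilities. Nine registered class-proportion conditions: equal
(.25⁴), four single-class-dominated (.70/.10/.10/.10 permutations), and
four non-mixture unit vectors. Item parameters, traits and memberships
are drawn once per condition; responses are redrawn per replication
(`redraw_persons=True` regenerates traits too, for robustness studies).

What the generator does *not* emulate: missing responses, careless or
acquiescent responding, item content effects, covariate-dependent
memberships, non-normal traits. A green test against this generator
therefore establishes internal consistency of model, sampler and
metrics under the stated population — not robustness to real-data
pathologies.

## Numerical choices

* Linear predictors are clipped to ±35 before the inverse link;
  probabilities are floored at 1e-300 inside logarithms.
* Structurally missing pseudo-items are a dedicated sentinel (−1) and
  never enter likelihood sums.
* Truncated-normal draws use `scipy.stats.truncnorm` with the seeded
  Generator; the PG sampler has its own numba-seeded stream, derived
  from the chain seed.
* Sub-seeds for every stage (items, traits, responses per replication,
  chains, pilot, trials) are derived from the master seed via
  `numpy.random.SeedSequence` over CRC32-hashed stage names, all below
  2^31, so each stage is independently reproducible.
* Empty mixture classes revert to their priors automatically through
  the conjugate updates (prior precision only).
* Block sizes in membership assignment round half up; the last class
  absorbs the remainder.

## Known limitations

* The sampler's trial-run arbitration resolves class-swapped modes by
  comparing mean deviances over short runs; on datasets where a swapped
  arrangement is nearly equally supported (small n, weak RS loadings)
  individual chains can still settle in different arrangements — this
  surfaces as large R̂ on class-specific parameters and should be
  treated as non-convergence, exactly as flagged.
* Estimation assumes listwise-complete 5-point data; other scale
  lengths and alternative tree topologies are out of scope.
* The probit link is available for the deterministic probability
  functions only; the sampler is logistic (Pólya-Gamma) throughout.
* At n ≈ 500 the class-specific RS loadings are weakly determined
  (posterior SDs comparable to the spread of their generating
  distributions); their posterior means recover the *level* well
  (small bias/RMSE) but item-rank correlations with truth are
  intrinsically modest at that sample size.
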