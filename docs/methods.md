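# Methods

## Model

`catfusion` models a categorical response series conditionally on a window
of lagged categorical predictors,

    p(y_t | z_t),   z_t = (y_{t-1}, .., y_{t-Dy}, theta_{t-1}, .., theta_{t-Dtheta}),

treating the conditional law as a (q+1)-order probability tensor over the
category combinations. The tensor is represented by a nonnegative
higher-order-SVD factorization

    p(y_t = c | z_t) = sum_{s_1..s_q} lambda_{s_1..s_q}(c)
                       prod_j omega^{(j)}[z_{j,t}, s_j],

where each mode matrix `omega^(j)` (C_j x k_j, rows on the simplex) softly
clusters the levels of predictor j into `k_j <= C_j` latent populations,
and the core holds one distribution over response categories per latent
string (s_1..s_q). Equivalently, latent allocation variables
`x_{j,t} ~ Mult(omega^(j)(z_{j,t}))` select a string and
`y_t ~ Mult(lambda-tilde_{x_t})`. Because the product over strings of the
k_j's can still be large, the core's columns are clustered
nonparametrically: a Pitman-Yor / stick-breaking prior with truncation L
assigns each string to one of L atoms (map `phi`), each atom carrying a
Dirichlet-distributed response distribution `lambda_l`.

Two distinct quantities drive inference about relevance:

* `k_j` — the dimension of predictor j's mixture (a model parameter), and
* `ktilde_j` — the number of clusters its allocations actually occupy.

The conditional tensor is constant in `z_j` exactly when `ktilde_j = 1`,
so predictor relevance — and Granger causality, by grouping all of a
source's lag columns — is read off the posterior of `ktilde_j`.

## Priors and default hyperparameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| a, b | Pitman-Yor strength/discount | 1, 0 | Dirichlet-process special case; sufficient clustering ability for these problem sizes |
| alpha | Dirichlet pseudo-count of the atoms | 1 | weak smoothing of response distributions |
| beta_j | Dirichlet pseudo-count of mode rows | 1/C_j | keeps the implied prior mass per mode row constant across cardinalities |
| mu_j | exponential penalty on k_j, p(k_j=k) ∝ exp(-mu_j k) | 1 | mild parsimony pressure; 0 is uniform; can increase with lag depth to encode fading memory |
| L | stick-breaking truncation | min(32, prod_j C_j) | prod_j C_j atoms suffice to represent any tensor exactly; 32 caps the cost with negligible truncation error at these data sizes |

Iteration schedule default: 30,000 sweeps with 20,000 burn-in, keeping
every 5th state (2,000 retained samples). This is the package's scaled
standard run for the desk-scale problems it ships with; heavier data can
use longer schedules via `fit(n_iter=..., burn_in=...)`.

## Posterior computation

A partially collapsed Gibbs sampler alternates:

1. `phi` for every latent string from its multinomial conditional
   (proportional to `pi_l * prod_c lambda_l(c)^{n_s(c)}`), in log space;
2. truncated sticks `V_l ~ Beta(1-b+n_l, a+lb+sum_{m>l} n_m)`, `V_L = 1`;
3. atoms `lambda_l ~ Dir(alpha + n_l(c))`;
4. mode rows `omega^(j)(c) ~ Dir(beta_j + n_{j,c}(s))`;
5. allocations `x_{j,t}` column-blocked (entries of a column are
   conditionally independent across t given the parameters, so each column
   is one vectorized categorical draw);
6. dimensions `k_j` with `omega^(j)` integrated out analytically — the
   exact Dirichlet-multinomial marginal
   `p(k | x_j, z_j) ∝ exp(-mu_j k) prod_c Gamma(k beta_j)/Gamma(k beta_j + n_{j,c})`
   on the support {max occupied label + 1, .., C_j}. Collapsing removes
   the need for trans-dimensional (reversible-jump) moves.

Design choices that were genuinely open:

* **When a new k_j takes effect.** The dimension draw happens last in the
  sweep and `omega` is not resized there; the new dimension materializes at
  the start of the next sweep (phi reallocated; omega redrawn at its own
  step). Every post-sweep state is therefore a fully consistent factor
  model, which is what gets snapshotted and scored.
* **Initialization.** `k_j = C_j`, allocations uniform, parameters from
  their priors. Starting at the largest dimension lets the penalty prune
  rather than grow, which mixes better than starting collapsed.
* **Log-likelihood trace.** `sum_t log p(y_t|z_t)` is evaluated on the
  post-sweep model via a dense conditional table whenever
  `prod_j C_j * C0 <= 1e6`, else via unique predictor rows.
* **Numerics.** All categorical draws use Gumbel-max or inverse-CDF on
  log-space weights with max subtraction; Gamma-ratio terms go through
  `gammaln`; probabilities are floored at 1e-300 before logs. Dirichlet
  draws are normalized Gammas. One `numpy.random.Generator` seeded once
  drives every draw in a fixed order, so runs are bit-reproducible.

### Mixing caveat

The indicator `ktilde_j = 1` changes only when all T allocations of a
column coalesce into one label, a rare-event transition. Its posterior
fraction therefore carries substantial Monte-Carlo error at short
schedules, and Bayes factors built from it vary noticeably between chains
(roughly a factor of two at the default schedule on the shipped coupled
example). `GrangerTestResult` exposes the raw sample fractions and the
ensemble size so this error can be judged; pooling retained samples from a
few independent chains (as `scripts/acceptance.py` does) reduces it.

## Causality testing

For a predictor set Lambda, `H0: ktilde_j = 1 for all j in Lambda` versus
its complement. Posterior probabilities are retained-sample fractions; the
prior follows the closed form

    p(ktilde_j = 1) = sum_{k=1}^{C_j} p(k_j = k) * k *
                      prod_c (beta_j)^(n_{j,c}) / (k beta_j)^(n_{j,c}),

with rising factorials `a^(n) = Gamma(a+n)/Gamma(a)`, independent across
j. BF10 is the posterior-to-prior odds ratio, `+Infinity` when H0 never
occurs among retained samples (reported with the raw fractions), 0 when H1
never occurs. Decision thresholds: 20 (strong), 150 (very strong).
Both the collapsed k-conditional and this prior expression are verified
in the test suite against brute-force Monte-Carlo marginalization and
forward simulation, since their printed forms are easy to get wrong.

## Sequential classification

Each class regime is a fitted posterior ensemble. Test data are scored by
the posterior predictive `p(y_t|z_t) ≈ (1/N) sum_n p_n(y_t|z_t)` (averaged
in probability space), accumulated per step in log space; class posteriors
follow by Bayes' rule with user priors (uniform default). Per-sample
conditional tables are precomputed and averaged into one dense lookup
table over all `prod_j C_j` predictor configurations when that table has
at most 1e6 entries (a ternary-alphabet, ten-lag model is ~1.2e5 rows and
comfortably fits); otherwise evaluation is on demand. The factorized model
assigns valid probabilities to predictor configurations never seen in
training, so no special smoothing is needed. The two-class case reduces to
a likelihood-ratio test with threshold theta (boundary decided toward
class 1); sweeping theta over the observed statistics traces the ROC
(pD vs pF), whose convention matches the decision rule ">= theta".

## Synthetic generators

`simulate_coupled_example` draws two coupled binary chains: y from a fixed
8-row table on its own lags (1, 3, 4), theta from a fixed 16-row table on
(y_{t-1}, y_{t-3}, theta_{t-1}, theta_{t-2}). By construction y
Granger-causes theta and not conversely, with every conditional
probability known exactly — the complete ground truth for structure
recovery, causality and transition-probability tests. The first max-lag
symbols are iid uniform and a 100-step burn-in is discarded (the chains'
memory is 4 steps, so the prefix is far past mixing).
`simulate_generic` builds arbitrary sparse-lag networks with
Dirichlet-random tables and returns the ground truth object.

What the generators do *not* emulate: real sensor data's non-stationarity,
measurement noise before quantization, long-range dependence, and regime
drift. Passing tests demonstrate correct inference *under the model's own
assumptions* (stationary finite-memory categorical dynamics); they do not
certify behavior on raw physical measurements, which additionally depend
on the preprocessing choices below.

## Preprocessing

Maximum-entropy partitioning is equal-frequency quantization: interior bin
edges at the empirical i/n quantiles, right-closed bins, ties to the lower
bin; it maximizes empirical symbol entropy among interval partitions of
the same size and is monotone. The AMI downsampling lag is the first
local minimum of a histogram plug-in mutual information (ceil(sqrt(n))
equal-width bins; I(0) taken as the marginal entropy; argmin fallback with
a warning when no interior minimum exists). The plug-in estimator has a
positive bias of order (bins-1)^2/2n, which cancels in the *location* of
the minimum but makes the MI values themselves unsuitable as absolute
dependence measures. Stationarity transforms: percent change (errors on
zero denominators) and first difference, both shortening the series by 1.

## Problem sizes used in the shipped checks

The packaged end-to-end checks run the coupled example at its study scale
(1005 collected, 1000 training rows after embedding; ten binary lag
predictors; L = 20; 30k-sweep scaled schedule), generator fidelity at
T = 1e6, the prior and collapsed-conditional oracles at 1e6 and 4e5
Monte-Carlo draws, and the classifier comparison with 1000-step training
series and 200 test instances per class at test lengths 5 and 9. These
sizes keep a full run in minutes on one CPU while leaving the binomial /
batch-means error bars a decade smaller than the effects being checked.

## Known limitations

* Slow mixing of the cluster-collapse indicator (above): Bayes factors
  near decision thresholds deserve multiple chains.
* The stick-breaking truncation is not adapted automatically; extremely
  large `prod_j k_j` with small L would bias the clustering prior.
* Posterior ensembles are stored densely; hundreds of thousands of
  retained samples with many predictors will be memory-heavy.
* The classifier assumes every class model shares the response and
  predictor alphabets; heterogeneous alphabets must be reconciled during
  preprocessing.
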