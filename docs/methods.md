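# Methods

## The inference problem

A multi-subject behavioral study yields trial-level data for N subjects
and a space of K candidate computational models (here: learning models of
choice).  Two questions are interdependent: *which model* generated each
subject's data, and *what parameters* each subject has under that model.
Hierarchical parameter estimation conditions individual fits on group
statistics but classically assumes one model holds for everyone (model
identity as a fixed effect); random-effects model selection allows the
model to vary by subject but has classically been fed by non-hierarchical
fits.  The HBI framework implemented here performs both inferences
jointly.

## Generative model

For subject n with data x_n, a 1-of-K indicator z_n selects the
generating model; its probabilities m follow a Dirichlet prior with
concentration alpha0.  Under model k the unconstrained parameter vector
h_kn (dimension D_k) is Gaussian with mean mu_k and diagonal precision
T_k = diag(tau_k).  The group parameters themselves carry a conjugate
Gaussian-Gamma prior: mu_k ~ N(a0, (b T_k)^-1), tau_ki ~ Gamma(v, s).
All model likelihoods p(x_n | h_kn, M_k) are parameterized on the
unconstrained scale; sigmoid / exponential transforms map to learning
rates (0,1) and positive parameters (0,inf) inside the likelihood, so the
Gaussian population assumption lives on the scale where it is natural.

## Variational algorithm

The posterior is approximated mean-field as q(H, Z) q(mu, tau, m), with
q(h_kn) a Laplace (quadratic) approximation around the subject-level mode
under the current expected group prior.  Each iteration:

1. **Summary statistics.**  Responsibility-weighted counts
   Nbar_k = sum_n r_kn, means theta-bar_k and deviances V-bar_k (which
   include the subject-level posterior covariances A_kn^-1).
2. **Group update.**  Conjugate updates: a_k is the responsibility-
   weighted average of subject modes shrunk toward a0 with weight b;
   beta_k = b + Nbar_k; nu_k = v + Nbar_k/2; sigma_k accumulates the
   weighted scatter; alpha_k = alpha0 + Nbar_k.
3. **Subject update.**  Laplace refit of every subject x model under the
   prior N(a_k, (nu_k diag(sigma_k)^-1)^-1).
4. **Responsibility update.**  log rho_kn adds to the subject-level
   Laplace evidence a digamma correction for group-parameter uncertainty
   and the expected log frequency E[log m_k]; r_kn is the softmax over
   models (log-sum-exp, exact ties split evenly).

Convergence uses the normalized summary statistic
theta-hat = theta-bar / sqrt(diag(V-bar)): the mean squared change d-hat
across consecutive iterations must fall strictly below 0.01, with a cap
of 50 iterations (flagged separately when hit).

**Lower bound.**  The variational bound is assembled as
L = sum_n log sum_k rho_kn − sum_k KL[q(mu_k,tau_k) || p(mu_k,tau_k)]
− KL[Dir(alpha) || Dir(alpha0)].  The first term follows from the
identity that log rho_kn equals the full per-subject expected-log-joint
plus entropy contribution under the Laplace approximation; the identity
and the assembled bound are verified in the test suite against an
independent term-by-term analytic assembly on a conjugate Gaussian toy
(agreement to 1e-6), where the bound is also confirmed monotone.

**Model selection.**  Exceedance probabilities phi_k are computed from
Dir(alpha) — exactly via the regularized incomplete Beta function for
K = 2, otherwise by 10^6 Dirichlet Monte-Carlo draws with a fixed seed.
Protected exceedance probabilities shrink phi toward uniform by
P0 = 1/(1 + exp(L − L0)), where L0 comes from re-running the algorithm
under the null of equal frequencies.  The null run realizes
alpha0 → inf by hard-pinning E[log m_k] = log(1/K) and dropping the
Dirichlet KL term (prior and posterior over frequencies coincide in that
limit); a large finite alpha0 would approximate the same thing less
crisply.

**Group-level test.**  Marginalizing tau from q(mu_k, tau_k) gives a
Student marginal for each group mean: dof n_k = 2 nu_k (= 1 + Nbar_k
with the default v = 1/2), empirical deviance s_ki^2 = 2 sigma_ki /
beta_k, hierarchical error s_ki / sqrt(n_k).  The HBI t-test reports
t = (a_ki − null) / hierarchical error with two-sided Student tails and
credible intervals from Student quantiles.  The predictive distribution
for a new subject is Student with center a_k and scale diag(s_k) (using
the b = 2v convention, exact under the defaults b = 1, v = 1/2); new
subjects are fit by MAP under that heavy-tailed prior.

## Subject-level optimization

MAP optimization is quasi-Newton (L-BFGS-B) with numerical gradients,
gradient tolerance 1e-6.  Cold fits start from the prior mean plus 2
random restarts drawn from the prior (learning-model likelihoods can be
multimodal); within HBI/HPE iterations each subject is warm-started from
its previous mode with no restarts, which is both faster and more stable
because the objective changes little between iterations.  Restart seeds
derive deterministically from (master seed, model, subject, iteration).
The Hessian is computed by central finite differences; non-positive-
definite Hessians are symmetrized and eigenvalue-floored at 1e-6 (flagged
on the result).  The Laplace log evidence is
log f + (D/2) log 2pi − (1/2) log |A|.

## Priors, initialization and guards

Defaults a0 = 0, b = 1, v = 1/2 (so the priors count as one effective
sample), s = 0.01 (small, so posterior deviances are data-driven; this
also makes a model that loses all responsibility collapse its subject
posteriors to the prior mean with small variance), alpha0 = 1 (uniform
prior over frequencies).  Initialization fits every model to every
subject under a weakly-informative N(0, 6.25 I) prior on the
unconstrained scale — the same prior the non-hierarchical baseline uses —
with responsibilities starting uniform.  Numerical guards: when
Nbar_k < 1e-6 the summary statistics revert to the prior location (the
weighted mean is undefined); V-bar is symmetrized and PSD-floored at
1e-10; responsibilities always via log-sum-exp.

## Baselines

**NHI** fits each subject independently under a fixed Gaussian prior
(mean 0, variance 6.25 per unconstrained dimension) and approximates
subject-level evidence by the Laplace formula.  The N x K evidence matrix
feeds variational random-effects model selection (Dirichlet-multinomial
updates); its protected exceedance uses the free-energy comparison
against the uniform-frequency null of the same evidence matrix.

**HPE** is empirical-Bayes EM per model: E-step Laplace fits under
N(mu, V) (V diagonal, floored at 1e-6), M-step mu = mean of subject
modes, V = mean scatter plus posterior variances; convergence at
relative change < 1e-4 or 50 iterations.  Models are compared as fixed
effects by summed subject evidence minus an iBIC-style penalty
(1/2) * (2 D_k) * log(total trials) for the mean and variance
hyperparameters; a "null fit" variant can pin selected dimensions'
(mean, variance), which then do not count as free hyperparameters.

## Cognitive model library

All models use a softmax choice rule with inverse temperature
beta = exp(raw).  Learned values start at 0.5, the midpoint of the {0,1}
outcome range; ties in greedy comparisons break toward the lower index.

- **RL**: Q <- Q + alpha (r − Q), alpha = sigmoid(raw).
- **Dual-alpha RL**: alpha+ applied when the prediction error is
  positive, alpha− otherwise; nests RL at alpha+ = alpha−.
- **Kalman filter**: per-option posterior mean/variance with gain
  k_t = v_t/(v_t + omega); the effective learning rate decays over
  trials.  Parameterization: initial mean 0, prior variance 1, no
  process-noise drift, one free observation noise omega = exp(raw) —
  the minimal single-extra-parameter variant consistent with a
  "gradually decreasing learning rate".
- **Actor-critic**: TD critic V and actor preferences sharing one
  learning rate (minimal two-parameter variant comparable to RL);
  softmax over preferences.
- **Last-outcome**: the chosen option's value equals the most recent
  outcome (an RL model with learning rate pinned at 1), one free
  decision-noise parameter; serves as the simple "soak-up" model for
  non-learning outliers.
- **Perseveration variants** add a bonus p (identity transform) to the
  previously chosen action's utility.
- **Go/no-go biased RL** keeps Q values per (stimulus, action) and adds
  a Pavlovian bias +b to the "go" utility for appetitive cues and −b
  for aversive cues; nests the plain go/no-go RL at b = 0.
- **Two-step models**: model-free SARSA with eligibility lambda = 1
  (reward updates both stages; the single-alpha, single-beta reduction
  of the standard formulation, with the repetition bonus omitted),
  model-based planning through the known 0.7/0.3 transition matrix, and
  the hybrid mixing stage-1 values with weight w = sigmoid(raw) — which
  nests model-free at w = 0 and model-based at w = 1.

## Tasks and synthetic groups

Reward probabilities follow Gaussian random walks (step sd 0.1) reflected
at [0.2, 0.8], binarized per trial and option; T = 100 trials by default.
The go/no-go task interleaves appetitive/aversive cues at random with
outcome values independent of cue valence.  The two-step task uses fixed
0.7/0.3 common/rare transitions and four drifting second-stage reward
probabilities.

Group generation draws each subject's unconstrained parameters from
per-parameter normal distributions, then simulates the agent on a freshly
generated task.  Default generating conditions (documented in
`DEFAULT_GENERATING_DISTS`; all sds 0.5 on the raw scale): inverse
temperature centered on 3; nested scenario RL learning rate centered on
0.1 with dual-alpha rates 0.8/0.4 (the plain-RL rate deliberately below
both, which is what makes unweighted pooling biased); same-complexity
scenario RL rate centered on 0.3 (mid-range — that scenario carries no
ordering constraint and a 0.1 learner at T = 100 is nearly a
non-learner); Kalman omega centered on 1.  Evidence-space outliers are
realized by duplicating a designated subject's data; parameter-space
outliers by near-zero decision noise (beta ~ 0.05), optionally with
near-zero learning rate (~0.02).

The skewed-null studies draw the bias parameter from a distribution with
prescribed (mean, variance, skewness, kurtosis) = (0, 1, −0.5, 3),
sampled by a cubic polynomial transform of a standard normal whose
coefficients are solved to match the standardized moments.

**What the generator does not emulate:** real within-subject
non-stationarities (attention lapses, strategy switches), reaction times,
and model misspecification — every synthetic subject is exactly one model
of the space.  Passing recovery tests therefore demonstrates correctness
of the inference machinery under the stated generative assumptions, not
robustness to violations of them (except where outliers are injected
explicitly).

## Problem sizes and reproducibility

The shipped benchmark studies run at desk scale: 10 replications for the
frequency/attribution scenarios and 20 for the baseline-failure rates
(the original studies used 20–1000); the t-test-on-true-parameters
studies run at full scale (2000 groups).  The test suite reruns the same
studies at 3–6 replications with tolerances widened for the extra
Monte-Carlo noise.  All randomness — task walks, parameter draws, agent
choices, optimizer restarts, Dirichlet Monte-Carlo — derives from
explicit integer seeds, so every reported number is exactly
reproducible.

## Known limitations

- Group precisions are diagonal (as in the underlying method);
  correlated parameters are not modeled.
- The subject posterior is a single Gaussian (Laplace); strongly
  multimodal subject likelihoods are summarized by one mode.
- Laplace evidence is an O(1/T) approximation; with very few trials per
  subject the responsibilities inherit its bias.
- Attribution between weakly discriminable models is information-limited:
  when two models' best fits differ by ~1 nat per subject, no method can
  attribute reliably, and measured attribution rates track that limit
  rather than the algorithm's ceiling.
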