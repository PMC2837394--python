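# Methods

## The generative model and its inversion

Let L_nm = log p(Y_n | m) be the log evidence of model m for subject n,
supplied by upstream model fitting. The package performs inference at the
group level only; it never touches raw data or time series.

**FFX.** Under the fixed-effects assumption a single model generated every
subject's data. Conditional independence over subjects gives
log p(Y | m) = Σ_n L_nm, and Bayes' rule with a model prior p(m) yields the
posterior over models. All arithmetic stays in natural-log space, with
normalisation by log-sum-exp: group log-evidence differences of order 10²–10⁴
are routine and would overflow or underflow any direct exponentiation. The
reported family "log posterior" column is shifted so the best family sits at
0, since raw values are uninformative offsets.

**RFX.** Under the random-effects assumption each subject's generating model
is a multinomial draw from population frequencies r ~ Dirichlet(α₀). The
Gibbs sweep is:

1. g_nm ∝ exp(L_nm) r_m, normalised per subject. Computed by subtracting the
   per-row maximum of (L_nm + log r_m) before exponentiation.
2. a_n ~ Multinomial(1, g_n) for each subject (inverse-CDF on the row).
3. β_m = Σ_n a_nm.
4. r ~ Dirichlet(α₀ + β).

The chain is initialised with a draw from the prior. Defaults: 30,000 total
sweeps, the first 10,000 discarded; both configurable. No thinning is
applied; autocorrelation is absorbed into batch-means Monte-Carlo standard
errors (30 contiguous batches) reported alongside every expectation. The g
matrix returned to the user is the average of the per-sweep weights over
retained sweeps; it is the input to RFX model averaging.

Exceedance probabilities are the fraction of retained draws in which a
component is the strict maximum. Ties at the maximum (possible only for
degenerate duplicated draws; measure zero for continuous chains) count for
no component, so the vector can sum to slightly below one only in
pathological inputs.

## Priors

- Model-level default: α₀ = 1 per model (one prior observation per model).
- Family-uniform: α_m = 1/N_k for every model in family k, so each family's
  total prior count is one and the aggregated family prior is
  Dirichlet(1, …, 1) regardless of family sizes. This is the unique
  count assignment with that property and is the RFX counterpart of the FFX
  family-uniform prior p(m) = 1/(K·N_k). It also acts as a dilution prior:
  prior mass inside a large family of similar models is shared out rather
  than accumulated.

Small-shape Dirichlet sampling (shapes like 1/64) is done via the boosting
identity Gamma(a) = Gamma(a+1)·U^(1/a) evaluated entirely in log space, then
normalised after subtracting the maximum log-coordinate; coordinates are
floored at the smallest positive normal before normalisation. This prevents
the exact zeros that naive gamma sampling produces at small shapes, which
would otherwise break the log r step.

## The variational alternative

`vb_update` iterates responsibilities
g_nm ∝ exp(L_nm + ψ(α_m) − ψ(Σ α)) and counts α = α₀ + Σ_n g_n to a fixed
point (tolerance 1e-6 on the counts, 1000 iterations max, warning on
non-convergence with the best iterate returned). It is fast and accurate for
α₀ ≥ 1, and the package verifies it against Gibbs in that regime. For
α₀ < 1 — precisely the family-uniform setting — the approximation is known
to be biased, so every such call emits a warning recommending Gibbs. The VB
free energy itself is not computed; the method is offered as a convenience,
not as the reference path.

## Family-level posteriors

FFX: family posterior = Σ member model posteriors (computed by log-sum-exp
over log model posteriors); the alternative probability 1 − p(k|Y) is
reported because family posteriors are often numerically
indistinguishable from 1. RFX: each retained draw is aggregated,
s_k = Σ_{m∈k} r_m, and expectations/exceedances are computed from the
aggregated draws, preserving their full posterior dependence.

## Bayesian model averaging

Within a family, the marginal posterior of the parameters for subject n is
the mixture Σ_m q(θ|Y_n,m) p(m|Y_n) over family members. Because models
exclude parameters a priori, the mixture contains delta functions at zero
whose mass equals the posterior weight of the excluding models. The density
is represented by samples:

- RFX: per sample, each subject draws a model from its own windowed,
  renormalised g row — the Occam's window is applied per subject, so
  subjects can retain different model sets.
- FFX: per sample, one model index is drawn from the windowed group
  posterior and applied to all subjects, the faithful reading of the FFX
  assumption that a single model generated all data (contrast with the
  per-subject draws of RFX).
- Each subject then draws θ from the chosen subject/model Gaussian on its
  free parameters (zeros elsewhere), and the group-average sample is the
  mean over subjects. Within-subject densities skip the averaging step and
  are exportable per subject for downstream group tests.

Zero mass is accounted analytically from the realised model draws (a
parameter is exactly zero in a group sample iff no subject's drawn model
freed it), never by comparing floating-point samples to zero.

Gaussian draws use a symmetric eigendecomposition square root; eigenvalues
below 1e-10 of the largest are clamped to zero because variational
covariances can be numerically indefinite, while genuinely negative spectra
are rejected. Occam's window keeps model j iff p_j/max(p) strictly exceeds
π_occ, with the (tied) maximal models always kept — so π_occ = 1 keeps
exactly the argmax set and π_occ → 0 reproduces full-family averaging.
Default π_occ = 1/20, matching the conventional "strong evidence" posterior
odds boundary; default sample count S = 10,000. Both are configurable.

## Synthetic data

`simulate_group_evidence` mirrors the Dirichlet-multinomial generative
model: subjects are assigned generating models (from given frequencies or an
explicit list), the generating model's log evidence is raised by a margin
above a common zero baseline, and optional i.i.d. Gaussian noise is added
cell-wise. Only within-subject evidence differences matter to any posterior
here, so the baseline is fixed at zero without loss of generality. A margin
of 10 log units makes a preference decisive (posterior weight > 0.9999),
pinning the Gibbs assignment step so the conjugate
Dirichlet(α₀ + counts) posterior is an exact oracle — that is the basis of
the sampler's correctness tests. What the generator does **not** emulate:
correlated evidences across models within a subject, heavy-tailed evidence
noise, subject-level covariates, or any misspecification of the upstream
evidence approximation. Passing tests therefore certify the inference
machinery given evidences, not the quality of evidences from real data.

`worked_example_comparison_set` builds the 17-subject two-vs-three-model
pair (decisive counts 7/10, then 7/6/4). The third model is appended without
touching the first two evidence columns: for the four switching subjects it
beats model 2 by the same decisive margin. This makes the FFX
ranking-invariance property hold exactly while reproducing the RFX rank
flip.

`simulate_parameter_posteriors` builds a complete subject × model grid of
Gaussian posteriors over a model space, with free-parameter masks taken from
each model's input/modulation patterns, means = true effect + optional
jitter, and diagonal covariance post_sd². Parameter names follow
`B:src->dst:mod` / `C:region:input`.

## Test problem sizes and numerical choices

Sampler-based checks use 12,000–25,000 sweeps with 2,000–5,000 burn-in and
groups of 10–60 subjects; these sizes give Monte-Carlo standard errors an
order of magnitude below the tolerances being asserted while keeping the
whole suite under half a minute. Stochastic assertions compare against
closed-form oracles at 3 Monte-Carlo standard errors (batch means), or at
fixed absolute tolerances where an oracle bound is exact. Frequency-recovery
checks average over 10 seeds because a single 60-subject draw carries
binomial sampling noise (sd ≈ 0.056 at p = 0.25) comparable to the ±0.05
recovery tolerance; the seed-averaged estimate isolates the inference error
from the sampling noise of the synthetic population itself.

## Known limitations

- Evidence approximations are trusted as given; no propagation of their
  error.
- The VB route reports exceedances by sampling its fitted Dirichlet, which
  ignores the factorisation error of the approximation itself.
- BMA assumes the per-model posteriors are Gaussian (mixture components are
  Gaussian/delta only); non-Gaussian upstream posteriors would need their
  own draw method.
- Family partitions must be hard; soft/overlapping family membership is out
  of scope.
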