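# Methods

`crisishmm` implements a multilevel (mixed-effects) hidden Markov model for
multivariate experience-sampling (ESM) panels, together with a synthetic-data
generator that emulates the crisis-monitoring study design the package is
built around: 26 patients answering a five-item symptom questionnaire
(self-control, negative affect, contact avoidance, contact desire, suicidal
ideation; each on a 1–100 scale) three times a day until 60 occasions are
reached, with whole occasions missing when a beep goes unanswered.

## Model

For patient *i* at occasion *t*, a latent crisis state
S_it ∈ {1, …, m} follows a first-order Markov chain with patient-specific
transition matrix Γ_i. Given the state, the K = 5 observed channels are
conditionally independent Gaussians:

    y_ikt | S_it = s  ~  N(μ_iks, σ_ks²)

* **Emission means** carry patient random effects:
  μ_iks ~ N(μ_ks, τ_ks²), with group means μ_ks and between-patient SDs τ_ks
  per state × channel.
* **Emission SDs** σ_ks are shared across patients (state × channel specific).
  This is the parsimonious variance structure: random effects enter the means
  and the dynamics, not the residual noise.
* **Transitions** are parametrized as multinomial logits with the row's own
  staying probability as the reference category. Cell (r, j), j ≠ r, of
  patient *i* is α_irj ~ N(ᾱ_rj, ω_rj²): Gaussian random effects on the
  log-odds of each switch against staying. The diagonal reference makes
  state relabeling act cell-wise on the logits and their variance components,
  which keeps the severity-ordering relabeling exact for every parameter.
  Random-effect covariance is diagonal (independent cells).
* **Initial state**: the stationary distribution of Γ_i, recomputed from the
  current draw. The generator's default initial distribution is likewise the
  stationary distribution of the group matrix, which avoids start-up
  artifacts in simulated chains.
* **Missing data**: whole-occasion missingness is treated as missing at
  random; missing channels contribute nothing to the emission density, and
  missing occasions keep their place in the chain (transition steps still
  apply). The chain is never split at gaps, consistent with the equal-spacing
  assumption of the design (the overnight interval is not modelled).

## Priors

Weakly informative and scaled to the 1–100 item range:
μ_ks ~ N(50, 25²); σ_ks, τ_ks ~ half-Cauchy(0, 10); ᾱ_rj ~ N(0, 5²);
ω_rj ~ half-Cauchy(0, 1). Half-Cauchy scales are handled by the
inverse-gamma auxiliary-variable representation (σ² ~ IG(½, 1/a),
a ~ IG(½, 1/A²)), which makes every variance update a conjugate Gibbs draw.

## Estimation

Metropolis-within-Gibbs, per iteration:

1. **State paths** by forward-filtering backward-sampling (FFBS), one exact
   joint draw per patient. The forward pass uses normalized (scaled)
   variables with accumulated log scalers, so the likelihood and FFBS share
   one filtering pass and stay exact at T = 60 and far beyond.
2. **Subject emission means**: conjugate Gaussian updates given the sampled
   states, shrinking toward the group means.
3. **Emission variances** σ², then **group means/τ**, **ᾱ/ω**: conjugate
   draws as above.
4. **Subject transition logits**: cell-wise Gaussian random-walk Metropolis
   against the multinomial transition counts, the stationary-initial-state
   term (recomputed from the full matrix, keeping rows exactly coupled), and
   the random-effect prior. Proposal SDs adapt by Robbins–Monro toward 0.35
   acceptance during burn-in and are frozen afterwards to preserve detailed
   balance.

Hierarchies over sparse per-patient information mix slowly in the centered
parametrization (the classic funnel), and patient-level state assignment can
be multimodal. Three additional move families address this; each is a valid
MCMC kernel for the same posterior:

* **ASIS interweaving for transitions**: a joint Metropolis shift of a group
  logit row together with every subject's row (offsets fixed), and a
  log-scale rescaling of ω with the standardized offsets fixed. The subject
  likelihoods then inform ᾱ and ω directly.
* **ASIS interweaving for emissions**: an exact non-centered Gibbs draw of
  the group means with subject offsets fixed, and a log-scale Metropolis
  rescaling of τ using per-(patient, state, channel) sufficient statistics.
* **Collapsed patient label swaps**: for each patient, a proposed exchange of
  an adjacent pair of states in that patient's parameters, accepted with the
  exact path-marginalized likelihood. Borderline patients can flip which
  group-level state explains their data, which otherwise traps chains in
  different assignment modes.

The transition blocks run twice per scan; all compiled inner loops
(forward/FFBS/Viterbi recursions, the Metropolis sweeps) are numba kernels
fed with pre-generated variates, so a run is replayable bit-exactly from
`(seed, chain)` — chain c uses the derived seed (seed, c).

Initialization: group emission means start at the k-means centroids of the
fully observed occasions (best of five restarts, per-chain jitter of SD 2,
rows sorted by the ordering channel), falling back to pooled per-channel
quantiles when fewer than 10·m complete occasions exist. Per-channel
quantile rows are ascending in every channel, which is anti-ordered for
channels that decrease with severity and was observed to trap the sampler in
a merged-state mode; the k-means start removes that failure. Each patient's
subject means start at their nearest-centroid within-assignment means shrunk
toward the group centroids (10 pseudo-occasions), so every chain's patients
begin near the same data-determined configuration while the chains still
differ through the jittered group start.

Label switching is resolved after sampling: every post-burn-in draw is
permuted so the group negative-affect means ascend with the state index
(severity order), ties broken by self-control descending, then by index.
The same permutation is applied to all parameters and sampled paths.

## Diagnostics and reporting

* **AIC**: −2·Σ_i loglik(y_i | group posterior medians) + 2·(2mK + m(m−1)).
  The likelihood uses sample-level point parameters and the penalty counts
  only sample-level free parameters; the formula is recorded in every export.
  Model selection fits a contiguous range of m (2–5 by default) and takes
  the minimum, ties to the smaller m.
* **Convergence**: classic (split-free) Gelman–Rubin PSRF per scalar
  group-level parameter, floored at 1 (the pooled-variance estimate
  understates the within-chain variance by (n−1)/n, so exact copies would
  otherwise fall below 1); parameters at or above 1.20 are flagged.
* **Posterior predictive checks** replicate the panel from thinned
  subject-level draws, reusing the observed missingness mask, and compare
  pooled per-channel means and SDs with 95% predictive intervals.
* **Pseudo-residuals** are one-step-ahead probability integral transforms:
  each observed value is evaluated under its forecast mixture (state-
  prediction-weighted Gaussian CDF) and mapped through the standard normal
  quantile; summaries are per patient × channel mean, SD and lag-1
  autocorrelation. PITs at exactly 0/1 are clamped and counted.
* **Dynamics reporting**: staying probabilities (the Γ diagonal), the
  "high" classification at the inclusive ≥ 0.70 threshold, normalized
  switching probabilities (off-diagonal mass divided by 1 − staying;
  all-zero row when staying = 1), and incidence from decoded occupancy
  (stationary-distribution incidence available as a labelled alternative).
  Patient-level dynamics use subject posterior medians; unvisited states in
  a patient's decoded sequence are flagged.
* **Decoding**: Viterbi at subject-level posterior medians, ties toward the
  lower state index; missing occasions decode from the transition structure.

## Synthetic-data generator

`default_study_config()` encodes the study conditions: 26 patients × 60
occasions, m = 4 states, the published sample-level state means for the five
channels, staying probabilities (0.84, 0.73, 0.63, 0.57), and beep-level
MCAR missingness at rate 14.23/60. Off-diagonal transition mass follows the
published qualitative switching pattern (from state 1 mostly to 2; from 2
mostly upward; from 3 mostly back to 2; from 4 mostly to 3); the exact
values are configuration, not ground truth. Dispersion defaults — within-SD
12, between-SD 8 on all cells, transition random-effect SD 0.7 on the logit
scale — are not published in the main study text; they were chosen once to
give visible but recoverable patient heterogeneity on the 1–100 scale and
are plainly labelled configuration. Scores are clipped to [1, 100] by
default as a realism toggle; recovery experiments disable clipping because
the model assumes unbounded Gaussians. Per-patient streams derive only from
(master seed, patient index), so panels are reproducible under patient
subsetting.

What the generator does **not** emulate: the bounded, often skewed and
heaped distribution of real visual-analogue items (real scores pile up at 1
and at round numbers), unequal overnight spacing, informative missingness,
item-level (channel-wise) missingness, and any covariate structure. Passing
recovery tests therefore demonstrate correctness of the estimator under the
model's own assumptions at the study's size and noise level — not robustness
to the ways real ESM data violate those assumptions.

## Problem sizes and numerical choices

The recovery experiment used by the acceptance checks runs the full
estimation length of the emulated analysis — 10,000 iterations with 5,000
burn-in, three chains — on the 26 × 60 design (about 3–4 minutes on one
CPU with the compiled kernels). Model-selection checks use scaled-down
single-chain fits (600 iterations, 300 burn-in) across five panel seeds;
AIC differences between m = 3, 4, 5 are small on heterogeneous panels of
this size, so selection is evaluated as a majority across seeds rather than
per panel. Tolerances: simplex rows validated to 1e-12; transition summaries
on the probability scale need not sum to 1 exactly (documented, checked to
0.05); probabilities are floored at 1e-12 before logit transforms; emission
variances at 1e-6. Degenerate inputs: m = 1 is supported as a hierarchical
Gaussian means model (no transition blocks); τ = 0 collapses subject means
onto group means; an all-missing channel is a data error at initialization.

## Known limitations

Discrete-time homogeneous dynamics (no overnight-gap handling, no
covariates); diagonal random-effect covariance; shared emission SDs across
patients; AIC as the only fit index (no WAIC/LOO); the PSRF is computed on
group-level parameters only. On heterogeneous panels the state-2/3 boundary
can be genuinely ambiguous for a few patients; the label-swap move mitigates
but does not abolish the resulting slow between-mode mixing, so occasional
PSRF values near 1.2–1.3 at the default run length reflect posterior
geometry rather than implementation error.
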