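# Methods

`tonebias` implements the behavioural and computational analysis pipeline
for an auditory judgement-bias task: participants learn that a low
(500 Hz) and a high (1000 Hz) tone predict small (£1) and large (£4)
rewards (pairing counterbalanced), and are then probed with an ambiguous
750 Hz mid tone whose outcome is a random 50/50 schedule.  The proportion
of mid tones classified as high-reward is the *affective bias*; reaction
times are decomposed with diffusion models.  This note records the models,
the numerical choices, and what the synthetic data can and cannot show.

## Task designs

Three designs are encoded (`tonebias.design`): a 20-trial acquisition
block (low/high only), a 120-trial main task (40 per tone) and a 240-trial
threat/safe task (4 blocks x 60 trials, 20 per tone per block).  Timing is
held at millisecond integer resolution: 1000 ms tone, 750 ms ISI, 750 ms
feedback after correct responses and 3250 ms after errors/timeouts, giving
the analytic duration bounds (per trial 2.5 s best case, 5 s worst case).
Mid-tone outcome schedules are balanced 50/50 within block and permuted
uniformly at random; the upstream description names a specific sorting
routine, but only the distributional contract (uniform permutation of a
balanced list) is kept.  Threat/safe block order alternates with subject
parity; shocks are recorded at post-threat trials 45 and/or 96 but have no
effect on the generative behavioural model (no shock-number or
shock-timing interaction is modelled).  Acquisition trial order is an
unconstrained uniform permutation (no run-length constraint is imposed).

## Wiener diffusion process

`tonebias.ddm` implements the two-boundary Wiener process: evidence starts
at `z*a`, drifts at `v` with infinitesimal SD `s`, and absorbs at 0 or
`a`; RT = first-passage time + `t0`.  The default diffusion scale is
`s = 0.1`, the convention of the EZ-diffusion literature, so drift rates
like 0.013 are directly comparable with EZ output; `DDMParams.rescaled`
converts between conventions (v and a scale linearly with s).

The first-passage density uses the two classical series expansions
(image-charge sum for small times, sine series for large times), choosing
per evaluation whichever needs fewer terms for a truncation error of at
most `eps` (default 1e-7) on the returned density.  The truncation
allowance is propagated through the `exp(-v a w - v^2 t / 2)/a^2` scaling
so the bound applies to the final value.  Unit tests verify normalization
(<= 1e-5), agreement of the upper-boundary mass with the closed-form
choice probability, the v -> -v, z -> 1-z reflection symmetry, and that
tightening `eps` moves the density by less than the stated bound.

Trial simulation is an Euler-Maruyama walk (default dt = 1 ms).  Discrete
monitoring systematically misses within-step crossings, biasing passage
times late by O(sqrt(dt)); the simulator therefore moves both thresholds
inward by the standard continuity correction `0.5826 * s * sqrt(dt)`.
With this correction the simulated RT distribution at dt = 1e-4 matches
the analytic density with a Kolmogorov-Smirnov distance of about 0.001 at
one million trials; without it the same check needs an order of magnitude
smaller dt.  The kernels compile under numba when present and fall back to
pure Python otherwise.

## EZ-diffusion

`tonebias.ez` maps (proportion positive, mean RT, RT variance) to
(v, a, Ter) in closed form under an unbiased start (z = 1/2), and also
provides the exact forward map, which doubles as the inversion's oracle:
the roundtrip is exact to <= 1e-8 over the working parameter range.  The
moment formulas are written in cancellation-free form (tanh(y/2)/(y/2) for
the mean, a guarded series/asymptotic split for the variance factor) so
they are continuous through v = 0.  RT variance uses denominator n - 1.

Degenerate observed proportions are shrunk before inversion: p = 0 maps to
1/(2n), p = 1 to 1 - 1/(2n), and p = 1/2 (where the boundary separation is
genuinely unidentified) to 1/2 + 1/(2n) with a returned flag.  At n = 1
the 1/(2n) rule itself lands on 1/2, so outputs are additionally kept off
the indeterminate point on the observed side.  EZ estimates are computed
on mid-tone trials pooled within subject (stimulus coding: positive =
high-reward response); responded trials only.

## Hierarchical Bayesian drift-diffusion model

`tonebias.hier` fits trials stratified into unambiguous ("u",
accuracy-coded) and mid-tone ("m", stimulus-coded) trial types.  A model
specification lists which of {v, a, t0, z} split by trial type, and
optionally which split by a cohort factor: a between-subject group
(separate group-level hyperparameters per cohort) or a within-subject
condition (separate subject-level values per condition).  The search grid
is the 16 trial-type subsets, plus cohort variants layered on the full
trial-type model (each single parameter, and all four).

Subject-level parameters are drawn from group-level normals; hyperpriors
are weakly informative on the internal s = 1 fitting scale — mu_v ~
N(0, 5), mu_a ~ N(1.5, 1) truncated positive, mu_t0 ~ N(0.3, 0.25)
truncated positive, mu_z ~ Beta(2, 2), subject-level SDs ~
Half-Normal(0.5).  Estimates are reported back in the s = 0.1 convention
(v, a divided by 10).  Each trial's likelihood is a mixture
`(1-p_out) * WFPT + p_out * 0.5/rt_max` with p_out = 0.05 and rt_max the
maximum observed RT, absorbing extreme RTs instead of trimming them;
missed trials are dropped.

Sampling is adaptive Metropolis-within-Gibbs: univariate random-walk
updates for every subject-parameter and hyperparameter, with proposal
scales adapted toward ~40% acceptance during burn-in only (so the kept
draws come from a fixed kernel).  Two deliberate approximations: hyper
updates use untruncated normal densities for the subject-prior terms
(bounds are enforced on proposals; the ignored normalizing constants are
negligible for parameters well inside their bounds), and chains are
initialized from per-subject-cell EZ moment estimates rather than prior
draws, which makes short burn-ins sufficient.  Defaults are 2 chains,
500 burn-in, 1000 kept draws; `MCMCSettings.paper_settings()` reproduces
the historical 2000-sample / 20-burn-in configuration, which is atypically
short and kept only for comparability.

Model fit is scored by DIC = Dbar + pD with pD = Dbar - D(theta_bar),
deviance focused on subject-level parameters (posterior means taken
arithmetically).  Models within Delta-DIC <= 2 of the winner are flagged
"at parity" (the parity threshold is configurable; 2 is the conventional
"barely worth mentioning" band).  Convergence is monitored by the
Gelman-Rubin potential-scale-reduction factor (single chains are split in
half).  Posterior calibration was checked by replicate z-scores of the
group-level drift mean against generative truth (SD ~ 0.92, i.e. slightly
conservative) and by credible-interval coverage tests.

## Group and condition statistics

`tonebias.stats` provides pooled-variance independent t, paired t,
Cohen's d (paired d = t/sqrt(n); independent d = t*sqrt(1/n1+1/n2)), and
Pearson correlations with two-tailed and one-tailed p-values (one-tailed =
half the two-tailed value on the observed side).

The default-prior Bayes factor is the JZS t-test: a Cauchy(0, 0.707) prior
on the standardized effect size, with BF10 the ratio of the Cauchy-mixed
noncentral-t likelihood of the observed t to its central-t likelihood
under the null.  The integral is evaluated by adaptive quadrature split at
the likelihood peak, which keeps the extreme-evidence regime stable
(t ~ 9 gives BF ~ 5e8 with relative quadrature error below 1e-6); an
independent dense-grid Riemann oracle and pingouin's implementation agree
in tests.  Verbal labels follow the classical scheme — anecdotal (1-3),
substantial (3-10), strong (10-30), very strong (30-100), decisive
(>100) — where the 30-100 band is included for completeness although the
source scheme as printed skips it; BF10 < 1 is labelled on the null side
via the reciprocal.

## Synthetic cohorts

`tonebias.cohort` draws per-subject diffusion parameters from cohort-level
distributions and simulates every scheduled trial through the Wiener
process.  Defaults encode the study conditions: 47 asymptomatic + 30
symptomatic subjects x 120 trials (study 1), 47 subjects x 240 trials
(study 2); mid-tone drift N(0.013, 0.075) v. N(-0.032, 0.066) in the
s = 0.1 convention (the printed group-level EZ drift moments, read as
s = 0.1-convention values); boundary separation log-normal around 0.09 —
the value at which the printed drift SDs and the printed bias SDs
(0.17 / 0.14) are mutually consistent, because the small-drift bias slope
is a/(4 s^2); unambiguous drift magnitude N(0.32, 0.05) (>= 93%
unambiguous accuracy at that boundary); t0 ~ N(0.30, 0.04 s) truncated,
z ~ N(0.5, 0.03), 1% lapse probability, and a null condition effect on
drift by default.  Every dataset carries its generating parameters
("truth records") for recovery scoring, and generation is byte-identical
under a fixed seed.

Covariates are truncated-normal anxiety ratings on [0, 10] with parent
moments (safe 1.64 +- 1.05, threat 4.93 +- 2.21; the printed moments are
used as parent parameters, so sample moments shift slightly at the 0
bound) and trait-anxiety scores tied to generative mid-tone drift through
a Gaussian copula at a target correlation of -0.21 within cohort.  The
trait distributions themselves (36 +- 9 asymptomatic, 55 +- 10
symptomatic) are realistic questionnaire values chosen here, as the source
demographics table is not machine-readable.

What the generator does *not* emulate: acquisition-phase learning
dynamics, shock-induced RT perturbations, response deadlines, sequential
dependencies, or RT contaminants beyond the lapse rule.  Passing recovery
tests therefore show that the estimators are correct for data satisfying
the diffusion model's assumptions, not that real data satisfy them.

## Problem sizes in the test suite

The stochastic acceptance checks run at deliberately reduced scale chosen
for stable pass/fail behaviour: parameter-recovery coverage uses 100
replicates of 20 subjects x 40 mid-tone trials (2 chains x 700 draws);
DIC model recovery uses 20 replicates of 14 subjects x 120 trials across
the 16-model grid (1 chain, 300 burn + 400 draws), with a generative truth
that separates all four parameters across trial types (the structure of
the winning model) by amounts large enough to be identifiable at that
size; the null-condition check uses 5 replicates of 8 subjects x 240
trials.  The simulation/density agreement check uses one million Euler
trials at dt = 1e-4.

## Known limitations

* The adaptive MWG sampler is adequate at desk scale but mixes slowly for
  strongly correlated posteriors (e.g. condition-split drift with few
  subjects); R-hat is reported so poor mixing is visible, not silent.
* DIC with a subject-level focus underpenalizes weakly identified splits;
  near-parity decisions (Delta-DIC ~ 2) should not be over-interpreted.
* The EZ inversion assumes an unbiased start; applying it to data
  generated with z != 1/2 folds start-point bias into drift.
* Printed-t Bayes factors inherit the rounding of the published t values
  (about 1-2% for moderate t, more in the extreme tail).
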