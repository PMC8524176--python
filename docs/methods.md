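# Methods notes

## Generative observer model

Each simulated trial draws an evidence sample x from the stimulus-conditional
distribution S2 ~ N(0, 1) or S1 ~ N(d′, σ_S1), with the S2 standard
deviation fixed at 1 as the unit of the evidence axis. The observer responds
S1 iff x exceeds the threshold k = d′/2 + criterion_shift; with
criterion_shift = 0 and σ_S1 = 1 the model is mirror-symmetric in the two
responses, which is the null condition every asymmetry statistic must
respect (property-tested).

**Difficulty link.** The task manipulates difficulty through SOA, so the
simulator needs a psychometric link d′(SOA). We use a saturating
exponential, d′ = d_max·(1 − exp(−SOA/τ)) — zero at zero exposure,
asymptoting at d_max, strictly increasing so the staircase has a unique
fixed point. This link is a modelling convenience, not a claim about any
dataset; defaults d_max = 2.5, τ = 40 ms place the staircase equilibrium
(~23 ms at d′ ≈ 1.09) in a plausible tens-of-milliseconds range for masked
letter discrimination.

**Staircase.** SOA follows a 1-up-2-down multiplicative staircase
(step factor 0.9, start 30 ms, clamped to [1, 1000] ms): an error divides
the SOA by 0.9 (easier), two consecutive correct responses multiply it by
0.9 (harder). Its asymptotic accuracy is the Levitt fixed point
p² = 0.5 ⇒ p ≈ 0.707 for any monotone psychometric function, verified by a
10⁵-trial simulation (0.707 ± 0.02) and, at the 96-trial session scale,
accuracy over the analyzed blocks stays in [0.65, 0.80] across
d_max ∈ [1.5, 3.5].

**Confidence.** Raw confidence is conf_gain·|x − k| plus zero-mean
Gaussian metacognitive noise (SD `metacog_noise_sd`), squashed to [0, 1)
by u ↦ 1 − exp(−max(u, 0)). The squash is monotone and bounded, mimicking
an analog confidence dial; since auROC2 and the H3 statistic are invariant
to monotone transforms of the scale, its exact shape is immaterial to the
asymmetry analyses (also property-tested). Note a consequence of the
distance-from-threshold rule: an unequal-variance observer develops a
*sensitivity* asymmetry (ΔAUC > 0 for the wide-distribution response) but
only a negligible *mean-confidence* asymmetry; metacognitive-bias effects
(H1) must therefore be studied by explicit injection (see parameter
recovery below).

**Response time.** log RT = log(rt_base) − rt_conf_slope·confidence +
Gaussian noise: RT is log-normal and inversely coupled to confidence
(defaults rt_base = 800 ms, slope 0.5, noise SD 0.3 give median RTs around
500–800 ms and a confidence/log-RT correlation near −0.5).

**Pathologies.** Lapses (probability `lapse_rate`, default 0.02) replace
the response and confidence with uniform draws; a per-subject
comprehension-check failure occurs with probability 0.02. Together with
parameter choices (high lapse rates, zero confidence gain, extreme RT
bases) these exercise every exclusion rule.

**Cohorts.** Between-subject heterogeneity is log-normal (multiplicative,
sigma on the log scale) for strictly positive parameters and additive
normal for the criterion shift — positivity plus right skew is the typical
shape of behavioral parameter distributions. Each subject's parameters and
trials come from an RNG stream spawned from the root seed and the subject
index, so subject i is bit-reproducible and invariant to cohort size.

**What the generator does not emulate.** Real confidence scales show
end-point clumping and discrete anchor use; real RT distributions have
express-guess and attention-lapse mixtures beyond the uniform-lapse model;
sequential effects (post-error slowing, confidence carry-over) are absent;
and the comprehension check is a coin flip, not a behavior. Passing the
simulation-based tests therefore certifies the *analysis machinery* —
estimator identities, null calibration, direction of predicted effects —
not any claim about human data.

## Preprocessing conventions

- RT boundary trials (exactly 250 ms or 5000 ms) are retained: the rule is
  read strictly ("below"/"above").
- The >25%-extreme-RT participant rule is evaluated on all trials; the
  accuracy, error-count and confidence-level rules on the analyzed (last
  five) blocks, which are what feeds the analysis. The accuracy basis is
  switchable (`accuracy_on_all_blocks`).
- Error-type and confidence-level counts use pre-RT-filter analyzed-block
  trials, so trial filtering can never create a participant exclusion.
- Rows with missing confidence are dropped with a warning; there is no
  imputation.

## rc-ROC and auROC2

Cumulative distributions are "at or above threshold" with thresholds at
the distinct confidence values in descending order; ties collapse to one
point and (0,0)/(1,1) close the curve. The trapezoidal area equals the
pairwise concordance statistic exactly (tested to 1e-12 on 1000 random
samples against a brute-force pairwise oracle). The per-subject 20-bin
equal-width confidence binning spans the subject's own dynamic range and
is used for visualization only.

## The SDT-matched null (H3)

Given a subject's hit/false-alarm counts, the equal-variance fit uses
d′ = z(H) − z(F), c = −(z(H)+z(F))/2, decision threshold k = −z(F); the
log-linear correction (+0.5 per cell, +1 per denominator) is applied only
when a cell is zero and is recorded. For each response, the subject's own
incorrect-trial confidence quantiles p are mapped through the fitted
truncated-normal evidence model to the correct-trial cumulative q the
model implies (for S1 responses, θ = Φ⁻¹(1 − p(1 − Φ(k))) and
q = [1 − Φ(θ − d′)]/[1 − Φ(k − d′)]; mirrored for S2). The construction is
analytic rather than simulation-based and is validated against a
10⁶-trial Monte Carlo of the matched observer (area agreement within
0.005, pointwise CDF agreement within 0.01). The H3 statistic — observed
ΔAUC minus this expectation — is mean-zero for *any* equal-variance
observer with a deterministic monotone confidence rule, including strongly
response-biased ones, but not under metacognitive noise, which violates
the monotone-readout assumption; the bias-control test therefore uses
noise-free observers, while the symmetric-cohort null test retains noise
(symmetry alone forces the mean to zero there).

## zROC

The signed-confidence axis (+conf for S1 responses, −conf for S2) is a
monotone transform of the evidence sample for deterministic confidence
rules, so hit/false-alarm rates at its thresholds trace the type-1 ROC and
the z-transformed points are collinear with slope σ_noise/σ_signal.
Degenerate rates (0 or 1) are dropped; slopes come from OLS of z(hit) on
z(FA) (≥3 points required); group descriptives use the median slope, group
inference the t-test on log slopes. The σ_S1 = 1.25 recovery test uses a
fixed-SOA session because staircase SOA jitter mixes d′ levels across
trials and bends the theoretical line the oracle checks.

## Inference

t-tests are one-tailed in each hypothesis's registered direction (H1–H3
greater, H4 less); Cohen's d = mean/SD. The JZS Bayes factor uses the
two-sided Cauchy(0, r) prior, r = 0.65 by default, even alongside
one-tailed t-tests. Quadrature: the substitution δ = r·tanθ maps the
Cauchy prior to a uniform density on (−π/2, π/2); adaptive quadrature
(relative tolerance 1e-8) serves scalar calls, and a 256-node
Gauss–Legendre rule in log space serves the design simulation's tens of
thousands of evaluations (the two routes agree to ~1e-14 relative error
over |t| ≤ 20, and both match an independent fine-grid trapezoidal
integration oracle). Non-finite noncentral-t density evaluations at
astronomically large noncentralities are treated as zero. The minimal
BF-decisive effect size solves BF10(d√n) = 3 by Brent's method on
d ∈ [min_detectable_d/4, 1].

**Design simulation.** 10,000 repetitions, each drawing 106 unit-variance
normal subject summaries with true mean δ (δ = 0, or δ ~ Cauchy(0, 0.65)),
then computing t and its Bayes factor. 10⁴ repetitions put the Monte-Carlo
standard error of each reported proportion below half a percentage point.

**Verdicts.** Reports base their verdict on the Bayes factor (support at
BF > 3, inconclusive otherwise) with the frequentist result always shown;
disagreements between one-tailed significance and the BF verdict are
flagged, not adjudicated.

## Parameter recovery

`h1_power_simulation` estimates the pipeline's power to detect a group
metacognitive-bias asymmetry: each run simulates a fresh symmetric null
cohort, applies the full exclusion-and-summary pipeline, shifts every
included subject's confidence-asymmetry summary by d times that run's
sample SD (an exact injection of an observed-scale effect size d), and
applies the registered one-tailed test. The detection rate at d = 0.66
matches the closed-form noncentral-t power within binomial error. The
summary-level injection is deliberate: calibrating raw observer parameters
to a target Cohen's d would require the very power curve under test.

## Problem sizes and determinism

Simulation-based checks use the smallest sizes at which their oracles are
sharp: 200 subjects for cohort-level nulls, 480 trials/subject for
finite-sample-bias-sensitive H3 checks, 10⁵ trials for staircase and zROC
asymptotics, 10⁶ for the SDT-null curve calibration, 100 runs for power
recovery. All stochastic tests run under fixed seeds; identical seeds give
bit-identical trial tables and reports.

## Configuration schema

```yaml
simulation:
  observer:            # ObserverParams fields, e.g. sigma_s1: 1.25
  dispersion:          # field -> log-sd (criterion_shift: additive sd)
  design:              # n_subjects, n_trials, n_blocks, soa_start_ms, fixed_soa_ms
analysis:
  rscale: 0.65
  accuracy_on_all_blocks: false
```

## Known limitations

- No meta-d′ fitting, no maximum-likelihood unequal-variance SDT fit (the
  variance ratio is read off the zROC slope only), no directional
  (half-Cauchy) Bayes factors, no multiple-comparison correction (none is
  part of the registered analysis).
- The mixed-effects cross-experiment model is out of scope; inter-subject
  effect correlations are per-experiment Pearson r.
- ΔAUC and the H3 statistic carry O(1/n_trials) finite-sample bias at the
  96-trial session scale; group tests against zero remain calibrated under
  symmetry, but absolute per-subject values at small trial counts should
  be interpreted with care.
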