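# metaroc

Analysis toolkit for **metacognitive asymmetry** in two-choice perceptual
decisions: does confidence track accuracy differently depending on *which*
response was given?

The package targets masked-discrimination experiments in which observers
choose between two stimulus classes (S1 vs S2), rate their confidence on a
continuous 0–1 scale, and have task difficulty (stimulus-onset asynchrony,
SOA) calibrated online by an adaptive staircase. It provides:

- a **signal-detection observer simulator** that generates realistic
  trial-level data (staircase-controlled difficulty, confidence–RT
  coupling, lapses, comprehension failures) with configurable
  unequal-variance evidence structure;
- the **pre-registered preprocessing rules**: first-block removal,
  250 ms–5 s response-time trial filter, and participant exclusions for low
  accuracy, extreme-RT fractions, failed comprehension checks, too few
  errors, or degenerate confidence distributions;
- **response-conditional type-2 ROC** (rc-ROC) curves and their areas
  (auROC2), the field's standard measure of metacognitive sensitivity, and
  the asymmetry statistic ΔAUC = auROC2(S1 responses) − auROC2(S2
  responses);
- an **equal-variance SDT-matched null** for ΔAUC (a response bias alone
  can create or mask an apparent asymmetry; subtracting the asymmetry an
  equal-variance observer with matched d′, criterion and incorrect-trial
  confidence distribution would show removes that confound);
- **zROC slope** estimation (inverse-normal-transformed hit/false-alarm
  rates across confidence thresholds), whose slope estimates the
  noise-to-signal evidence SD ratio — 1 under equal variance;
- **inference**: one-tailed group t-tests with Cohen's d, two-sided JZS
  (Cauchy-prior) Bayes factors computed by numerical quadrature
  (default prior scale r = 0.65), power and minimal-effect-size analyses,
  Bayes-factor design simulation, and prior-scale robustness regions.

## The statistics in brief

For trials sharing a response, the rc-ROC plots the empirical cumulative
distribution (high → low confidence) of correct trials against that of
incorrect trials; its trapezoidal area equals the concordance statistic
P(conf_correct > conf_incorrect) + ½P(tie). The JZS Bayes factor for a
one-sample t statistic is

```
BF10 = ∫ f_nct(t; ν, δ√n) Cauchy(δ; 0, r) dδ / f_t(t; ν),    ν = n − 1,
```

with a Cauchy prior on the standardized effect size δ, evaluated by
adaptive quadrature after the substitution δ = r·tanθ.

## Worked example

Simulate a 106-subject cohort whose S1 evidence distribution is 25% wider
than S2 (the generative structure that produces a metacognitive-sensitivity
asymmetry), then run the registered four-hypothesis analysis:

```bash
cat > asym.yaml <<EOF
simulation:
  observer:
    sigma_s1: 1.25
  dispersion:
    d_max: 0.15
    sigma_s1: 0.05
    rt_base_ms: 0.15
  design:
    n_subjects: 106
EOF
metaroc simulate --out trials.csv --config asym.yaml --seed 11
metaroc analyze trials.csv --out results
cat results/report.txt
```

```
Experiment analysis report
==========================
subjects: 102 included of 106 recruited
exclusions: {'failed_comprehension': 4}
descriptives: mean_accuracy=0.712, mean_response_bias=-0.021, mean_confidence=0.647, mean_last_trial_soa_ms=29.955

H1 confidence asymmetry (S1 - S2 responses): mean=+0.0005, t(101)=0.07, p=0.4715 (greater), d=0.01, BF10=0.12, BF01=8.39 -> null
H2 auROC2 asymmetry (Delta AUC): mean=+0.1275, t(101)=10.72, p=0.0000 (greater), d=1.06, BF10=2225633473449438.25, BF01=0.00 -> alternative
H3 Delta AUC beyond matched SDT null: mean=+0.1351, t(101)=11.01, p=0.0000 (greater), d=1.09, BF10=9521645664212540.00, BF01=0.00 -> alternative
H4 log-RT asymmetry (S1 - S2 responses): mean=-0.0004, t(101)=-0.05, p=0.4791 (less), d=-0.01, BF10=0.12, BF01=8.40 -> null
```

Reading the output: the staircase held accuracy near 71%; four subjects
were excluded by the comprehension-check rule. The wide-S1 cohort shows a
decisive metacognitive-sensitivity asymmetry — confidence discriminates
correct from incorrect answers better after S1 responses (ΔAUC ≈ +0.13,
BF10 ≫ 3) — that survives the SDT bias control (H3), while mean confidence
and response-time asymmetries (H1, H4) correctly come out null for this
generative model, whose confidence rule is symmetric in distance from the
decision threshold.

Design analysis from the shell:

```bash
metaroc design --n 106 --rscale 0.65 --n-reps 10000 --seed 1
```

reports 95% power at d = 0.32, a minimal one-tailed-significant observed
d of 0.16, a minimal BF-decisive (BF10 > 3) observed d of 0.26, and the
fractions of simulated experiments supporting null/alternative under
point-null and Cauchy-distributed true effects.

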