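# sirpower

Sample-size calculation, hypothesis testing, and Monte-Carlo calibration for
**indirect standardization** in hospital profiling.

## The problem

Hospital profiling compares an *index* hospital's rate of a binary adverse
outcome — here, "high-dose" CT exams — against a wider reference population,
adjusting for case mix (anatomic area scanned × patient size category). The
standard adjusted measure is the **standardized incidence ratio**

```
θ(Λ, p, q) = q / Σ_j λ_j p_j ,
```

the index hospital's outcome prevalence *q* divided by the prevalence
expected if the reference stratum risks Λ = (λ_1, …, λ_J) applied to the
index covariate mix **p**. θ > 1 means more high-dose exams than the
hospital's case mix warrants.

Traditional inference treats the denominator as known, which is untenable
before any data has been collected from the index hospital — exactly the
situation faced when planning how many exams to request. `sirpower`
treats **both q and p as estimated from the same sample of n exams**.
By the delta method, √n(θ̂ − θ) is asymptotically normal with variance
σ²(θ, p) = ∇θᵀ Σ ∇θ, where Σ is block-diagonal in the binomial variance
q(1−q) of q̂ and the multinomial covariance D_p − ppᵀ of p̂. The one-sided
level-α test of H0: θ = 1 versus θ > 1 rejects when

```
(θ̂ − 1) / (σ(1, p̂)/√n)  >  z_{1−α} ,
```

and the power to detect θ ≥ 1 + δ, **using no index-hospital information**,
averages over the I reference hospitals' covariate mixes p⁽ⁱ⁾:

```
1 − β = (1/I) Σ_i [ 1 − Φ( (z_{1−α} − δ√n/σ(1, p⁽ⁱ⁾)) · σ(1, p⁽ⁱ⁾)/σ(1+δ, p⁽ⁱ⁾) ) ] .
```

This expression is monotone in n, so the minimal sample size is found by
scalar root-finding. Two traditional fixed-denominator designs (denominator
from a preliminary index sample, or from the pooled reference mix) are
included as comparators, and a simulation framework measures empirical
type I / type II error rates of all three approaches on synthetic
multi-hospital registries.

## Worked example

```python
from sirpower import (RegistryConfig, generate_registry, build_reference_standard,
                      summarize_hospitals, PowerSpec, sample_size, SIRModel,
                      make_simulated_hospital, draw_index_sample)

# a synthetic registry standing in for a large multi-site CT dose registry
table = generate_registry(RegistryConfig(seed=42))
reference_ids = sorted(table["hospital_id"].unique())[:103]
reference = build_reference_standard(table[table["hospital_id"].isin(reference_ids)])

# how many exams must an unseen hospital share to detect SIR >= 1.2?
design = sample_size(reference, PowerSpec(alpha=0.05, target_power=0.80, delta=0.2))
print(design.summary())

# profile a hospital whose true SIR is 1.3 from a sample of that size
index = summarize_hospitals(table[table["hospital_id"] == 140], reference)[0]
elevated = make_simulated_hospital(index, reference, target_sir=1.3)
sample = draw_index_sample(elevated, design.n, seed=7)
print(SIRModel(sample, reference).fit(alpha=0.05).summary())
```

prints

```
SIR sample-size design  (proposed)
  minimal n        373
  achieved power   0.8006
  per-hospital power over 103 reference mixes: min 0.6491, median 0.8064, max 0.8930

One-sided SIR test  (H0: theta = 1  vs  H1: theta > 1)
  n exams          373
  SIR estimate     1.1447
  null scale sigma 1.6210
  z statistic      1.7238
  critical value   1.6449  (alpha = 0.05)
  p-value          0.04237
  decision         REJECT: SIR elevated
```

373 exams suffice for 80% average power against SIR ≥ 1.2 at level 0.05 —
the achieved power is the mean of the per-reference-hospital detection
probabilities, which vary with each hospital's case mix. The test then
finds θ̂ = 1.14 from the 373 sampled exams, with z = 1.72 above the 1.64
critical value: the hospital is flagged as having an elevated high-dose
rate.

## Command line

```bash
sirpower generate   --config registry.yaml --out registry.csv
sirpower samplesize --reference registry.csv --alpha 0.05 --power 0.80 --delta 0.2
sirpower power      --reference registry.csv --n 400
sirpower test       --index index.csv --reference reference.json --alpha 0.05
sirpower study      --config study.yaml --out error_rates.csv
```

Exam-level CSVs use the columns `fac` (hospital), `sizeC` (covariate
stratum) and `dlp.over` (binary high-dose outcome); reference standards
serialize to JSON.

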