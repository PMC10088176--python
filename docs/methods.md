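# Methods

## Model and estimator

Exams from a hospital fall into J covariate strata (here the crossing of
anatomic area with patient size category) with mix **p** = (p_1, …, p_J),
and each exam is high-dose with a probability that depends on its stratum.
A reference standard supplies stratum risks Λ = (λ_1, …, λ_J), treated as
known exactly — the reference registry is assumed large enough that its
estimation error is negligible next to index-hospital sampling error. The
standardized incidence ratio is θ = q / m with q the hospital's outcome
prevalence and m = Σ_j λ_j p_j its expected prevalence under the reference
risks.

From a sample of n exams, q̂ and p̂ are the observed proportions (no
shrinkage or smoothing) and θ̂ = q̂/Σλ_j p̂_j. The delta method gives

σ²(θ, **p**) = ∇θᵀ Σ ∇θ,  ∂θ/∂q = 1/m,  ∂θ/∂p_j = −qλ_j/m²,
Σ = blockdiag(q(1−q), D_p − ppᵀ),

so √n(θ̂ − θ) → N(0, σ²). Because q = θ·m, σ² is a function of (θ, p)
once Λ is fixed; `sigma(reference, theta, mix)` evaluates it along that
curve. With J = 1 the whole machinery collapses to the classical one-sample
proportion problem: σ(θ) = √(θλ(1−θλ))/λ.

The one-sided test of H0: θ = 1 against θ > 1 rejects when
(θ̂ − 1)/(σ(1, p̂)/√n) > z_{1−α}. The null scale uses the *sampled* mix p̂:
the true p is unknown at analysis time, p̂ → p preserves the asymptotics,
and an optional `known_mix` override accepts an externally known mix. The
test is purely asymptotic-normal — no continuity correction, no exact
small-sample variant — and is deliberately one-sided: profiling seeks
hospitals with *elevated* rates, and low-SIR hospitals are not of concern.

### The block-diagonal covariance is an independence assumption

Σ sets cov(q̂, p̂) = 0, which holds exactly when an exam's outcome is
independent of its stratum. When stratum risks genuinely differ (r_j
varying over j), the outcome *is* informative about the stratum and the
true covariance is negative in the relevant direction; conditional on the
sampled mix, θ̂ is then unbiased for θ whenever r_j ∝ λ_j, so the
mix-uncertainty term in σ² cancels and the true asymptotic variance is
Σ_j p_j r_j (1 − r_j)/m² < σ². The practical consequence, visible in the
simulation study, is a *conservative* test and an over-delivering design:
with stratum-proportional risks, empirical type I error runs near 3.8–3.9%
at nominal 5%, and empirical power near 83–84% at a nominal 80% target
(type II 16–17% at nominal 20%). The direction of the deviation is safe —
error rates are below, never above, their targets — and the package
reports whatever the simulation measures rather than the nominal values.

## Design calculations

`power` evaluates the reference-averaged power formula (strictly increasing
in n and δ; exactly α at δ = 0); `sample_size` brackets the continuous
power curve, solves it with Brent's method (xtol 1e-6, n ≤ 1e9), takes the
ceiling and scans ±1 so that power(n) ≥ 1−β > power(n−1) always holds.
Feasibility — (1+δ)·Σλ_j p_j⁽ⁱ⁾ < 1 for every reference hospital — is
enforced with an error naming the offending hospital rather than silent
exclusion.

The two traditional comparators treat m as a known constant, so
θ̂ = q̂/m carries only binomial noise with scale σ_f(θ) = √(θm(1−θm))/m,
and the textbook one-sided one-sample design applies:
n = ⌈((z_{1−α}σ_f(1) + z_{1−β}σ_f(1+δ))/δ)²⌉. The "reference mean"
variant takes the mix from the pooled reference population; the "index
sample" variant estimates it from a preliminary sample of 100 index exams
(a named, overridable constant). Note that the proposed design always
needs at least as many exams as a fixed-denominator design evaluated at
the same mix — the gap is exactly the multinomial mix-uncertainty term
(q²/m⁴)(Σλ_j²p_j − m²) that the traditional designs assume away — so the
two coincide only when that term vanishes (e.g. J = 1).

## Synthetic registry generator

The generator emulates the structure of a large international CT dose
registry at the level of its documented summary features; it is the data
source for all tests and for the calibration study. Defaults, all
overridable in `RegistryConfig`:

- **154 hospitals**, of which 103 form the reference split and 51 the
  index pool.
- **J = 16 strata** (4 anatomic areas × 4 size categories). Global stratum
  risks λ*_j increase over size categories within each area (size carries
  3/4 of the spread, area 1/4) and span [0.07, 0.51] — the documented range
  from the smallest patients' combined-area exams to the largest patients'
  abdomen exams. Area/size labels are opaque tokens (`a1s1` … `a4s4`); the
  DLP thresholds that define "high dose" upstream (1160/660/1580/1060
  mGy-cm by area) are narrative context only, since the schema carries the
  binarized outcome, not doses.
- **Hospital sizes** log-uniform on [500, 50000] exams, giving the
  realistic several-orders-of-magnitude spread of site volumes.
- **Covariate mixes** Dirichlet-distributed around a common near-uniform
  global mix with per-stratum weight `mix_concentration × J × global_mix_j`
  (default concentration 1.5 → per-stratum weights ≈ 1.5, coefficient of
  variation near 80% per stratum). This produces the strongly heterogeneous
  case mixes that motivate treating p as unknown; pushing the concentration
  to ∞ recovers the homogeneous limit in which all hospitals share one mix.
- **Hospital risk multipliers** c_i, applied as clip(c_i·λ*_j, 0, 1):
  log-normal with mean exactly 1 (log-sd 0.35), clipped to [0, 3]. Mean 1
  keeps the pooled reference risks centred on λ* (a uniform draw over the
  SIR range would inflate them by its mean); the resulting full-data SIRs
  span roughly 0.35–2.6, matching the documented 0-to-3 spread in shape.

Everything is reproducible from a single integer seed, and the generator
emits the same exam-level CSV schema the I/O layer reads, so synthetic and
real tables share one code path.

What the generator does **not** emulate: continuous dose values, scanner
or protocol effects, temporal drift, correlation between a hospital's size
and its case mix or quality, and any registry-specific marginals beyond
the summary facts above. Passing calibration tests on this generator
therefore demonstrates the method's behaviour under its stated sampling
model (i.i.d. exams, fixed per-stratum risks), not robustness to
real-world violations of it.

## Simulated index hospitals

To evaluate error rates at a prescribed true SIR θ*, a base hospital's
covariate distribution is kept fixed and its per-stratum risks are set to
r′_j = θ*·λ_j, clipped to [0, 1]; if any stratum clips, the unclipped
strata are scaled up (iteratively, water-filling style) until
Σ r′_j p_j = θ*·Σ λ_j p_j exactly, or an infeasibility error is raised if
even all-ones rates cannot reach the target. This multiplicative recipe is
the simplest construction that (a) leaves the covariate distribution
untouched and (b) hits the target SIR exactly in expectation; alternative
recipes (e.g. stratum-independent relabeling at the same marginal
prevalence, which makes the block-diagonal covariance exact and the test
almost perfectly calibrated) can be slotted in by constructing
`SimulatedHospital` directly. Index samples are drawn generatively —
stratum from the mix, outcome Bernoulli(r′_j) given the stratum — with
finite resampling from real exam tables available in
`registry_io.sample_index_exams` (with replacement by default, since the
designed n can exceed a small hospital's volume).

## Calibration study

`run_study` executes the full loop: split hospitals (seeded uniform
random split, or selection stratified into full-data SIR bands
<0.9 / 0.9–0.95 / 0.95–1 / 1–1.25 / 1.25–1.5 / >1.5 taking
max(2, ⌈band/3⌉) per band); build the reference standard from the
reference group only; compute each method's design size (single n for the
proposed and reference-mean designs, per-hospital n for the
index-sample design from its preliminary 100-exam mix estimate); then for
every index hospital × grid SIR (default 0.5 to 1.5 by 0.1, comparators at
1.0 and 1.2 only) draw the designed number of exams 1000 times, apply the
method's test, and tabulate rejection fractions. Rejections at true
SIR ≤ 1 count as type I error, non-rejections at SIR > 1 as type II. All
streams derive from one master seed via `SeedSequence` spawn keys
((0,) split, (1, h) preliminary samples, (2, h, g, m) testing cells), so
any subset reruns bit-identically. At 1000 replicates a single hospital's
rate carries ≈ ±1.3-point Monte-Carlo noise (MCSE √(r(1−r)/1000));
comparisons should use the MCSE-based tolerances the tests apply.

Problem sizes used by the shipped test suite and acceptance script — the
full default registry (154 hospitals, ≈1.7 M exams), 1000 replicates per
hospital per grid point, and brute-force variance checks at n = 10⁵ with
10⁴ replicates — run in seconds to a few minutes on one core thanks to
vectorized multinomial/binomial sampling.

## Known limitations

- Λ is treated as exact; reference registries of moderate size would add
  denominator uncertainty the variance formula ignores.
- The block-diagonal covariance overstates variance whenever outcome and
  stratum are dependent (see above); the resulting conservatism is
  quantified by the simulation study but not corrected analytically.
- Asymptotic normality needs n·m and n·(1−m) reasonably large; no exact
  small-sample test is provided.
- One outcome, one-sided alternative, no confidence intervals, no
  finite-population correction, no multiplicity control across hospitals.
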