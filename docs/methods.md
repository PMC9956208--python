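# Methods

## Models

All 27 models are pairs (baseline, structure). Structures:

* **plain** — the baseline itself;
* **hurdle** (zero-altered) — point mass φ at zero, baseline rescaled over
  the non-zero support by (1−φ)/(1−p₀(θ));
* **zero-inflated** — structural zeros with weight φ mixed with the
  untruncated baseline, so P(Y=0) = φ + (1−φ)p₀(θ).

p₀(θ) is the baseline zero probability: f_θ(0) for discrete baselines and 0
for continuous ones, which makes the two sparse structures *identical
distributions* for continuous baselines; the package implements them as one
distribution under two names, and a test asserts pointwise equality of
density and CDF. An exact recorded zero is treated as the zero mass; every
other floating-point value is "non-zero" (no zero tolerance — this matches
data in which zeros are literally recorded zeros).

Parameterizations (all scale/shape parameters strictly positive, φ ∈ [0,1]):
normal/log-normal (μ, σ); half-normal scale σ, density 2·ϕ₀(y/σ)/σ on y ≥ 0;
exponential **rate** λ (mean 1/λ); Poisson λ; geometric p on failures-before-
first-success support {0,1,2,…} (so p₀ = p > 0 and the sparse structures are
meaningful); negative binomial (r, p) failures before the r-th success; beta
binomial (n, α, β) with the size n continuous during estimation; beta
negative binomial (r, α, β).

Numerical notes on the count mixtures:

* Beta-binomial pmf uses gamma functions, C(n,y) = Γ(n+1)/(Γ(y+1)Γ(n−y+1)),
  defined for integer y < n+1, so a continuous n̂ slightly below max(y) is
  representable. The *likelihood*, however, diverges on the ridge
  n − max(y) + β → 0⁺, so estimation constrains n ≥ max(y); in practice n̂
  sits at or just above the data maximum. For non-integer n the pmf over
  {0,…,⌈n⌉} sums to slightly less than one; the CDF is clipped at 1 and the
  discrepancy is far below test tolerances at the parameter points used.
  Sampling requires integer n (beta-mixed binomial).
* Beta-negative-binomial sampling composes p ~ Beta(α, β) with NB(r, p).
  Its likelihood is nearly flat in r at moderate sample sizes: on 2000 draws
  from (r, α, β) = (5, 3, 3) with 30% zero inflation the exact MLE of r
  ranges from roughly 4 to over 20 across simulation seeds while φ̂ stays
  within ±0.03 of the truth. Tests and reported tolerances for r are set
  from a 50-replicate pilot of that sampling distribution; the flatness is a
  property of the model, not of the optimizer (the fitted log-likelihood
  always dominates the truth's).

## Estimation

Closed-form MLEs: normal and log-normal (means and 1/N variances of y or
log y — likelihood quantities feeding AIC, not the N−1 variants),
half-normal (σ̂² = mean y²), exponential (λ̂ = 1/ȳ), Poisson (ȳ), geometric
(1/(1+ȳ)); zero-truncated closed/near-closed forms for geometric (shifted
geometric, p̂ = 1/ȳ⁺) and Poisson (λ/(1−e^(−λ)) = ȳ⁺, solved by Brent).
Everything else is L-BFGS-B on log-parameters (default bounds 1e−10…1e5 per
positive parameter), ≥3 restarts from jittered moment inits, with discrete
log-likelihoods aggregated over unique values.

Hurdle likelihoods factorize exactly: φ̂ = n₀/N, and the non-zero part is the
baseline MLE on non-zero values (continuous) or the zero-truncated MLE
(discrete). Zero-inflated fits profile φ: for fixed θ the maximizing φ is
clip((n₀/N − p₀)/(1 − p₀), 0, 1), and when it is interior the θ-part of the
profiled likelihood *is* the zero-truncated likelihood. The joint MLE is
therefore the better of (truncated-MLE θ with its profiled φ) and
(plain-MLE θ with φ = 0), both evaluated under the profiled zero-inflated
log-likelihood. Boundary fits (φ̂ = 0) are valid results and φ still counts
in k. The convention 0·log 0 := 0 applies throughout. An all-zero sample is
an estimation error (φ̂ = 1 leaves the baseline unestimable). A plain
log-normal asked to fit data containing zeros estimates (μ, σ) from the
positive part and reports log-likelihood −∞ (zeros are impossible under the
model); this keeps the KS screen usable — such a model rejects through its
unmatched atom — while guaranteeing it never wins an AIC comparison.

AIC = −2·loglik + 2k and BIC = −2·loglik + k·log N (natural log), with k
counting φ whenever the structure is not plain.

## Goodness of fit

The KS statistic is D = max over observed points of
max(|Fₙ(y) − F(y)|, |Fₙ(y⁻) − F(y⁻)|), where F is the model CDF including
its jumps (φ-atom at zero; pmf masses for discrete baselines) — the two-sided
discrepancy of a step function against a possibly-jumpy CDF is attained at
data points. Because parameters are estimated, p-values come from a
parametric bootstrap: fit, simulate nsim samples of size N from the fit,
re-fit each replicate, and count replicate statistics ≥ the observed one
(plain proportion, no continuity correction, so exact 0 and 1 occur).
Method A simulates every replicate from the one fitted model; method B —
used by default for N ≤ 50 — re-estimates each replicate's generating
parameters from a with-replacement resample of the data first, propagating
small-sample parameter uncertainty into the null distribution. (Which of
these two schemes the original R implementation uses for its small-sample
variant is under-documented; the split here is isolated behind the `method`
flag.) Replicates whose re-fit fails are dropped and counted; fewer than 10
survivors aborts the test. Default nsim = 100. Type-I calibration at
nominal 0.05 is checked by simulation (N=100, nsim=200, 200 outer
replicates) for a continuous and a discrete model; the observed rejection
rates sit in [0.02, 0.10].

Model screening tests each candidate family in a fixed order (for continuous
data the 12-model list N, ZIN, NH, HN, ZIHN, HNH, LN, ZILN, LNH, E, ZIE,
EH); families with p ≥ 0.05 are admissible, the chosen family maximizes the
p-value, and ties are broken toward the *last* tied candidate — the list
order is therefore part of the contract and is logged. If nothing is
admissible the max-p family is still returned, flagged, so downstream
rankings remain total. `nsim=0` skips the screen (used by fixed-family
shortcuts).

## AIC-difference significance test

For one covariate with labels in {1,…,m}: Model I selects and fits the best
family on the pooled values; Model II does so per class independently
(classes may choose different families, and their AICs are summed and
compared as-is — no refitting to a common family). The statistic is
ModelIAIC − ModelIIAIC; larger means more label-informative, and a
difference > 2 (configurable) is flagged significant. Under exchangeable
classes Model II buys ~χ² log-likelihood but pays 2k extra penalty per
additional class, so the null mean difference is negative. `rank_features`
computes the statistic per column and sorts descending with a stable sort
(input order breaks ties; unfittable columns rank last). The fixed-family
option bypasses the per-feature KS screen with either one named family or a
zeros/no-zeros dichotomy (log-normal hurdle vs log-normal), which is the
shortcut used inside cross-validation. AIC is the ranking criterion (sample
sizes here are small-to-moderate); BIC is computed and stored alongside.

## Longitudinal pipeline

Subjects' irregular visit series are mapped to an equally spaced grid
(default 38 weekly points): linear interpolation between visits, and the
nearest observed value (1-NN on the time axis) outside the observed span.
The nearest-neighbor imputation is within-subject; a cross-subject
profile-based variant would be a different design and is intentionally not
implemented. Subjects with fewer than `min_obs` (default 2) observations are
dropped with a warning; outlier removal is manual via `exclude`, never
automated. At each grid week the AIC-difference test runs on the
cross-section; per-group normal-hurdle (μ̂, σ̂, φ̂) trajectories are recorded
for inspection (a group without zeros has φ̂ ≡ 0). `zero_rules` lets the
candidate list depend on the sample being fitted — the shipped rule uses
sparse models where zeros occur and plain continuous models where none do,
which collapses most selection noise while keeping the atom modeled where it
exists.

## Expression pipeline

Feature filtering is three ordered stages — drop all-zero columns, drop
zero-free columns, keep zero proportion within [0.05, 0.50] (closed) — with
an additive stage report. Classification is Euclidean 1-NN with distance
ties resolved toward the lowest training-row index; the "training error" is
leave-one-out (each sample predicted from all others), since self-inclusive
1-NN error is identically zero. Cross-validation splits rows into k
near-equal random blocks (seeded, unstratified), ranks features on training
rows only (default: the log-normal dichotomy shortcut), and pools held-out
errors per requested gene count; k = N with all features reproduces the
leave-one-out training error exactly. PCA cumulative variance fractions are
computed on centered, unscaled columns (whether to standardize is genuinely
open for this kind of data; unscaled matches the convention of reporting
variance explained in the measurement units).

## Synthetic data

The longitudinal generator emulates a two-group cohort of 22 "case" and 30
"control" subjects over 38 weeks. Both groups draw from one normal-hurdle
distribution (φ = 0.10, μ = 5, σ = 2) before a changepoint at week 22; from
that week on the case group shifts to (φ = 0, μ = 11, σ = 4) — mean up by
3σ, spread doubled, zeros gone, the qualitative late-pregnancy behavior of
the motivating cohort. σ = 2 (coefficient of variation 0.4) matters: with a
much tighter baseline, linear interpolation between a zero visit and a
normal visit manufactures extreme low outliers that randomly flag
pre-changepoint weeks. Visit schedules emulate the cohort design rather than
uniform thinning: enrollment in weeks 1–13, visits every 4 weeks up to the
changepoint region and every 2 weeks after, each non-terminal visit missed
with probability 0.15 (realized counts ≈ 5–14). Sparser cohorts (e.g. 3–8
visits) are reachable through `miss_rate`/`enroll_max`, but changepoint
localization under linear interpolation degrades with the longest
visit gap straddling the changepoint, so the recovery property is stated for
the default schedule. With all effect knobs zeroed the two groups are
identical in distribution throughout.

The matrix generator emulates a sparse expression table: five unbalanced
classes (300/146/78/141/136), 200 features of which 10 are informative,
log-normal-hurdle marginals with per-feature zero proportions uniform on
[0.05, 0.50] (informative features: [0.05, 0.20], shared across classes) and
(μ, σ) uniform on [0, 2] × [0.3, 0.8]. Informative features shift the
location by effect·σ_j·π_j(k) with a random class permutation π_j and
effect = 2 — strong class separation, consistent with the near-zero
cross-validated error the emulated study reports for its top-ranked genes.
Ground truth (changepoint, segment parameters, informative set) is returned
and serialized with every dataset, and both generators are deterministic
given a seed.

What the synthetic data does *not* emulate: within-subject autocorrelation
beyond the changepoint structure (visit draws are independent), zero runs
("absence spells"), feature–feature correlation, compositional or
sequencing-depth effects, and batch structure. Passing recovery tests
therefore demonstrates that the pipelines detect the planted parametric
structure at realistic sizes, not that real cohorts meet these assumptions.

## Reference experiments and problem sizes

`scripts/acceptance.py` reruns three reference MLE experiments at N = 2000
with a user seed: plain beta-binomial (4, 2, 3) — reporting n̂ and the
maximized log-likelihood — zero-inflated beta-negative-binomial
(φ=0.3, 5, 3, 3) — reporting φ̂ and r̂ — and log-normal hurdle (φ=0.3, 1, 4)
— reporting σ̂ and φ̂. A 50-replicate pilot fixes the expected sampling
spread of each estimate (e.g. SD(σ̂) ≈ 0.08, SD(φ̂) ≈ 0.01, SD(loglik) ≈ 16
for the beta-binomial); r̂ of the ZIBNB is the one weakly identified
quantity (see above). The test suite runs the same experiments at a frozen
seed with 3·√2·SD tolerances, plus the calibration study (N=100, nsim=200,
200 replicates per family), the changepoint recovery study (10 cohorts,
nsim=40 per KS screen), and the ranking/CV recovery study (10 and 5
generator seeds). These sizes were chosen to estimate each quantity to well
inside its acceptance band at desk scale.

## Known limitations

* Beta-binomial n̂ is pinned to max(y) when the true size equals the sample
  maximum — correct behavior for a boundary MLE, but intervals for n would
  need profile methods the package does not provide.
* No Fisher-information standard errors or likelihood-ratio tests; AIC/BIC
  and bootstrap p-values are the only inferential outputs.
* The per-feature KS screens are not multiplicity-corrected (by design — the
  downstream ranking consumes raw differences).
* Covariate-dependent φ or θ (regression/mixed-effects structures) are out
  of scope.
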