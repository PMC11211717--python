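# Methods

## The task and its generative model of behavior

The package models a visuospatial delayed match-to-sample (DMS) task. A
sample appears at one of 12 equiprobable polar-angle locations spaced
180/13 ≈ 13.85° apart on the arc (13.85°–166.15°), so that every sample can
be flanked on both sides; the 14 possible test locations therefore span
[0°, 180°]. After a delay T ∈ {1, 3, 9} s (equiprobable) a test appears
either at the sample location ("match"), one grid step away ("near"
nonmatch) or k ≥ 2 steps away ("far" nonmatch, 27.7°–166.15° depending on
the sample location). Blocks hold 63 trials. The printed category mix of
33/33/34% is not integer-realizable in 63 trials; blocks are generated with
exactly 21/21/21 trials per category, which reproduces the 33% match and
near proportions exactly and makes block composition deterministic. Delays
and sample locations are drawn i.i.d. equiprobably rather than balanced
within blocks ("randomly interleaved" does not imply balancing); far
distances are uniform over the admissible spacing multiples at the drawn
sample location, with the side then uniform among the sides where that
distance stays on the test grid.

Behavior is generated by a two-stage model:

1. **Memory diffusion.** The remembered location performs Wiener diffusion,
   so the across-trial SD of the memory trace after a delay T is
   σ_T = σ_mem·√T, with σ_mem in degrees·s^−1/2. The decision variable
   x = |memory − test| then follows a normal distribution centred on the
   true sample-test distance Δ and folded at zero:
   pdf(x | Δ, σ_T) ∝ φ((x−Δ)/σ_T) + φ((x+Δ)/σ_T).
2. **Decision.** A logistic decision function
   DF(x) = θ + (1 − 2θ) / (1 + e^−(x−δ)/σ_dec)
   maps x onto the probability of reporting "different": δ (degrees) is the
   decision threshold (DF(δ) = 0.5), σ_dec the decision-noise slope
   (σ_dec = 0 degenerates to a hard step threshold, with 0.5 returned at
   the tie x = δ), and θ a time-independent lapse probability setting
   symmetric asymptotes. A memory-lapse hazard λ (s^−1) additionally lets
   the trace vanish by time t with probability 1 − e^−λt, in which case the
   subject guesses. The choice probability is the mixture
   p(different | T, Δ) = θ_mem,T·0.5 + (1 − θ_mem,T)·Σ_x DF(x)·pdf(x).

Responses are coded different = 1, same = 0. The model is response-time
free; RT columns exist only so the exclusion rules can operate on them.

### Numerical evaluation

The reference evaluation discretizes the decision variable on [0°, 360°] at
dx = 0.05° (the wide bound accommodates extreme memory noise) with **bin
midpoints** as nodes. Midpoint placement matters: nodes at 0, 0.05, …
double-count the fold point and inflate total mass by φ(Δ/σ_T)·dx/σ_T
(≈ 0.5% at the representative σ_T), whereas midpoint bins conserve mass to
truncation accuracy for all (Δ, σ_T). No renormalization is applied; the
truncation loss beyond 360° is bounded by a test (≤ ~1.4·10⁻³ even at the
extreme corner σ_T = 60, Δ = 180, and negligible in the fitted regime).
σ_T = 0 is handled as a point mass at Δ.

Inside the optimizer the same quantity is evaluated faster, to
≲ 10⁻³ absolute everywhere and ~10⁻⁵ typically (the residual being the
reference grid's own quantization of the threshold into dx bins):

- σ_dec = 0: the step-function sum has the exact folded-CDF closed form,
  truncated at 360° like the grid;
- 0 < σ_dec ≤ σ_T: exact step term plus the logistic correction
  ∫ (expit((x−δ)/σ_dec) − 1[x>δ])·pdf(x) dx, integrated on nodes spaced
  0.05·σ_dec over |x−δ| ≤ 12·σ_dec (the kernel decays like e^−|u|), with
  exactly symmetric nodes so the kernel's jump sits on an exact zero and
  fractional bin weights at the support boundaries;
- σ_dec > σ_T: 129-node Gauss–Hermite quadrature in the memory trace
  (there the integrand varies on the slower decision-noise scale and the
  fold kink at zero is weak).

Choice probabilities are computed once per unique (delay, Δ) cell (keyed at
10⁻⁹ degrees, evaluated at the unrounded Δ) and broadcast to trials.

## Fitting, model comparison, recovery

The objective is the cross-entropy between binary responses and predicted
"different" probabilities (natural log; predictions clipped to
[10⁻¹², 1−10⁻¹²]). Six variants are fit; all free σ_mem and δ, and the
others add θ (variant 2), λ (3), σ_dec (4), θ+λ (5) or all three (6), with
absent parameters fixed at 0. Default bounds: σ_mem ∈ [0.01, 60],
δ ∈ [0.01, 180], θ ∈ [0, 0.5], λ ∈ [0, 1], σ_dec ∈ [0.01, 60] — wide
relative to the task geometry (Δ ≤ 180° at delays up to 9 s).

Minimization uses an in-house seedable global-best particle swarm
(constriction coefficients ω = 0.7298, c₁ = c₂ = 1.49618, positions clipped
to bounds, vectorized cost over the swarm), reference configuration 100
particles × 1000 iterations. Early stopping triggers after 75 iterations
without 10⁻⁹-nat improvement, deterministically. Scaled-down swarms can
occasionally collapse into a degenerate local mode (σ_mem ≈ 0 with all
errors attributed to lapses, seen for variants 5 and 6); `PSOConfig.n_restarts`
reruns the swarm from fresh seeded initializations and keeps the best
minimum, which eliminates these collapses at modest cost. The test suite
and acceptance script use 30–40 particles, 300–600 iterations and 2
restarts; this reliably reaches the same minima as larger swarms on the
3-parameter objective.

Variants are compared by BIC = 2·CE + k·ln(n) (natural log; the identity is
asserted bit-exactly on every fit result), winner = lowest across-subject
mean. Parameter recovery simulates datasets of 189 trials (three blocks,
regenerated per dataset with distinct seeds) at the representative
across-subject generating values σ_mem = 4.2856, δ = 11.1370, θ = 0.0203,
λ = 0.0049, σ_dec = 3.0802 — each variant using the values of its own free
parameters — refits, and summarizes each parameter's recovered distribution
by the FWHM of a normal density fit (2√(2 ln 2)·σ̂). Recoverability of the
shared parameters degrades sharply when σ_dec is freed (variants 4, 6),
because a shallow decision slope can mimic memory noise; this motivates
restricting BIC comparison to the step-threshold variants, where the
lapse variant (2) wins on data where it is the ground truth.

## Behavioral summaries

Trial exclusion removes invalid-button trials, RT ≤ 0.2 s, and
RT > subject mean + 4 SD; the mean/SD are computed in a single pass over
the subject's valid-button trials (including sub-0.2 s trials — the rules
are applied jointly, not iteratively). Trials without RT pass the RT
filters. Subjects are excluded when overall accuracy is strictly below
60%; the boundary is kept (an agent that always answers "different" scores
exactly 2/3 under the 21/21/21 mix and survives the screen).

Signal detection: H = P("same" | match); FA is computed separately for near
and far nonmatch trials and then averaged. Extreme rates are corrected to
1/(2N) and 1 − 1/(2N) before the probit transform (the standard correction;
whether the original analysis corrected is unstated). d′ = z(H) − z(FA).
The criterion is reported as c = z(H) + z(FA), matching the convention used
alongside this model; a flag exposes the textbook −½[z(H) + z(FA)].

## Optimal-threshold analysis

Expected accuracy is computed analytically as the weighted mixture over the
task's (delay, category, Δ) cells: categories at their block proportions,
delays equiprobable, and far-Δ weights marginalized over equiprobable
sample locations (uniform over each location's admissible multiples). The
performance-maximizing threshold δ* minimizes 1 − P(correct) by
Nelder–Mead simplex seeded from a 0.25° grid scan (deterministic); a
"simulated" mode instead minimizes 1 − accuracy of 189 freshly simulated
trials per evaluation, reproducing the noisy-objective variant of the
analysis; the two agree within binomial error. θ, λ and σ_dec are fixed at
0 during the sweep unless overridden.

The default sweep covers 100 levels of σ_mem on [0.5, 12] deg·s^−1/2, the
plausible range of fitted values in this task regime (the representative
fitted value is 4.29). The upper limit is deliberate: beyond roughly
σ_mem ≈ 14 the accuracy surface flattens onto the always-"different" floor
(P = 2/3) and the global optimum collapses toward δ* = 0, so the
noise-threshold relationship is only meaningful where the task still
carries discriminative information. Within the default range δ* is
monotone nondecreasing in σ_mem (r ≈ 0.996), the normative signature of
strategic threshold adjustment. Ties as σ_mem → 0 (any separator in
(0, spacing) is optimal) resolve near spacing/2.

## Cognitive composite scores

The ten PCA-eligible battery tests are semantic fluency, phonemic fluency,
Boston Naming Test, word-list learning/recall/recognition, constructional
praxis and its recall, and trail-making A and B (MMSE is excluded from the
PCA). Recognition enters the PCA as the discriminability score
(1 − ((10−H) + (10−CR))/20)·100 from hits and correct rejects out of 10,
and enters the six-test total as true positives − false positives — two
different printed definitions, both implemented. Tests are z-scored across
subjects (sample statistics, ddof = 1); the TMT z-scores are sign-flipped
so higher always means better; subjects with incomplete batteries are
dropped with a warning. The covariance matrix (not correlation — the
distinction is only an n/(n−1) scale once inputs are z-scored) is
decomposed by SVD; PC1 loadings are oriented so their sum is positive (the
SVD sign being arbitrary), and the PC1 score is each subject's projection.
The six-test total is semantic fluency capped at 24 + BNT + word-list
learning + recall + (TP − FP) + praxis.

## Temporal-generalization metrics

A TGM A holds decoding precision (correlation units) for train time x and
test time y on a uniform 0.05 s axis. Two scalar summaries over the delay
window [0.5, 1.5] s: the off-diagonal sum Σ A_{x,y} (x ≠ y), and the
wide-shift sum restricted to |x − y| ≥ 0.5 s, which removes spurious
generalization from temporal smoothing of the underlying estimates (0.4 s
analysis window). Dynamic coding is tested per cross-time element by
comparing A_{x,y} against both A_{x,x} and A_{y,y} with two-sided
across-subject sign-flip permutation tests (exhaustive when 2^n ≤ 4096,
else seeded Monte Carlo including the identity flip so p ≥ 1/n_perm), both
families of p-values Benjamini–Hochberg corrected jointly; an element is
dynamic iff both adjusted p < 0.05 and cross-time precision is reduced.
The permutation scheme (sign flips of paired differences) and the joint
FDR family are our resolutions of choices the procedure leaves open.

## Synthetic data: what it emulates and what it does not

`wmdrift.synth` generates every input with recorded ground truth, all
seed-deterministic:

- **Cohorts**: per-subject parameters from truncated normals within the fit
  bounds, per-subject block counts in {1, 2, 3} with default probabilities
  (0.1, 0.2, 0.7) emulating incomplete data collection; trials from the
  task module, responses from the model.
- **Batteries**: a single dominant shared factor with unit loadings plus
  independent noise (default 1:1 variance), mapped onto realistic test
  scales (e.g. word-list learning 0–30, BNT 0–15, recognition counts out of
  10, TMT seconds inverted so slower = worse). Scales are plausibility
  choices, configurable, since none are prescribed.
- **TGMs**: a rank-one rise-and-sustain profile (stable code), the same
  attenuated by a Gaussian band of width 0.15 s in |x − y| (dynamic code),
  or pure noise; additive Gaussian noise at a given SNR.

Synthetic cohorts reproduce the model's own statistical structure by
construction, so passing recovery tests demonstrates the estimation
machinery (identifiability, optimizer adequacy, selection consistency) —
not that real behavior follows the model. Real data would add RT
structure, sequential dependencies, non-stationary lapse rates and
unbalanced designs that these generators deliberately omit; the exclusion
rules are exercised with constructed RT tables instead.

## Problem sizes and known limitations

The shipped studies use 100 recovery datasets for the selected variant, 25
per variant for the recoverability comparison, a 20-subject cohort for
selection, 10⁶-trace Monte-Carlo oracles for the forward model, and 100
noise levels for the threshold sweep — sizes chosen so each analysis runs
in seconds to a few minutes on one CPU while leaving the qualitative
patterns stable across seeds.

Limitations: the BIC margin between the lapse variant and its neighbours is
small at 189 trials/subject (selection is reliable at the cohort level, not
per subject); FWHM estimates at 25 datasets carry visible sampling noise;
the grid reference quantizes the threshold to 0.05° bins, so fits are
meaningful only to that resolution; and the wide-shift TGM sum is undefined
(flagged, 0) when the shift exceeds the window span.
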