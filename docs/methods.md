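# Methods

## Task and generative design

The simulated experiment is a two-alternative distribution-discrimination
task with external noise.  Orientations (degrees; negative = CCW, positive
= CW, 0 = vertical) are drawn from N(−μ, σ²) for Distribution 1 or
N(+μ, σ²) for Distribution 2, each with probability ½ per trial.  Two
conditions are blocked and strictly alternating (4 runs × 4 blocks × 50
trials = 800 trials; the first block's condition is chosen from the seed):

| condition | μ (deg) | σ (deg) | max d′ = 2μ/σ |
|-----------|---------|---------|----------------|
| low       | 2.4     | 6       | 0.8            |
| high      | 7.2     | 18      | 0.8            |

The high-variability condition is an exact 3× scaling of the low one, so
the ideal decision criterion (orientation = 0) and the maximum attainable
sensitivity are identical across conditions, while optimal confidence
criteria differ by the factor 3.

## Simulated observers

Observers respond through criteria placed directly in orientation space: a
fixed decision criterion t₀ = 0 and six confidence criteria
t₋₃ ≤ t₋₂ ≤ t₋₁ ≤ 0 ≤ t₁ ≤ t₂ ≤ t₃ defined on the low-variability scale.
A single attraction factor α couples the conditions: the low-variability
condition uses α·tᵢ, the high-variability condition 3·tᵢ/α.  Their
element-wise ratio is 3/α² for every α > 0, attraction preserves criterion
ordering, and α = √3 makes the two sets coincide.

The percept is the orientation plus additive Gaussian internal noise
(default SD 0°).  The zero default reflects that full-contrast, long-
duration gratings carry very little orientation noise; with zero internal
noise, percept-space and stimulus-space criteria coincide, and empirical d′
converges to the 0.8 ceiling.  When nonzero, the noise is applied to the
orientation before criterion comparison.  The choice is D2 when the
percept exceeds t₀ and confidence is one plus the number of same-sign
criteria exceeded, capped at 4.  Region boundaries are half-open and
lower-inclusive (a percept exactly at a criterion takes the region above
it) — a measure-zero convention fixed for reproducibility and used
identically by the simulator and the fitted model.

Default base criteria are ±3°, ±6°, ±9°: under the default designs these
spread responses over all four confidence levels in both conditions.  RTs
are cosmetic (lognormal, median 855 ms, equal across conditions, so
simulated data echo the RT equivalence of the design) and are never used by
any analysis.  An optional within-block schedule relaxes α exponentially
from a start value at trial 1 toward an asymptote, emulating attraction
being strongest right after a block switch.

What the generator does **not** emulate: internal-noise-driven lapses,
criterion jitter across trials, learning from the trial-by-trial feedback,
serial dependencies, or any RT–confidence coupling.  Passing tests on these
simulations therefore validate the estimation and fitting machinery under
the design's statistical structure, not the full richness of human data.

## Congruence balancing

A trial is congruent when its orientation polarity matches its generating
mean's polarity (orientation exactly 0° is classed incongruent, a
measure-zero convention).  Sampling variability leaves the two conditions
with slightly different congruent counts, hence different attainable
accuracy.  If one condition has m more congruent trials, the m latest
congruent trials of that condition and the m latest incongruent trials of
the other are excluded (single backward scan over session order — a
deterministic reading of removing trials "from the end").  Afterward both
congruence classes have equal counts across conditions; exactly 2m trials
are removed; already-balanced data pass through unchanged.  Under the
default design the expected exclusion rate is ≈2.6% (Monte-Carlo envelope
1.8–3.3%).

One property worth knowing: because the balanced congruent count is
essentially the minimum of the two conditions' realized counts divided by a
reduced trial total, post-balance d′ is conditioned slightly upward
(≈ +0.03 at 400 trials/condition) — identically in both conditions, so
cross-condition comparisons, the procedure's purpose, are unaffected.

## Criterion estimation

For criterion index i, HRᵢ is computed on true-D2 trials (FARᵢ identically
on true-D1 trials) as the proportion of trials in the nested event: for
i ≥ 0, a D2 choice with confidence > i (i = 0: any D2 choice); for i < 0, a
D2 choice at any confidence or a D1 choice with confidence ≤ −i.  These
events are nested, so HRᵢ and FARᵢ are weakly decreasing in i by
construction.  Criterion locations follow
tᵢ = −½(Φ⁻¹(HRᵢ) + Φ⁻¹(FARᵢ))·σ with σ the condition's *generating* SD (6
or 18): using an effective SD is unnecessary because 1° of internal noise
moves the optimal cross-condition ratio only from 3 to
√(18²+1)/√(6²+1) = 2.964.

Rates of exactly 0 or 1 receive a log-linear correction (add 0.5 to the
event count and 1 to the trial count, for the affected rate only — standard
signal-detection practice); every corrected index is flagged on the
estimate.  Attraction is summarized by rᵢ = tᵢ,high/tᵢ,low for the six
confidence criteria; t₀ is compared across conditions as a difference in
degrees since both values sit near 0, where ratios are unstable, and a
confidence ratio whose denominator is within tolerance of 0 is reported as
NaN rather than fabricated.

## Model fitting

The fitted model has seven free parameters (t₋₃…t₋₁, t₁…t₃, α; t₀ fixed at
0).  The likelihood is multinomial over the 16 response types (choice ×
confidence × condition): p_ijk is the proportion of condition k's actual
stimulus orientations that fall in region (i, j) of the attracted criterion
partition.  The model contains no internal-noise parameter, so this mapping
is deterministic; probabilities are floored at 10⁻⁶ and renormalized, which
keeps the log-likelihood finite while leaving well-populated cells
unchanged to ~5 decimals.

Because p_ijk depends on parameters only through which orientations fall in
which region, the likelihood surface is piecewise constant.  The maximizer
is therefore built for plateaus: criteria are reparameterized as signed
cumulative positive gaps (log-increments), guaranteeing ordering for any
unconstrained parameter vector, and Nelder-Mead with a wide initial simplex
runs from ≥10 random starts plus two informed starts — a quantile-matching
start (each region edge placed at the orientation-gap midpoint implied by
the observed counts, per condition, then reconciled into (t, α)) and a
moment start from the SDT criterion estimates.  Bounds: α ∈ [0.5, 3.0],
criterion magnitudes ≤ 60°, enforced by penalty.  The best restart is
returned; failure of every restart to converge is flagged on the result,
not raised.  On 800-trial datasets generated by the deterministic observer
the fit attains the saturated log-likelihood bound and recovers α with mean
absolute error < 0.02; the implied ratio 3/α̂² agrees with the directly
estimated rᵢ.

## Statistics

Condition comparisons use paired t-tests with Cohen's d defined on the
difference scores (d = mean(diff)/SD(diff)); a zero-variance nonzero
difference is flagged degenerate rather than silently propagated.
Bayesian evidence uses the default JZS Bayes factor — a Cauchy(0, √2/2)
prior on standardized effect size, integrated by adaptive quadrature of the
noncentral-t density; BF₀₁ > 3 is read as support for the null.  Criterion
ratios are tested against 3 with Wilcoxon signed-rank tests (ratios are not
normally distributed); a complementary parametric test compares 3·t_low
against t_high per criterion, signed so that positive means the scaled
low-variability criterion is more extreme — the signature of attraction.
Time courses aggregate mean confidence by within-block epoch (block halves,
or five 10-trial epochs).  Individual-difference structure is summarized by
Pearson correlations of the per-subject confidence effect with the d′
effect, the RT effect, and the fitted α.

## Numerical and design choices

- Probability floor 10⁻⁶ (before renormalization) in the model likelihood.
- Ratio denominators |t| ≤ 10⁻⁹ → NaN, never a fabricated ratio.
- Orientation exactly 0° → incongruent; percept exactly at a criterion →
  the region above it.  Both are probability-zero under continuous
  sampling.
- The within-block α schedule uses a per-trial decay *rate*, so a large
  rate reaches the asymptote within the block.
- The confidence-database dialect codes stimulus/response as 1/2 and RT in
  seconds (`RT_dec`), alongside the design columns (orientation, run,
  block, trial); the native dialect is long-format UTF-8 CSV, one trial
  per row, missing RT as an empty field.
- Problem sizes in the test and benchmark suites: 50 cohorts × 26
  participants for the exclusion-rate calibration; one 26-observer cohort
  (800 trials each, ≥10 restarts) per generating α for parameter recovery —
  sizes at which the Monte-Carlo error is comfortably inside the tolerances
  being checked.

## Limitations

- The fitted model is deterministic given the stimulus; it has no lapse,
  internal-noise, or criterion-jitter parameters, so α absorbs any such
  unmodeled variability when fit to real data.
- The likelihood's plateau structure means α̂ is interval-identified at the
  single-subject level (any parameter change that reclassifies no stimulus
  leaves the likelihood unchanged); with 400 orientations per condition the
  intervals are narrow, and cohort means are stable.
- Group-level inference treats subjects as fixed, independent units; no
  hierarchical shrinkage is applied.
- The congruence-balancing selection effect on absolute d′ noted above.
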