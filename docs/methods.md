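# Methods

## The measurement problem

The pupillary light response (PLR) constricts the pupil when luminance
increases.  If covert attention modulates the PLR, then on a display
split into a bright and a dark half the pupil should be slightly smaller
when the cued (attended) side is bright than when it is dark, with
retinal input held constant.  The effect is small (a few percent of
baseline pupil area), slow (arising several hundred ms after the cue),
and sits on top of cue-evoked constriction, task-evoked dilation, blinks
and fixational gaze drift.  The pipeline's job is to estimate the size
and onset of this modulation and relate it to behavioral cueing effects.

## Generative model of the synthetic data

The generator produces the noise-free pupil trace

```
x(t) = baseline × [ 1 − A·G(t − t₀)  +  r·t  −  s·(m/2)·g·ramp(t − t_a) ] + noise
```

* **PLR kernel** `A·G(u)`: a shape-2 gamma CDF (`G(u) = 1 − (1+u/τ)e^(−u/τ)`,
  τ = 150 ms, amplitude A = 0.30 of baseline area), used only when the
  cue is visual.  The *latency* of the constriction is defined the way a
  velocity criterion measures it: the drawn latency (per-trial
  N(241, 25) ms) is the time at which the noise-free trace's velocity
  reaches 0.5 normalized size/s, and the kernel onset `t₀` is shifted
  earlier by the numerically solved criterion-crossing time.  This makes
  the latency parameter directly recoverable by the analysis and keeps
  its semantics independent of the kernel shape.
* **Task-evoked dilation** `r·t`: linear ramp from cue onset,
  r = 0.03 /s — slow effort/arousal dilation, present for both cue types.
* **Attention term**: a ramp starting at the divergence onset `t_a`
  (defaults 716 ms for the visual-cue design, 656 ms for the auditory
  one) saturating over 500 ms; sign `s` is +1 when the cued side is
  bright, −1 when dark, amplitude m/2 each way so the dark-minus-bright
  asymptote equals the modulation parameter m (default 0.035).  A
  per-trial lognormal *attention gain* `g` (log-SD 0.5, unit mean)
  scales the term and simultaneously shifts RTs (−100 ms per unit gain
  on valid trials, +100 ms on invalid), producing the trial-level
  coupling between pupil modulation and cueing effect that the
  rank-order bin analysis is designed to detect.
* **Noise**: 1% white measurement noise plus 1.5% slow drift
  (Ornstein–Uhlenbeck, time constant 500 ms), approximating tracker
  noise and hippus.  The drift is what makes the consecutive-run
  divergence criterion non-trivial under the null.
* **Blinks**: Poisson (10/min), ~120 ms dropouts with 20 ms linear
  occlusion shoulders, giving the spline reconstruction a realistic
  target.  **Gaze**: OU drift (SD 0.4°, τ = 300 ms) plus tracker noise;
  the trial-mean horizontal position supplies the bias that the pairing
  control removes.

Behavior: RTs are shifted lognormal (shift 200 ms) with validity-specific
means (535/685 ms for the speeded design); error rates 11%/20% for the
speeded design; for the accuracy design, correctness follows a cumulative
Gaussian psychometric function of the staircase-controlled
signal-to-noise ratio, with an attention penalty added to the threshold
on invalid trials.  Observer samples draw correlated attention traits (a
latent strength couples pupil modulation to the behavioral effect,
coupling 0.6), giving realistic between-subject correlations.

**Staircase.**  The up/down rule with 5% multiplicative steps is
implemented in two variants: a weighted rule whose up step is twice the
down step (equilibrium p·down = (1−p)·up ⇒ converges at 2/3 correct —
consistent with the ≈66% accuracy the design targets), and the
transformed 1-up-2-down rule (converges at 70.7%).  The weighted variant
is the default; the rule name "2-up-1-down" is ambiguous between the
two, so both are exposed and the convergence accuracy is computed from
the rule, never hard-coded.  Staircases run separately for targets on
the bright and the dark background and update on validly cued trials.

### What the generator does *not* emulate

Foreshortening of the pupil image with gaze angle, binocular effects,
saccades/microsaccade dynamics (gaze is pure drift — consequently the 2°
gaze filter discards almost nothing, unlike the ~33% in typical human
data), luminance-dependent baseline changes, and the real-time
gaze-contingent gray-band display (emulated only as the 2.8° horizontal
discard rule).  Passing tests therefore demonstrate correctness of the
*analysis* under a plausible signal model, not robustness to every
artifact of real recordings.

## Analysis choices

* **Blink reconstruction**: cubic spline through the four control
  samples at gap ± one and two 50 ms margins (the margin covers the
  occlusion shoulders at 1000 Hz); on exactly four points the
  not-a-knot spline is the unique interpolating cubic, which the test
  suite verifies against a brute-force Vandermonde solve.  Edge blinks
  fall back to linear fill and are flagged.
* **Velocity criterion**: central finite difference over a 50 ms window;
  the 0.5 pupil-size/s threshold is interpreted in baseline-normalized
  units (configurable).  This is the single documented exception to the
  no-smoothing rule.  In the pipeline the latency is estimated on each
  participant's mean cue–target trace: averaging ~100 trials suppresses
  the noise velocity (which would otherwise cross the criterion
  spuriously on single trials), and the recovery test shows the drawn
  latency is recovered with < 10 ms mean error on noise-free traces.
* **Selection order** (gaze → timeout → RT → pupil → pairing) follows
  the narrative order of the protocol; each discarded trial carries
  exactly one reason code and the report records the order, so per-rule
  fractions are interpretable.  Outlier bounds use the single-pass
  mean/SD including the candidate outlier (no iterative trimming).
* **Gaze-bias pairing**: within participant × attend condition, trials
  with opposite-sign biases are matched when the magnitudes agree within
  0.14°.  For opposite-sign pairs the readings |b₁+b₂| < tol and
  ||b₁|−|b₂|| < tol are algebraically identical, so one criterion
  implements both.  Matching uses a two-pointer sweep over the
  magnitude-sorted sides; because each trial's compatible partners form
  a contiguous run in the sorted opposite side, the sweep attains
  maximum cardinality, which the tests confirm against Hopcroft–Karp on
  every random instance up to 12 trials.
* **Pointwise condition test**: the default is a paired t-test across
  participants' condition-mean traces, vectorized over time; a
  trial-level mixed model (participant random intercept) per time point
  is available but orders of magnitude slower, with the same asymptotics
  for balanced designs.  Non-converged time points count as
  non-significant.  The 200-consecutive-sample run criterion is treated
  as a 200 ms duration and rescaled to the sampling rate in use (50
  samples at 250 Hz).
* **Modulation area**: trapezoidal rule on the native grid (exact for
  piecewise-linear traces), signed, over 1000–2000 ms of the cue–target
  epoch.  Condition means at each time point use only the trials still
  extant there (no imputation); counts are reported alongside.
* **Bin pairing**: valid trials RT-ascending, invalid RT-descending,
  four contiguous bins each, remainder to the earliest bins, ties broken
  by trial id.  Bin-level effects are non-increasing by construction.
  Note that the *unweighted* mean of bin effects is slightly biased when
  bin sizes are unequal (larger extreme bins get less per-trial weight);
  aggregate statements use size-weighted means.  Bin-level modulation
  uses the union of the bin's valid and invalid trials (a valid-only
  variant would halve the trial counts per condition and was not
  needed).
* **Inference**: mixed models are fit by REML with Wald inference
  (statsmodels `MixedLM`); singular fits fall back to OLS with
  cluster-robust standard errors, flagged in the output.  This replaces
  the MCMC-based p-value estimation of the original protocol with
  standard approximations.

## Numerical and degenerate-input conventions

Half-open epoch windows [start, end) with t = 0 at the epoch-defining
event; fully missing traces and non-positive or fully interpolated
baselines invalidate a trial; SD = 0 disables the outlier bound; a
constant per-participant vector makes the correlation and Cohen's d
undefined (raised, not silently NaN); identical conditions yield p = 1
rather than NaN at time points with exactly zero difference.

## Problem sizes and calibration studies

Simulation studies run at 250 Hz (the generator's fast grid; 1000 Hz is
the default for single-trial work).  The null calibration uses 50
simulated experiments of 8 observers × 48 trials with zero modulation
and equal RT means: the divergence detector fired in 0/50 runs and the
95% CI of the grand-mean area contains 0.  Parameter recovery uses 20
replicates of 15 observers × 120 trials with m = 0.035 and onset 700 ms:
the detected onset stays within 700 ± 100 ms (the detector has an
intrinsic power delay of a few tens of ms, since the effect must grow
before the pointwise test turns significant) and the grand-mean relative
difference within 3–4% in 20/20 replicates.  The acceptance script runs
both full designs (15 × 160 and 15 × 240) in well under a minute each.

## Known limitations

The consecutive-run onset criterion controls false positives only
heuristically under serially dependent noise; with stronger or slower
drift than modeled here its false-fire rate rises.  The detected onset
is biased late by the power delay, more so for smaller effects or fewer
observers.  Between-subject effect sizes depend directly on the assumed
observer heterogeneity (SD 0.02 around m = 0.035), which is only loosely
constrained by published data.  The pairing control assumes biases are
symmetric around zero; a constant offset in fixation would discard many
trials rather than bias the estimate.
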