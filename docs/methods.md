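# Methods

## The task and the quantities computed

The package analyses constant-force production with four fingers of one
hand.  The task is defined at the *virtual finger* (VF) level: the sum of
the four finger forces must track a constant target `f_T` (18 N by
default) for 20 s per trial while the subject hears auditory feedback on
the deviation — tone frequency modulated at 7 Hz/N (condition F), tone
intensity at 0.7 dB/N (condition I), or both (condition FI), around a
1000 Hz / 70 dB reference tone.  Only the 6–17 s plateau of each trial is
analysed; windows are half-open `[start, end)` so an 11 s window at
1000 Hz has exactly 11000 samples.

### Hierarchical variability decomposition

For trial `i`, the VF force is written `y_i(t) = X_i(t) + E_i + m`, where
`m` is the grand mean over all samples of all trials, `E_i` the deviation
of trial `i`'s mean from `m`, and `X_i(t)` the demeaned within-trial
signal.  The overall mean-squared error

```
OMSE = (1/N) Σ_i mean_t (f_T − y_i(t))²
```

then partitions exactly as

```
OMSE = σ̄_X²  +  σ_E²  +  b²
       online    offline   systematic
```

with `σ̄_X²` the within-trial variance averaged over trials
(consistency), `σ_E²` the variance of trial means (repeatability), and
`b = f_T − m` the bias (accuracy).  At the finger level each VF variance
equals the sum of the four finger variances plus the summed between-finger
covariance (ordered pairs `i ≠ j`, i.e. twice the upper triangle); the
covariance sum is the synergy index — negative means error compensation,
positive error amplification.  The summed finger variance additionally
splits along the uncontrolled-manifold geometry of the force-sum task:
with Jacobian `J = (1,1,1,1)` and `u = J/‖J‖`, the task-relevant variance
is `uᵀΣu = Var(VF)/4` and the task-irrelevant variance is
`trace(Σ) − uᵀΣu`, the variance inside the null space of `J`.

**Normalization.** All variances and covariances are population
(divide-by-N) moments.  The additive identities above are exact only
under one consistent convention, and the package treats them as exact
(tested at 1e-10 relative tolerance); sample (N−1) normalization would
break them by trial-count-dependent factors.

**Per-dimension convention of the task-relevant variance.** Reporting
`Var(VF)/4` (variance per dimension of the one-dimensional task-relevant
subspace) makes the task-relevant component carry exactly the same
statistical information as the VF variance itself; the alternative
convention without the 1/n factor only rescales it.  No detrending is
applied within trials; `X_i(t)` is deviation from the trial mean only, and
no filtering is applied to measured data anywhere in the analysis path.

### Bayesian cue fusion

Each single-cue condition yields a cue summary: an estimation variance
`σ_c²` and a bias `b_c = f_T − m_c`.  Under the flat-prior Gaussian
fusion model the combined condition is predicted by inverse-variance
weighting:

```
w_F = σ_I²/(σ_F²+σ_I²),  w_I = 1 − w_F
σ_FI² = σ_F² σ_I² / (σ_F² + σ_I²)
b_FI  = w_F b_F + w_I b_I
OMSE_FI = σ_FI² + b_FI²
```

The fused variance never exceeds the smaller single-cue variance — the
fusion benefit.  The model ignores the biases when forming the posterior
(they enter only through the weighted bias of the prediction) and uses no
informative prior; both are deliberate modelling assumptions, not
options.

**Which variance counts as estimation variance.** The per-condition VF
variance mixes online and offline timescales and the model does not
separate them; the default attributes the *total* VF variance (online +
offline) to the cue's estimation variance.  `variance_mode="online_only"`
is provided for sensitivity analysis.  Because the fusion formulas are
degree-1 homogeneous in the variances, a common multiplicative
attenuation of all three conditions' variance estimates (finite trial
counts, autocorrelation of the online noise) cancels between the
predicted and observed sides, which is what makes the
predicted-vs-observed comparison calibrated at finite sample size.

### Group statistics

Per-subject measures go into a one-way repeated-measures ANOVA (sums of
squares partition; `df1 = k−1`, `df2 = (k−1)(n−1)`), optionally with the
Greenhouse–Geisser sphericity correction (epsilon from the
double-centered condition covariance matrix, clamped to
`[1/(k−1), 1]`; both dfs are scaled).  Post hoc pairs use Fisher's LSD:
pairwise t with the pooled ANOVA error term on the error dfs, unadjusted
— the omnibus test is the gatekeeper.  Paired and one-sample t-tests are
two-sided; zero-variance inputs return flagged degenerate results
(`t = 0, p = 1` for no difference) instead of raising.  Learning effects
are screened by OLS of the per-trial VF mean and variance (averaged over
subjects within a condition) on trial number, with the slope F-test.
The pipeline applies the Greenhouse–Geisser correction by default.

## The synthetic cohort generator

Human data for this paradigm are not publicly deposited, so the package
ships a generator that emulates the experiment's statistical structure;
it is first-class, tested code and defines the conditions under which the
pipeline is validated.

Per subject × condition, the VF-level model is: trial plateau
`f_T − b_c + D_i` with offline deviation `D_i ~ N(0, (1−ρ)σ_c²)`, plus
within-trial noise with variance `ρσ_c²`.  The online noise is white
Gaussian noise low-pass filtered at 2 Hz (2nd-order Butterworth applied
forward-backward, rescaled by the filter's impulse-response energy so the
stationary variance is exact).  The experiment does not constrain the
noise spectrum; a low band limit reflects the slow character of
physiological force drift and keeps the 11 s within-trial variance
estimate realistically imprecise.  A raised-cosine ramp (2 s) connects
0 N to the plateau at both trial ends so that window extraction is
meaningful.

**Finger allocation and coupling.** The VF signal is shared among the
fingers by a fixed sharing vector (default 0.30, 0.30, 0.22, 0.18 — an
index≈middle>ring>little profile; nothing downstream depends on it).  The
coupling parameter `κ ∈ [−1, 1]` controls the between-finger covariance
per timescale: for `κ ≥ 0` a fraction `κ` of the VF-level noise variance
is a single common source distributed by the sharing vector (covariance
sum `κ·v·(1−Σs_k²) ≥ 0`, error amplification) and the rest is independent
finger noise allocated proportionally to sharing; for `κ < 0` the VF
noise is all independent and additional zero-sum noise with total finger
variance `|κ|·v` is injected in the null space of the force sum
(covariance sum `κ·v < 0`, error compensation with the VF variance
unchanged).  The default `κ = 0.3` reflects the positive covariances
observed with auditory feedback.

**Condition parameters.** Defaults: `σ_F² = 0.9 N²`, `σ_I² = 0.7 N²`,
`b_F = 0.5 N`, `b_I = 0.35 N` — sub-newton VF-force scatter and a slight
undershoot, plausible magnitudes for auditory-only feedback at an 18 N
target.  FI defaults to the Bayes-fused variance and bias of the
subject's own F and I parameters, so generated cohorts embody the fusion
hypothesis exactly; both can be pinned explicitly to generate
fusion-violating cohorts.  The online fraction `ρ` defaults to 0.5; it is
a free parameter rather than being matched to any particular finger-level
observation.  Between-subject heterogeneity is a common lognormal factor
(sd 0.25 on the log) scaling both single-cue variances and a common
Gaussian shift (sd 0.15 N) on both biases; keeping the factor common
across conditions preserves each subject's self-consistency under
fusion.  For parameter-recovery checks the scatter is disabled so
estimates are compared with configured values directly.

**Randomness.** One root seed; every subject, condition, and the
subject-parameter draw use `numpy` `SeedSequence` streams derived
deterministically from it.  Same seed ⇒ byte-identical output.

**What the generator does not emulate.** Stationary Gaussian noise within
the window only: no tremor peaks or 8–12 Hz physiological bands, no
within-trial drift or serial dependence between trials (no learning or
fatigue — the trend tests are expected null here), no enslaving matrix
between fingers beyond the single shared source, no sensor noise or
quantisation.  Passing tests therefore show that the estimators and the
fusion logic are correct and calibrated under the model's own
assumptions, not that real behaviour satisfies those assumptions.

## Problem sizes used in the test and acceptance runs

Study-scale defaults (10 subjects × 3 conditions × 15 trials × 20 s) are
kept for the pipeline and the reported run.  Because the online noise
lives below 2 Hz, the decomposition is insensitive to the sampling rate,
and cohort-scale simulations sample at 250 Hz (self-consistency sweeps)
or 200 Hz (parameter recovery at 200 trials × 11 s windows over 20 seeds;
coupling-direction sweeps over a κ grid with a fixed 15-seed batch);
protocol constants (11000-sample window) are always verified at the full
1000 Hz.  The ANOVA type-I calibration uses 2000 null simulations of
10 × 3 tables.

## Numerical and degenerate-input choices

- Window membership uses a 1e-9 s tolerance against the sample grid to
  keep `[6, 17)` exact under floating-point time stamps.
- `ucm_split` requires symmetry (1e-8 relative) and rejects non-4×4
  input; PSD-ness is not enforced (averaged sample covariances can have
  tiny negative eigenvalues).
- CSV round-trips are exact: values are written with `%.17g` and parsed
  with round-trip float precision.
- Degenerate statistics (zero-variance differences, identical condition
  profiles) return flagged results with the conventional limits rather
  than raising; `trial_trend` on an exact line reports `F = inf, p = 0`.
- Condition-order counterbalancing has no computational effect on any
  quantity here and is not modelled.

## Known limitations

- The repeated-measures ANOVA reports the standard error dfs
  `(k−1)(n−1)`; printed F-statistics from other sources that use a
  different denominator-df reporting convention will differ in df but not
  in F.
- The fusion model is congruent-cue only; incongruent feedback and
  learned priors are out of scope.
- The tone map assumes positive gain (overshoot raises pitch/loudness);
  the experiment's sign convention is not documented, and the choice only
  relabels the feedback direction.
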