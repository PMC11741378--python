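# Methods

## Problem and model

After cardiac surgery, patients with temporary dual-chamber pacing can be
haemodynamically optimised by tuning the atrioventricular delay (AVD): the
programmed interval between atrial and ventricular stimuli. Arterial blood
pressure (ABP) responds to AVD with a single-peaked, approximately quadratic
curve; central venous pressure (CVP) responds as its smaller inverted mirror
image, because anything that improves forward output simultaneously raises
arterial and lowers venous pressure. `avdopt` implements the full analysis
chain for protocols that alternate between a reference AVD (120 ms) and each
tested AVD (40–280 ms in 40 ms steps) with replicated transitions.

The response model is

```
y(x) = a x^2 + b x + c,        x_opt = -b / (2a)
```

where `y` is the mean pressure change of a tested AVD relative to the
reference and `x` the AVD in ms. For ABP the physiological curve is concave
(`a < 0`, a maximum); for CVP it is convex (`a > 0`, a minimum).

### Per-transition deltas

Every setting change contributes one replicate: the mean per-beat feature
(systolic ABP peak; peak or mean CVP) over a window of `W` beats immediately
after the transition minus the same window immediately before, signed as
tested-minus-reference. The beat during which the setting changes belongs to
neither window. `W` is 6 beats by default, or the number of beats spanning
one respiratory cycle (`round(HR / (60 f_resp))`) in respiratory-cycle mode.
Both transition directions are pooled after sign correction, doubling the
replicate count; `use_both_directions=False` restricts to
reference-to-tested transitions. Replicates at one AVD give a mean and SEM;
AVDs with fewer than two surviving replicates are excluded.

### Optimum and its uncertainty

The per-AVD means are fitted with an inverse-variance-weighted quadratic
(zero-SEM points receive the smallest nonzero SEM; all-zero SEMs fall back
to an unweighted fit). Treating the SEMs as known standard deviations, the
coefficient covariance is the inverse weighted normal matrix. SE_opt, the
horizontal standard error of the vertex, is computed two ways:

* **Delta method** — first-order propagation through `x_opt = -b/2a` with
  gradient `(b/2a^2, -1/2a)`; fast, default.
* **Parametric bootstrap** — resample each per-AVD mean from
  `Normal(mean, SEM)`, refit, and take the SD of vertices over replicates
  with a correctly oriented, non-degenerate fit. When more than half the
  replicates are discarded the bootstrap SE is flagged unreliable (NaN).

The two agree within a few percent away from degeneracy; when they disagree
by more than 50% the bootstrap value (more robust when `a` is nearly 0)
feeds the quality gate. Fits with `|a| < 1e-12 mmHg/ms^2` are degenerate:
the vertex is undefined and the SE infinite. Vertices may extrapolate beyond
the tested grid but are flagged beyond ±40 ms outside it.

### Quality control

Two gates, applied per channel: (i) orientation — the fitted parabola must
open the physiologically correct way (concave ABP, convex CVP); (ii)
uncertainty — SE_opt must be *strictly less than* the threshold, default
50 ms. Both failures are reported as reasons, never raised.

### Respiratory correction

Respiration moves CVP by roughly as much as the pacing effect itself, so it
is removed before beat extraction. Respiratory frequency is estimated as the
Welch-periodogram peak in 0.05–1 Hz (60 s windows); the peak must exceed 5×
the band median and carry ≥0.1% of total signal variance, otherwise
"respiration not detected" is raised and callers fall back to hints or the
fixed window.

* **ALS** minimises `sum w_i (y_i − z_i)^2 + lam sum (Δ² z_i)^2` with
  `w_i = p` above the baseline and `1−p` below, solved by a banded Cholesky
  factorisation per iteration. Defaults: `p = 0.5` (midline tracking; the
  classic small-`p` lower envelope is available), `lam = 1e7 · (fs/250)^4`,
  placing the smoother's cutoff (~0.7 Hz) between the respiratory and
  cardiac bands at any sampling rate; 10 iterations.
* **DWT** uses a shift-invariant stationary wavelet transform (`sym8`,
  reflected padding to a dyadic length) and reconstructs only the detail
  levels whose dyadic band overlaps `[f_resp/1.5, 1.5 f_resp]`. Shift
  invariance avoids edge artefacts at pacing transitions.

Subtraction is level-preserving (`y − r + mean(r)`), so absolute mmHg values
survive. The pipeline corrects CVP only by default: ALS applied to ABP can
*add* noise, because arterial beat-to-beat amplitude variability (SD ~4 mmHg
on a 40 mmHg pulse) leaks below any smoother cutoff that still passes
respiration; `correct_abp=True` exposes the option regardless.

### Agreement statistics

Spearman rank correlation (midranks for ties; exact permutation p-values
below n = 10, t-approximation above) is used throughout because replicate
deltas are strongly heteroskedastic. Reported statistics: the pooled
per-transition CVP-vs-ABP correlation (the mirror image; negative when the
venous signal is informative), the correlation between per-subject SE_opt
and the |ABP − CVP| optimum gap (uncertainty predicting disagreement),
Bland–Altman bias and 1.96·SD limits of agreement between the two channels'
optima, and the signal-to-noise ratio: best-minus-worst observed per-AVD
mean divided by the average per-AVD SEM (observed means, not fitted values;
cohort summary is the median).

## Synthetic generator

`generate_subject` emulates the protocol: atrial pacing at 90 bpm, a
reference lead-in, then for each tested AVD the configured number of
test/reference state pairs. Defaults are the study conditions: 7 tested
AVDs (40–280 ms), 8 replicates, best-to-worst effect 11.4 mmHg (ABP) and
4.15 mmHg (CVP, inverted), respiratory peak-to-trough 2.5 / 2.3 mmHg
(ABP / CVP) at 0.25 Hz with Poisson-timed inspiratory amplitude spikes
(2/min, ×2.5, scaled by `resp_irregularity`), and Gaussian per-beat
amplitude noise (SD 4 mmHg for ABP; CVP noise scaled by the effect ratio
4.15/11.4 so the two channels share a comparable signal-to-noise ratio, as
observed clinically). The default true optimum is 180 ms; cohorts draw
optima from U(100, 320) ms and respiratory frequency from U(0.18, 0.35) Hz
— the realistic adult range, which also prevents the fixed 6-beat window
from coinciding with one respiratory cycle in every subject.

Waveform morphology is fixed; only the per-beat peak amplitude carries the
AVD effect. ABP beats are raised-cosine pulses peaking at 30% of the cycle
over a 40 mmHg pulse pressure; CVP beats have two raised-cosine peaks per
cycle (a-wave at 15%, v-wave at 57% with 0.75 relative height) over a
5 mmHg venous pulse. Peaks are snapped to the sample grid so the sampled
maximum equals the configured per-beat peak exactly, which is what makes
noiseless recovery exact to numerical precision. Each state lasts 13 beats
so that the 6-beat windows of neighbouring transitions are disjoint
(6 + straddling beat + 6) and replicate deltas are statistically
independent; shorter states correlate adjacent replicates and bias the SEM
low. Settings take effect 0.35 of a beat before the first beat of the new
state, so exactly one beat straddles every transition. An optional 0–2 beat
exponential settling transient is available and off by default.

What the generator does **not** emulate: ectopy and arrhythmia,
ventilator-synchronised breathing, baseline drift, measurement quantisation,
catheter damping, and intrinsic AV conduction cutting the protocol short.
Passing tests therefore demonstrate correctness of the analysis under the
protocol's statistical model, not robustness to every artefact of real
intensive-care recordings.

## Numerical and design choices

* The reference-vs-reference transition (tested 120 ms, expected delta 0)
  is included as an ordinary point in the fit.
* Events are `(time, avd)` pairs; direction is reconstructed from strict
  protocol alternation (even events enter a tested state), which also
  disambiguates the tested-120 case. Validation rejects streams whose
  odd-indexed events disagree on the reference setting.
* Beat onsets are anchored at the pulse foot (minimum preceding the
  upstroke); detection requires one dominant peak per pacing cycle with
  ≥0.6-cycle separation, so the taller venous a-wave wins over the v-wave.
  Detected-rate deviation beyond ±25% of the pacing rate only warns.
* CSV I/O writes floats with 17 significant digits and reads with
  round-trip precision, making write/read cycles bit-lossless.
* Monte-Carlo test and acceptance runs use 100 Hz sampling and 200–500
  subjects per experiment; these sizes give Monte-Carlo error comfortably
  inside the asserted tolerances.

## Known limitations

* SEMs are treated as known when weighting and propagating; with 16
  replicates per AVD the residual bias in SE_opt is a few percent,
  within the calibration tolerance but visible.
* The delta method degrades near-degenerate fits (`a → 0`); the bootstrap
  gate covers this but reports NaN when most bootstrap replicates are
  mis-oriented — such subjects should simply be measured longer.
* ALS on arterial signals can increase beat-level noise (see above).
* The exact-permutation Spearman p-value enumerates up to 9! orderings;
  it is intended for the small-cohort case only.
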