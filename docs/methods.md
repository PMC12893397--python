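# Methods

`orgwave` analyzes optical recordings of hybrid 2D/3D cardiomyocyte
cultures: a central beating organoid whose cells spread outward into a 2D
monolayer. Two per-cell signals are quantified — a calcium-indicator
fluorescence trace and a brightfield motion trace — and the package adds
spatial segmentation around the organoid, a 2D/3D synchrony test, and a
classifier for arrhythmia-prone calcium morphology. Because the kind of
microscopy data it targets is rarely shareable, the package ships a
synthetic scene generator with exact ground truth; every estimator in the
analysis chain is validated as a round trip through that generator.

## The transient template and its calibration

A calcium transient is modelled as a piecewise C1 waveform with four free
parameters:

* a **raised-cosine upstroke** of duration `t1`, rising to a fraction
  `h1 = 0.45` of the apex amplitude `A`; its maximum derivative is
  `S = (π h1 / 2) · A / t1`, so the upstroke carries the transient's
  maximum rate of rise — as in real cells, where release is fastest early
  in the upstroke;
* a **quadratic shoulder** of duration `d` easing into the apex with end
  slope `2(1−h1)A/d` (strictly below `S`);
* an **exponential recovery** with time constant `τ`, accelerated ten-fold
  once the signal falls below 12% of the apex, so the trace genuinely
  settles at the diastolic baseline between beats. The acceleration sits
  well below the 20%-of-maximum level and therefore does not touch any
  measured functional; without it the waveform approaches its asymptote
  so slowly that the baseline is unidentifiable from sampled data.

The four functionals used throughout — left width at 20% of maximum
(release), right width (reuptake), maximum rise slope, and the area above
baseline between the 20% crossings — have closed forms in
`(A, t1, d, τ)`:

```
τ  = R / ln 5
t1 = (π h1 / 2) A / S
d  = L − (1 − tc) t1,   tc = arccos(1 − 0.4/h1) / π
U  = a_up·A·t1 + ((1+2h1)/3)·A·d + (0.8/ln 5)·A·R     (quadratic in A)
```

so calibration to target functionals is an exact algebraic solve, not a
fit; infeasible targets (e.g. an AUC no amplitude can satisfy, or a
release width shorter than the upstroke the slope demands) raise a named
error. A simpler family — logistic rise times exponential decay — cannot
reach the functional combinations this package targets: after removing
the time and amplitude scales it has one shape degree of freedom for two
dimensionless constraints (`R/L` and `U/(S·L²)`), and numerical scans
show its reachable set misses the required values by 30–60%. The
template above was designed so that all four functionals are independent.

Contractile beats are piecewise-linear pulses. With the 10% onset/offset
convention used by the beat segmenter, a linear limb of duration `T`
contributes exactly `0.9 T` to the measured phase, so a systole target of
`s` seconds is rendered as a rise of `s / 0.9`. This makes the beat
ground truth exact by construction.

## Default presets (the simulated study conditions)

Per condition, group-mean kinetics parameterize the generator:

| quantity | control | dox |
|---|---|---|
| width at 20% max (ms) | 556.2 (182.1 + 374.1) | 1063.2 (393.6 + 669.6) |
| max rate of rise (a.u./ms) | 0.090 | 0.060 |
| AUC (a.u.·ms) | 2823 | 4745 |
| rhythm (s) | 1.1876 | 2.0 |
| beat: systole/diastole (s), organoid | 0.207 / 0.281 | 0.207 / 0.281 |
| beat: systole/diastole (s), 2D cells | 0.159 / 0.252 | 0.293 / 0.400 |
| mean surrounding cells | 111.2 (Poisson) | 81.29 (Poisson) |
| beating fraction | 0.729 | 0.485 |
| radial density scale (µm) | 220 | 140 |
| abnormal fraction Center→Far | .30/.42/.55/.68 | .45/.63/.82/.92 |

The control rhythm follows from the organoid beat duration (0.4881 s)
and its period-normalized ratio (0.411 s/s). No dox beating rate is
reported for this preparation; 0.5 Hz is a physiologically sensible
bradycardic rhythm that leaves the doubled transient a diastolic
interval. The dox systole/diastole values sum to 0.693 s, which the
generator uses as the beat duration (the additive identity is enforced
exactly). Regional gradients are mild monotone time factors
(0.94/1.00/1.06/1.12 Center→Far); the gradient direction is the modelled
claim, not specific per-ring values. Abnormal fractions rise with
distance and average to ~0.50 (control) and ~0.69 (dox) under each
group's radial occupancy.

Per-cell heterogeneity is a unit-mean lognormal time factor (CV 8% for
calcium, 6% for beats). Cells carrying a morphology-level abnormality
additionally slow by 1.3× (which blunts the maximum slope to ~0.77×) —
except spontaneous-release cells, which instead keep normal kinetics and
lose 25% of amplitude: a diastolic SR leak depletes the releasable pool,
and (geometrically) a 1.3×-slowed control transient would leave no
settled diastole for the leak events themselves. The total time factor
is capped so the transient settles within 92% of the cycle; a
periodically driven cell cannot sustain a transient longer than its
cycle, and uncapped draws produced overlapping transients with no
identifiable baseline.

Noise is additive Gaussian with SD 2% of the cell's amplitude. Default
drift is a slow ramp (10% of amplitude over the recording) plus a
sinusoid (3% of amplitude, 10 s period, random phase), included to
exercise the drift-removal stage. Recordings default to 15 s at 50
frames/s; the acquisition rate is not reported for the target
preparation, so it is configurable, and the resolution guard requires at
least five samples per release phase.

### Abnormal morphology injection

* **bifid** — the apex is replaced by a W: linear dip to 62% of `A` over
  70 ms, partial recovery to 88% over 90 ms, then exponential decay from
  there. The sub-peaks sit 160 ms apart — inside the 200 ms
  peak-detection separation, so the pair reads as one transient for any
  kinetics, while both maxima stay far above the 20% level.
* **plateau during uptake** — the rise is held flat mid-shoulder for 50%
  of the rise duration (a third of the extended rise).
* **early second upstroke** — every third beat starts while the previous
  transient is still at 50% of its amplitude; the off-grid beats keep the
  cell quantifiable between episodes.
* **spontaneous release** — a sub-threshold Gaussian bump (15% of
  amplitude, σ 45 ms) at a random diastolic phase between the settled
  tail and 157 ms before the next onset; spontaneous release is not
  phase-locked in real cells.

Additive bumps were tried for the bifid morphology first and rejected:
on a fast decay any bump wide enough to survive smoothing merges with
the limb and loses topological prominence. The W-shaped apex is
kinetics-independent.

### Phase locking

All cells beat at the organoid's rhythm. After synthesis, each cell's
trace (with its noise and drift realization held fixed) is iteratively
shifted — including sub-sample phase, estimated from a parabola through
the correlation peak — until its cross-correlation against the shipped
organoid trace peaks at lag zero with margin. Synchrony is therefore a
construction invariant of the generator, and the analysis-side
cross-correlation test recovers it.

## Measurement chain

**Drift removal** subtracts a rolling 5th-percentile baseline (window
4 s). The 5th percentile still tracks the floor when a prolonged
transient occupies ~85% of the cycle, where a higher percentile climbs
onto the decay. Shrinking edge windows bias a one-sided percentile, so
the edge halves are replaced by the linear trend of the adjacent
interior baseline; a pure linear drift is then removed to numerical
precision. Finally the trace is shifted so the median of its quiet band
(samples within 4 noise SDs of the 5th percentile) sits at zero.

**Noise SD** is estimated from the MAD of second differences (σ =
1.4826·MAD/√6). Second differences cancel locally linear signal, so the
estimate tracks frame noise rather than transient slopes even at high
duty cycles — a first-difference estimator is inflated several-fold by
the transients themselves.

**Peak detection** is prominence-based (scipy), with the prominence
floor referenced to the span between the trace maximum and the
quiet-band floor (not the median, which sits mid-transient for prolonged
kinetics); plateau ties resolve to the left-most sample. Defaults:
prominence 20% of span, minimum separation 200 ms — separating beats at
any plausible rhythm while keeping intra-transient structure (bifid
sub-peaks) inside one detection.

**Per-peak morphometry.** The local baseline is the quiet-band median of
the two adjacent inter-apex intervals (anchored at their 10th
percentile). Taking the median of the whole band — rather than of the
lowest samples — keeps the estimate unbiased under noise; selecting on
low value alone biases it by about −1.6 noise SDs. Amplitude is the apex
sample corrected for the expected sampling deficit of a wedge-shaped
peak (`sL·sR/(2(sL+sR))` per sample, with limb slopes from short
disjoint fits either side of the apex); the apex *time* itself remains
the maximum sample, uncorrected. The 20% crossings are found walking out
from the apex with a two-sample debounce and linear interpolation at the
bracketing pair; width20 = left + right holds exactly because both
widths share the same interpolated crossings. AUC is the trapezoid above
the local baseline between the crossings, including the fractional end
segments. The maximum rate of rise uses a Savitzky–Golay(5, 3)
derivative — a 4th-order-accurate differentiator — with parabolic
sub-sample refinement of its peak and a small curvature-based correction
for the residual attenuation (clamped at 10%); a raw forward difference
is ~6% low noise-free (the 20 ms box under-samples the upstroke) and
>10% high under noise (maximum over noisy differences). Peaks whose
crossings collide with a neighbouring apex or the trace edge are flagged
and excluded from per-cell means. Time-to-peak is measured from the 20%
rise crossing to the apex (and therefore equals the left width); the
crossing-referenced definition is the noise-robust reading of an
otherwise ambiguous convention.

With these estimators, ensemble means over 150+ noisy cells recover
every generator target within ~1.5% (widths, AUC) and ~2% (control
slope); the residual biases are dominated by apex-time discretization
(the apex sample sits up to half a frame from the continuous apex).

**Contractility.** From a stack or 1D motion trace: speed is the mean
absolute frame difference, amplitude the mean absolute difference from a
reference frame chosen automatically as the frame minimizing summed
absolute difference to its 10 temporal neighbours among the
lowest-quintile-speed frames (the resting phase). Beats are segmented
with a dynamic threshold (rolling 10th percentile baseline + 10% of the
rolling local span, 3 s window) so baseline steps between beats do not
move onsets or offsets; beats within one window of a step are in the
threshold's adaptation zone and may be dropped. Two guards make the
non-beating call robust: a recording whose amplitude range is within 6
noise SDs is non-beating, and apexes must clear a prominence floor
(25% of global span), because in long quiet stretches the local
threshold collapses onto the noise. Onset/offset are threshold crossings
with the same debounce-and-interpolate scheme; systole + diastole =
beat duration exactly by construction. Period normalization divides each
beat's phases by its own apex-to-apex period; single beats are flagged
as undefined.

**Spatial segmentation** partitions the plane into Center (the organoid
disk, radius taken from the organoid ROI), and Close/Mid/Far annuli of
185 µm spacing; boundary radii belong to the inner region (a
deterministic convention — the data cannot distinguish the alternatives).

**Synchrony** is per-lag Pearson correlation over ±2 s of lags with ties
broken toward zero lag.

## Rule-based morphology labeling

The four expert criteria are transcribed into deterministic rules,
evaluated on a lightly smoothed trace (SG 7/2; the plateau rule uses
SG 9/2) with thresholds referenced to the estimated noise SD:

1. **bifid/multi-spiked** — ≥2 local maxima above 20% of amplitude
   within one transient's support, each with prominence ≥ max(3σ, 5% of
   amplitude);
2. **plateau during uptake** — some window of ≥25% of the rise whose
   total increase is below min(5% of the max slope sustained over the
   window, 2% of amplitude). Window totals are testable at 20 ms
   sampling; pointwise derivative thresholds at this level drown in
   noise;
3. **early second upstroke** — the signal never returns below 40% of a
   peak's amplitude before the next apex (evaluated over all measured
   peaks, because overlapping transients defeat width measurement);
4. **spontaneous release** — a diastolic excursion that both rises above
   the running minimum of the gap and falls back by the same amount
   (band: max(3σ, 5% of span) to 20% of span). The rise-and-return form
   keeps full sensitivity to bumps riding the decay tail while ignoring
   the next beat's sub-threshold foot, which rises without returning.

Plateau and spontaneous release recur every beat, so both require
corroboration on a second beat/gap before the cell is labeled; this
suppresses single-gap noise artifacts. A cell is abnormal iff any rule
triggers. On noise-free scenes the labeler agrees with generator ground
truth at 100%; at default noise ~99%.

## Classifier

Per-cell averaged features (amplitude, time to peak, inter-peak time,
full/left/right widths, max slope, AUC, frequency) feed an RBF-kernel
SVM under stratified 10-fold cross-validation with a grid search over
C ∈ {1e-3 … 1e3} (decade steps across the printed range; mean CV
accuracy selects C, ties toward the smaller value). Standardization is
fit inside each training fold (scikit-learn pipeline), so no statistics
leak from held-out folds. The report pools out-of-fold predictions into
one confusion matrix (abnormal = positive) and builds the ROC from
decision-function scores; its AUC equals the Mann–Whitney statistic of
the scores, which the tests verify by brute force. The default
benchmark is 500 cells per condition, labeled by the rules at default
noise.

## Statistics

Group contrasts use two-tailed pooled-variance Student's t-tests (Welch
behind a flag); regional contrasts use one-way ANOVA with Tukey's HSD
from the studentized-range distribution (scipy). Zero-variance
degeneracies return t = 0 / p = 1 for equal means and are flagged for
unequal means. No correction is applied across metrics. Cells are
treated as independent; organoid-level clustering is a known limitation.

## What the generator does and does not emulate

It emulates: group-mean transient and beat kinetics and their additive
identities, a shared rhythm with lag-zero synchrony, Poisson cell counts
with exponentially thinning radial placement, monotone regional
gradients, mixed abnormality labels with morphology injections, frame
noise and slow baseline drift. It does not emulate: photophysics
(bleaching, indicator saturation), cell migration, non-circular
propagation geometry, inter-cell timing jitter, or non-stationary
rhythms. Passing round-trip tests therefore demonstrates that the
estimators are unbiased under the stated noise/drift model at 50 frames
per second — not that they are robust to every artifact of real
microscopy.

## Problem sizes

Defaults keep everything desk-scale: recovery ensembles use 100–200
cells per condition (ensemble SEM ~0.6% of the mean, well inside the 2%
recovery checks), scenes use Poisson-mean cell counts, and the
classifier benchmark uses 1000 cells. The full test suite runs in about
two minutes; the acceptance script in about three.
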