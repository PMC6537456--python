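# Methods

`myofatigue` emulates and analyzes a single-group neuromuscular fatigue
experiment: 15 subjects perform 60 five-second isometric maximal voluntary
contractions (MVCs) of the knee extensors, with a measurement block at
control and after every 10 MVCs (7 time points).  Each block contains an
MVC with a superimposed 100-Hz doublet, a potentiated resting doublet and a
potentiated single twitch (femoral-nerve stimulation), surface EMG of the
vastus lateralis, and a 5-s resting shear-wave elastography clip of the
vastus lateralis with passive-torque and EMG monitoring.

The package has two halves that share no hidden state: a **synthetic
cohort generator** that renders raw signals from drawn ground truth, and an
**extraction + statistics pipeline** that recovers the physiological
metrics from those signals alone.  All validation rests on that separation:
the pipeline never reads the truth it is checked against.

## Generative model

For every measured quantity q (MVC peak torque, doublet amplitude
Db_pot100Hz, twitch amplitude Tw_pot, EMD, CT, HRT, MRTD, VAL, M-wave
amplitude, RMS/Mmax, resting shear modulus mu, passive measures), a subject
draws once:

* a baseline `B ~ N(ctrl_mean, ctrl_sd)`, truncated at 5% of the control
  mean (physiological positivity), and
* a signed fractional end change `d ~ N(end_change_mean, end_change_sd)`
  for quantities that change with fatigue (d = 0 otherwise),

and follows the trajectory `v(t) = B * (1 + d * g(t))`, where
`g(t) = (m_t/m_0 - 1) / (m_end/m_0 - 1)` is the normalized group-mean
change shape (g = 0 at control, 1 at exercise end; intermediate values from
the calibration table's group means).  The cohort mean of per-subject end
changes equals the configured mean by construction; between-subject spread
at intermediate time points is inherited from d and g, not separately
calibrated.  Quantities are drawn independently across subjects and across
quantities; any in-vivo correlation between, say, MVC loss and modulus loss
is not modelled (a correlation hook is deliberately left out).

Default calibration (means +/- SD, and end changes): MVC 352 +/- 68 Nm
(-38.4 +/- 12.6%), Db_pot 114.3 +/- 14.3 Nm (-38.2 +/- 10.8%), Tw_pot
77.9 +/- 10.2 Nm (-49.4 +/- 12.6%), EMD 28.8 +/- 10.8 ms (+21.9 +/- 6.8%),
CT 47.7 +/- 9.5 ms (+20.4 +/- 10.4%), MRTD 4.8 +/- 3.3 Nm/ms
(-51.0 +/- 12.7%), mu 9.3 +/- 2.0 kPa (-34.7 +/- 6.7%); VAL (89.0 +/-
3.9%), HRT (128.2 +/- 39.7 ms), MRTR, Mmax (5.2 +/- 2.8 mV), RMS/Mmax
(0.06 +/- 0.02) and the passive measures are held constant per subject.

Note that the configured end change is the *mean of per-subject ratios*;
it differs from the ratio of group means (e.g. MVC: -38.4% vs -40.1%), so
a zero-variance cohort reproduces the group trajectory shape scaled to the
mean-of-ratios end point, not the printed group means verbatim.

Feasibility adjustments (all preserve per-subject percent changes):

* VAL clipped to (0, 100]; HRT clipped to [20, 340] ms so the decay
  constant stays within the solver bounds.
* The dimensionless twitch shape factor `s = MRTD * CT / P` is kept in
  [1.45, 4.5] at every time point by rescaling the subject's whole MRTD
  trajectory.  The lower bound is near-mathematical (no rise reaching its
  peak at CT can have maximal slope below the mean slope P/CT; the
  waveform family's floor is ~1.4 P/CT); the upper bound excludes
  spike-like rises far outside the observed ~2.9-3.2.  A common rescale
  changes the MRTD baseline, never the percent change.
* Passive EMG truths are clipped to <= 0.008 mV: the emulated study
  contains only scans that passed the relaxation gate, so rendered scans
  are relaxed by construction.  (The exclusion path is exercised in tests
  with deliberately contaminated sessions.)

## Twitch waveform family

The unit-peak twitch is piecewise, with each target feature exact:

* **rise** on [0, CT]: saturating exponential
  `B (1 - e^(-tau/tau_r))^2`, joined C1 to a **quadratic apex cap**
  `1 - a (tau - CT)^2` that covers the last 10% of the rise (apex exactly
  at CT);
* **decay**: the same quadratic continues past the apex until it joins,
  C1-continuously, an exponential whose time constant is solved so the
  waveform crosses half-peak exactly at CT + HRT.

The quadratic cap exists for an identification reason: a purely saturating
rise is exponentially flat near its peak, so the sampled argmax (which
defines measured CT) wanders several ms under measurement noise and,
because the flat side is the rise side, wanders asymmetrically - a
systematic early bias that grows with fatigue and corrupts the CT
time-course.  A locally symmetric quadratic apex makes the sampled argmax
an unbiased estimator (measured residual bias < 0.05 ms at the default
noise).  The rise time constant `tau_r` is solved by 1-D root finding so
that the *measured* normalized MRTD - computed with the same 2-kHz
sampling, 5-sample moving average and central difference the extraction
pipeline uses - matches the target exactly; targets outside the family's
range ([~1.4, ~13] P/CT) are clamped with a flag.

The 100-Hz doublet is the linear sum of two twitches 10 ms apart, rescaled
to unit peak (no force-frequency saturation model).  The maximal rate of
torque relaxation (MRTR) is emergent from this shape model rather than
independently calibrated; consequently the generator's MRTR declines
roughly with twitch amplitude, unlike the emulated study's flat MRTR row -
a known infidelity with no downstream consumer.

## Trial rendering

One measurement block is a 13.25-s, 2-kHz torque + EMG record: 0.5 s rest,
0.25-s cosine ramp, 5-s plateau at `MVC * (1 + N(0, 0.01))` (trial-to-trial
plateau variability), superimposed doublet 3.0 s into the plateau, cosine
ramp-down, potentiated doublet 3 s after cessation and single twitch 3 s
later.  Additive torque sensor noise is N(0, 0.05 Nm).

The superimposed evoked increment has amplitude
`Db_pot * (1 - VAL/100)` (interpolated-twitch identity) and is rendered as
a brief transient: natural doublet rise (time-compressed only if the peak
would land beyond 90 ms post stimulus), accelerated 12-ms-half-life decay,
and a raised-cosine taper to exact zero 145 ms after the stimulus.  In a
near-maximally active muscle the evoked extra force is indeed brief, and
confining it makes the +/-150 ms guard used by the MVC peak reader exact.

EMG: voluntary activity is 10-500 Hz band-limited Gaussian noise scaled so
its RMS over the analysis window (2.3-2.8 s into the plateau, i.e. ending
200 ms before the superimposed stimulus) equals `(RMS/Mmax) * Mmax`
exactly; each stimulus pulse adds a 12-ms Hann-windowed biphasic wavelet
with peak-to-peak amplitude Mmax, 3 ms after the pulse.  The exact EMG
spectrum is an artifact choice; only the RMS and peak-to-peak amplitudes
carry information.

Elastography: a clip is 5 frames (1 Hz) of 40 x 40 speed maps (1 mm
pixels).  Pixel value (m/s) = `sqrt(mu_true) + eta_frame + eps_pixel` with
`eta_frame ~ N(0, 0.045)` shared within a frame and
`eps_pixel ~ N(0, 0.15)` per pixel; the ROI is a centered 12 x 12 px
square (~1.44 cm^2).  These two noise scales reproduce the reported
within-clip frame scatter (~0.26 kPa at control stiffness) and intra-clip
ICC range.  Maps carry *speed*; the mu = rho Vs^2 conversion
(rho = 1000 kg/m^3, shear - not Young's - modulus, reported in kPa) is the
analysis pipeline's job and is applied pixel-wise before ROI averaging
(averaging speed first would bias the modulus low by the within-ROI speed
variance).

Determinism: one seed drives a `SeedSequence` spawned per subject; the
same config + seed reproduce the dataset bit for bit.

## Extraction conventions

* Derivatives: central difference of a 5-sample moving-average-smoothed
  trace, reported per ms.
* Onset (defines EMD): first sample whose smoothed torque exceeds baseline
  mean + max(3 x baseline SD, 0.5% of the evoked peak) *and stays above it
  for 5 ms* (isolated noise excursions at 3 SD are common over a 150-ms
  search window), back-tracked on the raw trace to the last baseline
  crossing.  Exact at the sample level on noiseless traces; mean absolute
  error ~0.7 ms at the default noise.
* Peak: raw argmax within 300 ms of onset (unbiased because the rendered
  apex is locally symmetric); amplitudes (P, doublet amplitudes) are read
  from the smoothed trace (the raw maximum of a flat apex is biased upward
  by noise extremes).  CT = peak - onset; HRT = first half-peak crossing
  after the peak (error if none within 500 ms).
* MVC peak: trace maximum excluding a +/-150 ms guard around superimposed
  stimuli and everything from 0.5 s before the first resting stimulus.
* Doublet baselines: 25-ms pre-stimulus mean; onset baseline: 100 ms.
* VAL = (1 - Db_superimposed / Db_potentiated) x 100, clamped to [0, 100].
* M-wave: max minus min within [2, 50] ms post stimulus.
* Relaxation gate for modulus cells: mean passive torque < 2 Nm and each
  passive EMG RMS < 0.01 mV (strict); failing cells are excluded and
  logged.
* Recruitment curve: optimal intensity = lowest from which all subsequent
  amplitudes stay within 2% of the maximum; supramaximal = 130% of it; a
  plateau that would start at the last point is "still rising" (error).
* MRTD/MRTR are reported raw in Nm/ms (matching the calibration table's
  units); peak-normalized variants (1/ms) are computed and stored on the
  result object but take part in no downstream statistic.

## Statistics

* **RM-ANOVA** (one-way, time as the within factor, balanced):
  `SS_total = SS_subjects + SS_time + SS_error`,
  `F = MS_time / MS_error` on (m-1, (n-1)(m-1)) df, no sphericity
  correction.  A zero error mean square is reported as the sentinel
  F = inf, p = 0 (F = 0, p = 1 when the time effect is also zero).
* **Fisher LSD** vs control:
  `t = (mean_t - mean_0) / sqrt(2 MS_error / n)` on the ANOVA error df,
  two-sided, unadjusted; protected by the omnibus test at alpha = 0.05
  (results carry a `tested` flag; the gate can be bypassed explicitly).
* **ICC / SEM** (intra-clip reliability): two-way consistency,
  single-measure form ICC(3,1) = (MS_subjects - MS_error) /
  (MS_subjects + (k-1) MS_error); SEM = sqrt(MS_error) (typical error).
  Under the balanced model this SEM coincides with SD*sqrt(1-ICC) up to
  the measure-effect term.
* **Power / sample size** (within-factor test): noncentral F with
  `lambda = f^2 n m / (1 - rho) * epsilon`, `df1 = (m-1) epsilon`,
  `df2 = (n-1)(m-1) epsilon`; the smallest n with power >= target is
  returned.  This lambda convention reproduces the classical G*Power
  within-factors result (n = 11 at f = 0.40, alpha = 0.05, power = 0.95,
  m = 7, rho = 0.5, epsilon = 1).  epsilon is exposed for power only; the
  ANOVA itself applies no correction.
* **Relative changes**: cohort change = mean over subjects of per-subject
  `100 (v_t - v_0)/v_0` (mean of ratios).  The ratio of group means is a
  different statistic (see above) and is what `relative_change` returns
  when applied to a group-mean series.

## Validation design and problem sizes

The test suite checks, among others: noiseless round trips (every
extracted metric equals its ground truth within 1% or ~1 sample - timing
intervals bounded by two sample-quantized endpoints are allowed 1.5
samples); recovery of the calibrated mean per-subject end changes on
15-subject cohorts (single cohort within 2 SD/sqrt(15); the mean over 20
replicate cohorts within 1.5 points); first-principles sums-of-squares
oracles and pingouin cross-checks for ANOVA/LSD/ICC; null p-value
uniformity (2,000 replicates, KS test); a 10,000-replicate Monte-Carlo
confirmation of the analytic power curve; and scale/shift invariance
properties (hypothesis).  `scripts/acceptance.py` reports the cohort-level
estimates as means over 10 replicate 15-subject cohorts - replication
reduces the sampling error of the reported estimate (single-cohort SD is
~2.7-3.3 points for the change statistics) without touching the per-cohort
study conditions.

What passing these tests shows - and does not.  The generator reproduces
the *calibrated statistical structure* (means, SDs, change distributions,
noise scales) with idealized waveforms.  It does not emulate: motor-unit
EMG structure, force-frequency saturation in doublets, torque-angle
effects, tendon mechanics, correlated per-subject changes across
quantities, drift or probe motion in elastography, or a realistic MRTR
time course.  Recovery on this cohort therefore validates the extraction
and inference machinery, not the physiological model of any real muscle.

## Known limitations

* CT and EMD estimates carry sample quantization (0.5 ms at 2 kHz) and,
  under noise, ~1 ms jitter for shallow twitches; the estimators are
  unbiased by design but per-cell errors are not negligible for small
  effects.
* The EMD onset rule's small late bias under noise (~0.3-0.5 ms) largely
  cancels in relative changes but not in absolute EMD.
* MRTR is emergent, not calibrated (see above).
* The ICC point estimate at n = 15 subjects has substantial sampling
  spread (~2-8% of runs fall below 0.967 even when the true ICC is 0.983);
  reliability statements about a single cohort should quote its confidence
  interval, not the point estimate alone.
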