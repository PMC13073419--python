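# Methods

## The measurement problem

In REM sleep behavior disorder (RBD) the atonia that normally suppresses
movement during REM sleep fails, and motor activity during REM becomes a
diagnostic signal. Limb EMG, infrared video and wrist actigraphy each observe
a different physical correlate of that activity — muscle activation, visible
displacement, and limb acceleration — so no single modality is a gold
standard. `remact` treats the three as binary raters on a common time base
(3 s mini-epochs within REM sleep) and quantifies their agreement, their
individual burden estimates, and the stage-specificity of movement.

## Activity-count model

One wrist recording is a tri-axial acceleration series in g at the device
rate (default 50 Hz, ±8 g). The pipeline is:

1. **Calibration.** A single global gain is chosen so that the median vector
   magnitude over still windows equals 1 g. A still window is a
   non-overlapping 10 s block whose magnitude standard deviation is below
   0.013 g — roughly 30% above the default simulated sensor noise, and in
   line with the stillness criteria used by wearable autocalibration
   methods. Per-axis offset/gain sphere fitting is deliberately not
   attempted: overnight wrist data rarely explore enough orientations to
   constrain a sphere fit, and a single gain is testable and sufficient for
   a magnitude-based count. If no window qualifies, calibration fails loudly
   with advice rather than silently skipping.
2. **Resampling** to 25 Hz (polyphase FIR, anti-aliased, linear-extension
   padding so constant signals stay constant), harmonizing devices with
   different native rates.
3. **Magnitude deviation.** The per-sample deviation from gravity,
   `sqrt(x²+y²+z²) − 1`. The classical ENMO statistic clips negatives to
   zero; where the clip happens relative to filtering matters, see below.
4. **Drift removal.** A minimal-order high-pass Butterworth filter meeting
   80 dB attenuation at 0.1 Hz and ≤ 1 dB ripple above 0.5 Hz, applied
   forward–backward (zero phase) as second-order sections. Stability is
   verified from the pole radii; DC is rejected exactly.
5. **Rectify, bin, round.** Negative filtered values are clipped to zero,
   samples are averaged in 1 s bins (partial tail bins dropped, never
   padded), and counts below 0.1 are rounded down to zero — the threshold is
   a strict "less than", so exactly 0.1 survives.
6. **Epoch classification.** A 3 s mini-epoch is active iff the maximum of
   its 1 Hz counts exceeds zero.

### Where the filter runs

Two orderings are plausible: filter the 1 Hz binned count series, or filter
at 25 Hz before binning. Both are implemented
(`CountsConfig.filter_stage`); the default is `"raw"` (filter at 25 Hz, on
the *signed* deviation, then rectify, then bin) for a numerical reason that
the package's tests make concrete:

- At a 1 Hz bin rate the 0.5 Hz passband edge *is* the Nyquist frequency.
  Clamping the edge to 0.45 × rate produces a legal design whose passband is
  the sliver [0.45, 0.5] Hz; a movement that occupies one to three 1 s bins
  has almost no energy there (a two-bin pulse even has a spectral null at
  Nyquist), so the zero-phase pass attenuates a 0.08 g binned burst to
  ~0.001 g and the 0.1 rounding then zeroes everything. Under that ordering
  no epoch is ever classified active.
- Filtering at 25 Hz leaves burst oscillations (≳ 0.5 Hz) untouched while
  removing baseline drift. Rectification must follow the filter: the
  filtered deviation is zero-mean, so averaging it into 1 s bins *before*
  clipping would cancel to zero as well.

The `"binned"` variant is retained for comparison; both variants satisfy the
non-negativity and forbidden-band ((0, 0.1)) invariants.

## Staging, REM periods, and the grid

Hypnograms are 30 s epochs labelled W/N1/N2/N3/R. REM periods are maximal
runs of consecutive R epochs — a single non-R epoch splits a period, the
strictest reading of period segmentation. Periods strictly shorter than
5 min are excluded; exactly 5 min is kept. Each period is tiled from its
onset with 3 s bins (30 s staging guarantees whole bins). All timelines are
seconds from one recording-start origin with half-open `[start, end)`
intervals and 0-based epoch indices, which removes off-by-one ambiguity.
Stream alignment offsets can be estimated from the brisk-arm sync maneuver
by windowed cross-correlation of magnitude signals; a normalized peak below
0.2 triggers a warning and an offset of 0 rather than a spurious shift.

## EMG scoring rule

Within each REM period the atonia baseline is the minimum envelope
amplitude in that period or, if lower, in the preceding non-REM interval —
interpreted as the full interval since the previous REM period (or recording
start), since no fixed look-back is defined. A suprathreshold run
(envelope ≥ 2× atonia) is a scorable burst when its duration lies in
[0.1, 5.0] s; a mini-epoch is active iff it overlaps a scorable burst.
Runs longer than 5 s are *not* scored but are flagged per-epoch as
"sustained activity, unscored" rather than silently dropped — tonic
activity handling is a documented package choice, not an established
convention. A zero atonia baseline makes the 2× threshold undefined and
raises unless the caller supplies an explicit floor. The rule is invariant
under uniform envelope rescaling, which the tests assert.

## Agreement statistics

For a modality pair (A, B) the 2×2 table has A on rows and B on columns
(`a` = both active, `b` = A only, `c` = B only, `d` = neither); all reported
probabilities name the direction explicitly. Cohen's κ uses the standard
chance-corrected form and returns NaN when both raters are constant
(expected agreement 1). Conditional probabilities with a zero conditioning
margin are NaN, never a division error. Pooled odds ratios across
participants use the Mantel–Haenszel estimator with a Haldane–Anscombe 0.5
correction applied to any table containing a zero cell and a
Robins–Breslow–Greenland log-scale confidence interval; epoch-pooling is a
deliberate non-default because participants differ widely in prevalence.
Multi-epoch events count as independent active epochs in κ and probability
analyses; run-merging (onset-to-offset) applies only to the activity rate,
where runs never span REM periods. Group summaries bootstrap participants
with replacement (B = 10,000, percentile method, fixed seed).

## Stage-wise statistics

Movement load is the summed left+right 1 Hz counts per minute within each
stage; an absent stage is a missing value, never zero, and unilateral
recordings are flagged. Stage contrasts use two-sided Wilcoxon signed-rank
tests (zeros dropped before ranking, exact null for small n, p = 1 when all
differences vanish) with Holm correction over the six pairwise combinations
of {N1, N2, N3, R} — the conservative family, configurable; wake is
computed but not tested. Between-group contrasts use Mann–Whitney U with
Cliff's δ and Benjamini–Hochberg FDR across the four sleep stages.

## Synthetic data: what it does and does not emulate

The generator's defaults describe an RBD-like night: Markov-chain staging
at the 30 s scale (REM self-transition 0.94, mean bout ≈ 8 min, so most
bouts survive the 5 min filter); stage-dependent homogeneous Poisson motor
events, 1.2/min in REM versus 0.1–0.5/min in NREM; log-normal durations
(median ≈ 1.5 s, σ = 0.8) and peak amplitudes (median ≈ 0.6 g, σ = 0.6 —
with the 0.1 g count threshold this yields an effective actigraphy
sensitivity near 0.7, comparable to wrist actigraphy's reported share of
multimodal detections); 35/35/30% left/right/bilateral involvement; flat
per-modality detection probabilities (EMG 0.6, actigraphy 0.6, video 0.35)
with small false-positive rates; accelerometry as a fixed gravity vector
plus 0.01 g Gaussian noise plus raised-cosine-enveloped 2–4 Hz bursts; and
an EMG envelope as an atonia baseline with 3× excursions for detected
events. One global seed expands into named sub-streams (hypnogram, events,
noise, bursts, envelopes, annotations), so each stream is independently
reproducible and bilateral events render identically on both wrists.

Deliberate simplifications, hence what passing tests do *not* show about
clinical data:

- Bursts are aligned with the gravity axis so the magnitude responds
  linearly at small amplitude; real movements have arbitrary, time-varying
  orientation, and purely gravity-orthogonal components enter the magnitude
  only quadratically.
- Events never straddle stage boundaries (truncated at the bout end),
  keeping stage attribution unambiguous; real movements can span
  transitions.
- Annotation detection probabilities are independent of event amplitude, so
  the generator does not by itself reproduce the empirical ordering of
  actigraphy count magnitude by multimodal consensus; that ordering is
  exercised by dedicated constructions in the tests.
- EMG is an envelope only (no waveform, no physiological burst
  morphology); there are no EEG, respiratory or cardiac channels, no
  artifacts, and no device quantization by default (a resolution parameter
  exists but is off).

## Numerical choices and degenerate inputs

Filter designs come from `scipy.signal.buttord`/`butter` in second-order
sections; zero-phase application uses `sosfiltfilt` and rejects series
shorter than the warm-up length. Resampling rationalizes the rate ratio
with a denominator cap of 1000. Binning requires an integer number of
samples per second (resample first otherwise). Tie and boundary behavior is
pinned by tests: the 0.1 count threshold and the 0.1–5.0 s burst window are
inclusive at both ends, 5 min REM periods are kept, and empty strata,
degenerate κ tables and zero conditioning margins yield NaN sentinels.

## Problem sizes

The test suite validates distributional behavior at reduced but adequate
sizes chosen for statistical resolution: detection-probability recovery on a
10 h REM-only night with ~580 latent events (3σ binomial half-width ≈ 0.08);
stage-contrast power over 20 replicates of nine participants on 90 min
block-design nights at 25 Hz. The acceptance script analyses nine full 8 h
nights at the native 50 Hz. All runs are deterministic given their seeds.

## Known limitations

Only the flexor-digitorum-superficialis-style single EMG site is modelled
(no chin/tibialis channels); video labels are always external input (no
pixel analysis); weighted or multi-rater κ and time-warped event matching
are out of scope; and the activity-count filter placement, while argued and
configurable, cannot be settled from the published description alone.
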