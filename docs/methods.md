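# Methods

This note documents the models, conventions and numerical choices behind
scigait, in the spirit of a package methods appendix: what each stage
assumes, which defaults matter and why, what the synthetic generator does
and does not emulate, and the known limitations.

## Signal model and filtering

All analyses consume `SignalChannel`: a uniformly sampled scalar series
with an explicit rate, units (°/s², °, m/s², °/s) and axis label.  Time
columns in delimited files are seconds, 0-based; the rate is inferred from
the median time step.  Sampling must be uniform to within 1 % of that
median step — gaps are rejected rather than imputed, because the
block-FFT walking detector assumes contiguous uniform blocks.  A rate
deviating more than 1 % from the nominal instrument rate (2 kHz IMU,
1 kHz goniometer) is logged as a warning.

**Savitzky–Golay smoothing** is parameterised by frame *duration*:
window = `round(frame_seconds × rate)` forced to the next odd integer
(the algorithm requires odd windows).  The default 3rd order, 0.051 s
frame gives 51 samples at 1 kHz and 103 at 2 kHz.  An order-3 window
reproduces any cubic exactly on interior samples, which the tests verify
to 1e-9.

**Butterworth low-pass** (default 4th order, 10 Hz) is applied
forward–backward (`sosfiltfilt`), i.e. zero-phase.  Gait metrics include
extremum *timing*, and a causal filter would bias every timing estimate
by the group delay; zero-phase application is the biomechanics
convention.  `order` is the per-pass design order, so the effective
magnitude response is squared.

**Resampling** uses polyphase filtering (`resample_poly`) with its
built-in anti-aliasing; constant signals and band-limited content below
100 Hz round-trip within 1 % RMS.

Devices that log angular velocity instead of angular acceleration can be
accommodated with the `differentiate_gyro` schema flag (central
difference).

## Activity quantification

The dorsal-plane magnitude defaults to the absolute smoothed yaw-axis
(dorso-ventral) component — rotation parallel to the horizontal plane of
the animal, i.e. turning left or right.  The wording "parallel to the
dorsal plane" could also be read as the norm of the two in-plane axis
components; both readings are implemented (`mode="yaw"` |
`"in_plane_norm"`), yaw being the default.

Intensity bins are a half-open partition so no sample is double-counted:
Rest `[0, 5)`, Low `[5, 50)`, High `[50, ∞)` °/s².  A value of exactly
5 °/s² is Low — consistent with non-rest being defined as ≥ 5 °/s² — and
exactly 50 is High.  Non-rest % = Low + High.  Recovery = 100 × session
non-rest / mean of the animal's Baseline non-rest values (a single
Baseline session contributes its own value as the mean); change vs
baseline is recovery − 100.  Group values are mean ± SEM over animals
(SD with n−1 denominator; n = 1 is reported as SEM 0 with a flag).
Thoracic and lumbar sensors are binned separately; there is no
cross-sensor fusion.

## Walking detection and gait cycles

Walking is detected on the thoracic medio-lateral component because
forelimb rhythm survives hindlimb paralysis.  The channel (resampled to
1 kHz, low-passed at 10 Hz) is cut into consecutive non-overlapping 5-s
blocks; each block's rectangular-window FFT is searched for its peak
magnitude excluding bins below 0.4 Hz, and the block is walking when that
peak frequency lies in the closed band [2.5, 4.0] Hz.  Five-second blocks
give 0.2 Hz resolution, so the detector cannot distinguish a tone at the
band edge from one half a bin outside it; adjacent walking blocks merge
into one interval whose dominant frequency is taken from the strongest
block.

Gait cycles are delimited **peak-flexion to peak-flexion**: hip traces
carry no foot-contact instrumentation, and flexion peaks are the only
robust landmark.  Peaks need ≥ 5° prominence; cycles outside
[0.4, 2.0] s are discarded; the first 10 valid cycles per session
(chronological, deterministic) are retained.  Each cycle is linearly
interpolated onto 101 points (0, 1, …, 100 % of its duration) and
summarised by max angle (peak flexion), min angle (peak extension),
ROM = max − min, and the percentage of the first occurrence of each
extremum.

Two consequences of peak delimitation are handled explicitly:

* the flexion extremum of every cycle sits at the 0 %/100 % wrap point,
  so timing percentages are **averaged and differenced on the circle**
  (0 ≡ 100).  Arithmetic averaging of per-cycle values like {0, 100, 0}
  would place the peak mid-cycle; the circular mean keeps it at the wrap.
  Away from the wrap the circular mean coincides with the arithmetic one.
* extremum timing is quantised to the 101-point grid, so recovered timing
  is accurate to one cycle-percentage point by construction.

Per-session metrics are the mean of per-cycle metrics; the pointwise
mean ± SEM curve is computed for visualisation but extrema are *not*
re-extracted from it (averaging asynchronous curves damps their peaks).
Left and right hips are processed independently and reported with side
labels.

Baseline-relative deltas: angle terms are 100 × (post − base) / base with
the *signed* baseline in the denominator, so a shallower extension (a
negative angle moving toward zero) reads as a negative extension change —
the convention in which a weaker post-injury extension is a "decrease".
Timing terms are percentage-point shifts along the cycle circle (shortest
arc; negative = earlier).  Zero baseline denominators yield NaN with a
warning.

Eligibility mirrors the behavioural gate: a session enters the
quantitative analysis only if the aggregated PTIBS score exceeds 3 and at
least three valid cycles were found.

## PTIBS

The 10-level rubric ships as editable JSON (`data/ptibs_rubric.json`).
Only levels 1, 2, 8 and 10 plus the category bands (1–3 dragging, 4–6
stepping, 7–10 walking) have verbatim behavioural anchors; the remaining
levels carry paraphrased descriptors consistent with the scale's
structure and are marked `provisional` so users can substitute the
original scale's wording.  Observer scores are integers 1–10; aggregation
defaults to the arithmetic mean (median selectable).  The aggregate's
category is reported only when all observers agree on the band, otherwise
"mixed".  Group summaries and per-animal changes from Baseline are
mean ± SEM as above.

## Synthetic data

The generators are phenomenological — they emulate the statistical
structure each analysis stage assumes, not pig biomechanics.

**Activity sessions** follow an epoch schedule (default: a shuffled
30-min sequence of 30-s epochs hitting prescribed rest/low/high shares).
Within an epoch, the signed yaw signal interpolates linearly between
per-second uniform draws from a per-state magnitude range — rest
(0.2, 3.5), low (7, 45), high (55, 150) °/s² — kept clear of the 5 and
50 °/s² bin edges so smoothing and additive Gaussian sensor noise
(sd 0.5 °/s²) cannot flip a sample's bin.  The label track is exact
ground truth; recovery error is dominated by the short smoothing
transients at epoch boundaries (≈ 0.05 s per 30-s epoch).

**Gait sessions** place walking bouts (default aligned to the 5-s block
grid) in a 60-s recording.  The thoracic medio-lateral channel is a
sinusoid at the configured rhythm (default 3.0 Hz) during bouts over a
background of Gaussian noise plus a 0.8 Hz postural-sway component.  The
sway term matters: a resting animal's trace is dominated by slow postural
drift, whereas spectrally flat noise, once low-passed at 10 Hz, has a
uniformly random dominant frequency and would land in the walking band
~15 % of the time — an artefact of an unrealistically featureless
background, not of the detector.  Default amplitudes (signal 8,
sway 3, noise sd 1.6 °/s²) put the walking tone at SNR 5.

The hip waveform is a periodic template built from two cubic smoothstep
segments joining (pct_at_max, peak flexion) to (pct_at_min, peak
extension) and back, with zero slope at both extrema: it attains the
prescribed extrema exactly at the prescribed cycle percentages, is
monotone in between, and supports asymmetric cycles (pct_at_max ≠ 25 %).
Waveforms start and end on zero crossings so bout edges are continuous;
the right hip runs half a cycle out of phase.  The default hip cycle is
0.65 s: the 2.5–4.0 Hz detection band tracks the (faster) forelimb step
rhythm, while hindlimb stride cycles must fall inside the [0.4, 2.0] s
duration bounds — the two rates are deliberately distinct parameters.
The truth table lists every realised cycle in the analysis convention
(flexion at the wrap point, extension at the arc fraction between peaks).

**Studies** combine both generators with PTIBS observer-score tables into
the full 2-group (DAMAGED n = 3, CONTROL n = 1) × 3-session layout:
complete paralysis at 2-d Post (hips flat, forelimb rhythm preserved, so
walking is detected but no cycles exist and eligibility fails), partial
recovery at 14-d Post with only one DAMAGED animal regaining analysable
gait.  Everything is written as delimited text plus a JSON truth
manifest; fixed seeds give byte-identical output.

What the generators do **not** emulate: postural transitions and composite
behaviours (each sample belongs to exactly one scheduled state),
cycle-to-cycle amplitude/duration variability within a bout, gravity and
orientation artefacts, sensor drift, or any forward biomechanics.
Passing recovery tests therefore demonstrates that the pipeline inverts
its own assumed signal structure at realistic noise levels — not that it
is robust to every artefact of live recordings.

## Problem sizes and determinism

Activity recovery is checked on full-length 30-min sessions at 2 kHz
(in memory); end-to-end gait recovery on 60-s sessions written to and
re-read from delimited files; study-level checks use shortened recordings
(30-s activity, 40-s gait) as a scaled worked example.  Reports contain a
provenance block (config hash, seed, package version) and no timestamps,
so a rerun with the same config and seed is byte-identical.  All
generator randomness flows through `numpy.random.default_rng` seeded
explicitly; study generation draws per-session sub-seeds from a master
generator.

## Limitations

* The walking detector uses peak frequency only (no magnitude threshold),
  faithful to the block-FFT rule it implements; on recordings whose idle
  periods are spectrally flat it will produce false positives, and a
  magnitude gate would then be a sensible extension.
* Cycle extremum timing is quantised to 1 % of the cycle; sub-point
  precision would require parabolic refinement around the extremum, which
  is deliberately not done (metrics are defined on the 101-point curve).
* Whether the 2.5–4.0 Hz band is a step or stride frequency is left to
  the user (`walk_band` is configurable); the default reading treats it
  as the forelimb step rhythm.
* PTIBS levels 3–7 and 9 carry provisional descriptor wording.
* No spatiotemporal stride parameters (speed, stride length), no
  knee/ankle joints, no sensor-fusion orientation estimation, no
  proprietary vendor formats.
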