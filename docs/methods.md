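# Methods

This note documents the models, numerical choices and known limitations of
the `ankle_adl` package: rule-based detectors for walking, turning and
sit/stand transitions from a single ankle-worn IMU, an event-level
evaluation stack, and a scripted signal simulator.

## Signal model and filter bank

A recording is a uniform 50 Hz grid of six channels: acceleration (g) and
angular velocity (rad/s) on three axes.  Channels are addressed by *role*
(`vertical` = along-shank, `medio_lateral`, `anterior_posterior`) through
an explicit `axis_map`, because a consumer watch strapped at the ankle has
no canonical mounting orientation.  Recordings at other sample rates are
accepted — all cutoffs are in Hz — but are never resampled implicitly, and
the rule constants were only exercised at 50 Hz.

All filtering uses second-order Butterworth filters applied
forward–backward (`scipy.signal.filtfilt` with odd-reflection padding of
3× the coefficient length).  Forward–backward application cancels phase:
a symmetric pulse keeps its centre, and a tone at frequency *f* is scaled
by |H(f)|², the squared single-pass magnitude.  The closed-form digital
(bilinear) magnitude is exposed as `butter_zero_lag_gain` and serves as an
analytic reference in tests.  Consequences worth knowing:

* the effective attenuation is doubled on a dB scale relative to a single
  pass, and
* filter energy spreads in *both* time directions: a walking bout "rings"
  into the quiet period before and after it.  The 0.5–0.8 Hz band is only
  0.3 Hz wide, so this ring has a time constant of roughly 1.5 s — the
  dominant practical limit on separating closely spaced walking bouts (see
  *Simulator* below).

Derived signals: `a_bplow` (vertical acceleration, 0.5–0.8 Hz band),
`a_bpwalk` (0.5–3 Hz band), `g_lp` (vertical angular velocity, 0.5 Hz
low-pass, full-wave rectified), `g_mvt` (medio-lateral angular velocity,
4 Hz low-pass; a config switch substitutes the three-axis norm).

## Walking detector

1. **Threshold calibration.**  `mean + 30·sd` (sample sd, n−1) of the
   0.5 Hz high-passed vertical acceleration of a static recording of at
   least 5 s.  The ×30 multiplier dwarfs the n−1 vs n difference.  When no
   static file is supplied, the CLI falls back to the quietest 5 s window
   of the trial itself (logged).
2. **Candidates.**  The threshold is compared against the *rectified*
   `a_bplow`: the band-passed trace oscillates through zero, so a strictly
   one-sided exceedance could never persist 0.4 s.  Sub-threshold dips
   shorter than 1 s are bridged (the same constant as the later
   concatenation rule, keeping the rule set minimal); bridged runs shorter
   than 0.4 s are dropped.
3. **Stationary-step removal.**  Per segment, local maxima of `a_bpwalk`
   (minimum spacing 0.25 s ≈ the fastest plausible step cadence) below a
   quarter of the segment's range are deleted; the segment is re-spanned
   over the surviving peaks.  A one-peak rebuild keeps one extra sample so
   the interval stays non-degenerate; such segments die in step 4 anyway.
4. **Merge and prune.**  Segments closer than 1 s concatenate (peak lists
   merge); segments with fewer than two retained impact peaks are removed.
5. **Boundary refinement.**  The first/last `a_bplow` peak of a segment is
   snapped to the nearest retained `a_bpwalk` impact peak (the wide band
   is sharper in time).  The peak search window extends 0.6 s (about half
   a gait cycle) beyond the current span, because step 3 can re-span a
   segment past the narrow-band peak that belongs to its first impact; if
   no impact peak lies within 0.6 s the original boundary is kept.

Raising the threshold can only shrink total detected walking time
(monotonicity), and the pipeline output never overlaps and stays inside
the recording span; both are property-tested.

## Turning detector

On `g_lp`, stage 1 collects peaks with prominence ≥ 0.1 rad/s; stage 2
keeps a peak if its amplitude strictly exceeds the mean amplitude of all
stage-1 peaks of the trial (a global mean — the simplest consistent
reading) or its prominence reaches 0.8 rad/s.  The 0.1/0.8 constants are
interpreted in rad/s on the rectified filtered signal and live in the
config so a deg/s deployment can rescale them.  Peak width is measured at
half prominence (the conventional relative-height-0.5 definition, which
matches 1–5 s turn durations); each event spans peak ± width/2, clipped to
the recording, and overlapping or abutting events merge.

## Transition detector

The complement of walking within the trial is the set of non-walking
segments.  A segment is *testable* when it can hold a minimal sitting bout
plus two useful edge windows: duration ≥ 2 s + 2 × 0.5 s.  For testable
segments the RMS of `g_mvt` is computed over the sample windows
[0, 25 %), [25 %, 75 %), [75 %, 100 %).  Sitting-down is emitted when
`rms_f > (1 + 0.33) · rms_m`, standing-up symmetrically for `rms_l`.  Two
deliberate choices:

* **Margin reference.**  The printed threshold formula is self-referential
  (an edge RMS can never exceed 1.33 × itself), so the margin is applied
  to the middle-window RMS, the only reading under which "edge greater
  than middle" is well-posed.  The alternative edge-referenced margin
  (`(1 − 0.33)·rms_edge > rms_m`) is available as
  `rms_margin_reference="edge"` for sensitivity analysis.
* **Emitted bounds.**  By default (`transition_bounds="refined"`) the
  emitted segment is the half-height extent of the dominant rectified
  `g_mvt` burst inside the qualifying edge window, which localises the
  transition to a fraction of a second.  The coarser variant
  (`transition_bounds="window"`) emits the raw 25 % edge window; it is the
  behaviour implied by duration-error magnitudes of 2–3 s and is kept for
  comparison.  Window bounds are inherently poor whenever a turn occupies
  the start of the gap, since the window is pinned to the gap start.

An absolute floor of 1e-6 rad/s on the edge RMS rejects windows whose
content is numerical dust on an all-zero channel (relevant only for
noise-free synthetic data; real sensor noise is orders of magnitude
larger).  At zero noise the rule is exactly symmetric under time
reversal: reversing a recording swaps the Sitting-down and Standing-up
outputs, which is property-tested.

## Evaluation

Events are paired one-to-one by temporal overlap with an optimal
assignment (`scipy.optimize.linear_sum_assignment`), maximising the number
of admissible pairs first and total overlap second; a greedy
largest-overlap-first pass can strand a segment that an optimal assignment
would pair.  A pair is admissible when overlap is positive (a configurable
minimum-overlap fraction of the shorter segment tightens this).

TP/FN/FP are event counts from the matching.  Sensitivity and F-score
(`2TP/(2TP+FN+FP)`) are event-level.  Specificity needs a true-negative
count, which is undefined for events; it is computed on the per-sample
(frame) complement, the only well-posed reading, and documented as such.
ΔT compares segment *durations* (end − start), not boundary timestamps;
outliers use the standard 1.5×IQR boxplot rule.  The confusion matrix cell
(A, B) is the percentage of truth-A events overlapping at least one
detected-B segment; its diagonal equals event sensitivity whenever each
prediction overlaps at most one truth event.  With empty truth and empty
prediction, rates are reported as 100 % by convention (logged).

## Simulator

`synthetic_generator` renders an ordered script of activity primitives
into a recording plus ground truth.  Morphology:

* **Walk**: one damped-sinusoid impact burst per stride on the vertical
  acceleration, carrier at the stride rate (default 0.9 Hz), decay 0.8 s,
  peak 1 g, first impact 0.2 s after bout start.  The carrier-at-cadence
  choice gives the train the strong step-frequency fundamental that the
  0.5–0.8 Hz band detects (|H|² ≈ 0.16 at 0.9 Hz), while the decay keeps
  exactly one countable impact peak per stride.  The final burst decays
  past the bout end, as a real last footfall does.
* **StationaryShuffle**: the same train at 20 % amplitude — its narrow-band
  response (~0.03 g) stays well under a typical activity threshold
  (~0.06 g), exercising the stationary-step rules in the failing regime.
* **Turn / SitDown / StandUp**: smooth unimodal `sin(πτ)^0.3` bursts with
  compact support (vertical gyro, peak 1.5 rad/s; medio-lateral gyro, peak
  1 rad/s).  The exponent makes the half-height width ≈ 0.94 of the
  scripted duration, so detected peak widths track scripted activity
  durations, and compact support keeps the gyro channels *exactly* zero
  outside scripted spans (an invariant the tests assert).
* Gravity is a constant 1 g on the vertical acceleration channel; white
  noise (per-channel sd in g / rad/s) and an optional 4–6 Hz tremor
  sinusoid are added to all channels.  All randomness flows from one seed
  through `numpy.random.SeedSequence` spawns (three acceleration streams,
  three gyroscope streams, one tremor-phase stream), so identical scripts
  and seeds give bit-identical recordings.

Ground-truth gating mirrors manual segmentation practice: walks shorter
than two strides (the 1.5 m minimum expressed without a spatial model) and
transitions flanking sits shorter than 2 s are left unlabelled.

Scripted trial builders: `make_tug_script` (sit 5 s, stand up, walk 4 s,
turn 5 s, walk 4 s, turn 5 s, sit down, sit 19.5 s) and
`make_free_living_script` (seed-randomised interleaving of walking bouts
with exactly the requested numbers of sitting bouts and turns, plus
shuffles and rests; leftover time spreads over the walks and a final rest
so durations conserve exactly).  Turn and shuffle durations are ~5 s:
given the narrow band's ~1.5 s ring constant, two walking bouts merge
unless separated by roughly 4.5 s of quiet, and slow multi-step turning of
that length is characteristic of the impaired gait this tool targets.
The TUG's long final sit places the sit-down burst inside the trailing
gap's leading 25 % RMS window.

**What passing on synthetic data does not show.**  The simulator has no
gait variability (fixed cadence and impact amplitude within a bout), no
orientation drift or gravity leakage during postural change, no curved
walking, no freezing episodes, and sensor noise is white.  Recovery rates
on these signals therefore demonstrate correctness of the rule
implementations and their interplay, not clinical performance; on real
data, expect boundary errors of seconds rather than tenths of seconds and
substantially lower transition specificity.

## Numerical choices and degenerate inputs

* Time grids must be uniform to 1e-6 s; readers reject, never repair.
* Intervals are half-open `[start, end)`; abutting segments are disjoint
  and frame counting is unambiguous.
* Segment-to-sample conversion rounds `start·fs` / `end·fs` to the nearest
  index; CSV floats are printed with 9 decimals, making write–read round
  trips stable to < 1e-9.
* A zero-variance static recording yields threshold ≈ 0 (no error); an
  empty stage-1 turn-peak set yields no turns; non-walking segments too
  short for the RMS windows are skipped and logged.
* Problem sizes in the test-and-reproduction scripts (one TUG, twenty
  180 s free-living trials, 100-instance oracle sweeps) keep full runs in
  the tens of seconds while giving pooled event counts in the hundreds.

## Known limitations

* The 1 s bridge/merge constants make walking bouts separated by < ~4.5 s
  inseparable after narrow-band filtering; this is a property of the
  published rule set, not an implementation artefact.
* The transition rule tests every sufficiently long non-walking gap,
  including gaps occupied by turning; with noisy medio-lateral channels
  this yields false transitions in quiet gaps (the rule's specificity is
  intrinsically modest).
* Prominence constants are interpreted in rad/s; deployments with deg/s
  hardware must either convert units on read (supported) or rescale the
  constants in the config.
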