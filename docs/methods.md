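# Methods

drowsefuse monitors driver vigilance by extracting five indicators from
commodity sensor streams and fusing them with a fuzzy Bayesian network
(FBN).  This note describes the models, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical conventions.

## Indicators

**PERCLOS (PR).** The fraction of frames within a sliding window whose eye
openness falls below a closure threshold.  Openness is the combined area of
the two eye holes in the skin mask, normalized by the running session
maximum (a proxy for the largest observed pupil/eye size).  The default
closure threshold of 0.2 realizes the P80 criterion — an eye at least 80 %
closed counts as closed; setting it to 0.3 gives a P70-style variant.  How
the session maximum should be measured or reset is genuinely open; we use a
running maximum, which adapts within a session but never shrinks.  The
window length defaults to 60 s (standard PERCLOS practice) and is
configurable; short sessions and reactive pipelines use 10 s.  PERCLOS is
only emitted once a full window of frames exists — partial windows are
dominated by single blinks.

**Eye detection.** Frames are converted to HSV (hue in degrees); pixels
with hue in the skin band (default 0–50°, wrapping bands supported) and
saturation ≥ 0.15 form the skin mask.  Neither band carries external
authority — they are common skin-chroma defaults and fully configurable.
A morphological close (5×5 square) smooths the border, then interior holes
smaller than 1 % of the largest component are filled (a scale-free reading
of "remove small holes"); the largest component's bounding box is the face.
Eye candidates are interior holes; candidate pairs must be vertically
aligned within ±10 px.  Among aligned pairs (the eyebrow/eye confound) we
group pairs into vertical bands one tolerance tall and pick the lowest
band, breaking ties by larger combined area and then by the lower exact
row — the "lower and larger" rule made total.  Frames with a face but no
aligned pair count as fully closed (closed eyes leave no holes); frames
with no face are tracking failures and contribute nothing.

**Heart rate (HR).** Pan–Tompkins-style R-peak detection: 5–15 Hz
second-order Butterworth bandpass (zero-phase), derivative, squaring,
150 ms moving-window integration, adaptive signal/noise thresholds with a
250 ms refractory period, and peak refinement to the bandpassed maximum
within ±80 ms.  HR is 60 / mean(RR) over a 10 s window.  SDNN is available
as an HRV diagnostic but is not fused.  Traces shorter than 2 s, flatlines
and sub-50 Hz sampling are rejected.

**Blood pressure (BP).** The linear surrogate BP = a·PP − b, where PP is
the interval from a PPG systolic peak to the following valley within one
cycle (seconds; the opposite valley→peak convention is a configuration
switch).  The calibration constants are subject-specific configuration
inputs; the package defaults a = −250 mmHg/s, b = −180 mmHg map typical PP
intervals (0.25–0.45 s) onto a plausible systolic band (≈67–117 mmHg) with
the physiologically expected sign: a longer pulse interval reads as lower
pressure.  Cycle detection uses prominence-gated extrema with a 0.4 s
refractory; buffers under 15 samples are rejected (too few points make
spurious extra extrema likely), and peak→valley pairs longer than 2 s are
discarded as recording gaps rather than pulse cycles.

**Speed (SP).** SP = (√(x²+y²+z²) − C)·3.6 km/h with C standard gravity
(9.80665 m/s², i.e. 35.30394 (km/h)/s).  The formula converts the
magnitude's deviation from 1 g; it is implemented exactly as stated even
though it is not an integrated velocity, and an explicitly separate
trapezoidal integrating estimator is provided for comparison.  Magnitudes
below gravity would read negative and are clamped to 0 (negative speed is
meaningless downstream and the fuzzifier expects ≥ 0).  A 2 s trailing
moving average smooths the output.

**Temperature (TP).** Passed through unchanged; readings outside a
plausibility band (default −20…60 °C, edges inclusive) are flagged and
excluded from fusion.

## Fuzzy Bayesian fusion

Each indicator is a parent variable with linguistic states defined by
triangular/trapezoidal membership functions (open ∞-shoulders give
unbounded low/high states).  A crisp value is fuzzified by evaluating
every membership function and normalizing the raw degrees to sum to 1 —
normalization is required for the probability semantics below, since raw
memberships need not sum to 1.  A value outside every support raises an
error and the caller holds the last valid state vector.

For parent state vectors y₁…y₅ the joint weight of a combination
(s₁,…,s₅) in the Cartesian product of parent states is the **product
t-norm** t = ∏ᵢ yᵢ(sᵢ).  With normalized inputs, ∑ t over all L
combinations is exactly 1 (a product of sums).  The CPT assigns each
combination a probability of fatigue; the fused pair is

    p_true  = ∑_p t_p · cpt_p        p_false = ∑_p t_p · (1 − cpt_p)

The false branch reuses the same joint weights with the CPT's complement
column, which preserves p_true + p_false = 1; treating the false-branch
weights as independent quantities would break that identity, so the
complement-column reading is the one implemented.

Parents default to binary states (normal/fatigued); the state count per
variable is configurable.  No CPT values carry external authority, so the
shipped default is a **noisy-OR** table — P(true | combo) =
1 − (1−leak)·∏_{fatigued i}(1−wᵢ) with leak 0.32 and weights PR 0.85,
HR 0.55, BP 0.45, TP 0.25, SP 0.25 — monotone non-decreasing in every
parent's fatigued state, with PERCLOS deliberately the strongest cue.  The
leak puts an all-normal subject at p_true = 0.32, inside the awake band;
a fatigued PERCLOS plus any vital pushes p_true past the alert threshold.
Any CPT, membership set or threshold can be loaded from a YAML network
definition (`FusionNetwork.from_yaml`).

Default membership breakpoints (package defaults, matched by the
generator, no external authority): PR fatigued ramps 0.15→0.40; HR
fatigued below resting, ramping 65→55 bpm; BP fatigued ramping
95→85 mmHg; TP fatigued ramping 24→28 °C (warm cabins promote
drowsiness); SP fatigued ramping 60→80 km/h (sustained high speed).

**Interpretation.**  p_true maps to three layers: (i) a soft-binned
state distribution over safe/warning/dangerous (ramps across 0.54–0.60
and 0.75–0.80, normalized; the reported state is the argmax); (ii) a
banded vigilance label — awake [0.30, 0.54], partial-sleep [0.60, 0.75]
with a "rest" advisory, alert above 0.75; the bands [0, 0.30) and
(0.54, 0.60) are not mapped by the underlying scheme and are surfaced as
"below-range" and "indeterminate" rather than guessed; (iii) the alert
trigger, which fires **strictly** above 0.75.  A 0–100 vigilance index
(100·p_true) is provided for display.

## Pipeline

The orchestrator ticks every 0.2 s over the common time span of the five
streams.  Heavy detectors (R peaks, PPG cycles, speed smoothing) run once
over the full trace; each tick then reads the most recent window of each
modality (HR and BP windows 10 s, PERCLOS window configurable).  A feature
whose window is empty is held at its last value; a feature whose newest
supporting datum is older than 2 s is flagged stale (e.g. `bp_stale`
during a PPG dropout).  Ticks before a feature's first availability are
backfilled from its first computed value and flagged.  Scoring maps a tick
to a drowsy prediction when p_true ≥ 0.60 (the lower edge of the
partial-sleep band) and tabulates awake/drowsy counts with integer
percentages under round-half-up; aggregate rows sum counts before
computing percentages.

## Synthetic generator

The generator is the package's study-condition definition, not a
calibration dial.  Per-state defaults: awake — 75 bpm with 40 ms RR
jitter, PP 0.30 s, 15 blinks/min of 0.2 s, 22 °C, 30 km/h; drowsy —
52 bpm with 15 ms jitter (reduced variability), PP 0.42 s (shifted pulse
interval), slow droops covering 35 % of each 4 s cycle plus sparse 0.3 s
blinks, 29 °C, 85 km/h.  ECG is a Gaussian R-spike train with a small
T wave and 5 % additive noise; PPG is a per-cycle asymmetric half-cosine
pulse whose peak sits exactly PP before the closing valley; the
accelerometer inverts the speed formula along a random fixed orientation;
eye openness uses a deterministic droop duty cycle so windowed PERCLOS
equals the droop fraction by construction.  Rendered face frames
(160×120, skin-hue ellipse, dark eye rectangles scaled by openness,
optional eyebrow bars) exercise the vision chain; below roughly one-third
openness the eye slit is thinner than the morphological kernel and
vanishes, reproducing the real failure mode of hole-based eye detection
on closed eyes.

What the generator does **not** emulate: realistic ECG/PPG morphology
(no P/QRS detail, no baseline wander by default), motion artefacts,
illumination changes, head pose, skin-tone diversity, or sensor clock
drift.  Passing tests therefore demonstrate correctness of the algorithms
under clean, well-separated conditions — not field performance on real
drivers.

## Evaluation sizes and numerics

The end-to-end check uses a 230 s two-segment session (110 s awake,
120 s drowsy; ≈1145 ticks at 0.2 s, ≥200 per class) with 10 s HR/BP/
PERCLOS windows so state transitions settle within seconds; accuracy on
this well-separated spec is ≈99 %, comfortably in the ≥95 % regime.
Inference is validated against exhaustive enumeration (32-term sums agree
to <1e−12 over 200 seeded draws), and t-norm mass conservation holds to
1e−12.  All randomness flows from explicit seeds; identical seeds give
bit-identical sessions.  Region coordinates are 0-based, top-left origin,
half-open on bottom/right; percentages round half up; achromatic pixels
take hue 0 by convention.

## Known limitations

- The eyebrow/eye disambiguation needs open eyes: with eyes fully closed
  and eyebrows visible, the eyebrow pair is the only aligned candidate
  and is measured instead.  A per-session eyebrow-region exclusion would
  fix this but is not implemented.
- The speed formula reads acceleration deviation as speed; it is kept by
  design (see above) and is only meaningful with the matching generator
  convention or a calibrated device.
- Blood-pressure constants require per-subject calibration; the defaults
  are plausible placeholders, not population values.
- The FBN is static: no temporal smoothing of p_true beyond the window
  overlap of its inputs, and no CPT learning.
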