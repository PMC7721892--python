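# Methods

## Task geometry and coordinate conventions

All positions are screen-centered degrees of visual angle (x positive
rightward, y positive upward) at a 76.5 cm viewing distance; time is in
milliseconds relative to the onset of the saccade targets, sampled at
1 kHz. The fixation target sits 15° left or right of center, the first
saccade target at the center, the second 15° above or below it, and the
four distractor positions at (±7.5°, ±7.5°). A distractor is *clockwise* or
*counterclockwise* of the second-saccade target by the sign of the angle
from the target direction to the distractor direction about the screen
center.

## Saccade detection

Gaze speed is computed as centered finite differences of position, averaged
componentwise with a 20-sample boxcar, then taking the Euclidean norm
(averaging the velocity *vector* before the norm lets fixation noise cancel
instead of rectifying). A saccade is a maximal run of samples exceeding

    threshold = max( median(v) + k · SD(v),  floor )

for at least 20 ms, with k = 3. Two estimation details are deliberate
choices, since the detection rule's distributional details are
underdetermined by its usual one-line description:

* **SD is robust (1.4826·MAD) by default.** The plain standard deviation of
  the whole-trial speed series is dominated by the two task saccades
  themselves: for a 15° saccade the threshold then lands near 60% of peak
  speed and onsets are detected ~15 ms late. The MAD reflects the fixation
  noise floor, which is what the threshold is meant to clear.
  `DetectionParams(robust=False)` restores the plain SD.
* **A threshold floor (20 deg/s) bounds degenerate cases.** On noiseless
  (or heavily pre-filtered) recordings the MAD collapses to zero and any
  smoothed-speed ripple — which leaks ~10 ms ahead of true motion through
  the boxcar — would otherwise trigger. 20 deg/s is well below any saccadic
  peak speed and above fixational drift.

Events separated by less than 10 ms of sub-threshold speed are merged
(dynamic overshoot would otherwise double-count); the offset is the first
sample back below threshold. Blink gaps propagate as undefined speed, can
never be inside a detected run, and invalidate the trial. With these
choices, detected onsets sit within ±2 ms of ground truth on noiseless
synthetic trials and within a few ms at 0.05° RMS noise.

Sequence assignment picks the earliest saccade that leaves the fixation
target (start within 3.5°) and approaches the center, then the earliest
later saccade leaving the center with at least half the target
eccentricity. The assignment gate is deliberately loose (half-eccentricity
radii): the strict 3.5° inclusion radii belong to validation, so that a
saccade landing at 4° is reported as a *landing error* rather than a
missing saccade, and small corrective saccades are ignored.

## Trial selection and timing windows

A trial is valid when fixation stayed within 3.5° of the fixation target
for the 200 ms before target onset, both saccades start and land within
3.5° of their respective targets, latencies are under the 400/700 ms online
caps, and no blink occurred. Failures are reported with exactly one primary
reason, checked in a fixed order (blink, fixation break, first-saccade
start/landing, first latency, second-saccade start/landing, second
latency).

Distractor timing, on the same clock as the detected saccades:

* *pre-saccadic*: distractor offset in `[onset1 − 150 ms, onset1)` — closed
  on the early side, open at saccade onset (a distractor still on at onset
  belongs to neither window);
* *inter-saccadic*: distractor onset strictly after `offset1` **and**
  offset at most `onset2 − 100 ms`;
* otherwise *excluded* (too early, overlapping a saccade, or too close to
  the second saccade to influence its programming).

Pre-saccadic trials are *inter-hemifield* when the distractor's horizontal
position lies on the fixation side (between fixation and center, so the
first saccade carries its eye-centered trace across the vertical meridian)
and *intra-hemifield* on the far side. Eye–distractor eccentricity is
reported as the planar distance in degree coordinates (10.6° inter, 23.7°
intra for this geometry); the true angular separation on the flat screen is
also provided (`angular_separation`), because the two differ at these
eccentricities and published roundings cannot always be traced to one of
them.

## Trajectory normalization and the curvature angle

For each valid trial the second-saccade samples are rigidly rotated so the
start→end chord points upward (start at the origin). Because the rotation
is proper, a clockwise distractor always maps to the positive orthogonal
side. Samples are then averaged within 50 equal-width along-axis bins
(≈1 bin/ms for a 50 ms saccade at 1 kHz); the bin's along-coordinate is the
mean along-axis position of its samples, which keeps the profile monotonic
even through dynamic overshoot, and empty interior bins are linearly
interpolated. The participant- and sequence-specific mean profile of the
distractor-absent trials is subtracted (removing idiosyncratic curvature),
and the orthogonal axis is negated for counterclockwise distractors so that
negative always means *away from the distractor*.

The curvature angle is the median over interior profile points of
`arctan(orthogonal deviation / along-chord distance from start)`. The first
and last 5% of the chord are excluded (configurable): the deviation angle
is numerically unstable near the start point. The chord is the saccade's
own start→end line, not the start→target line. |θ| < 90° by construction,
and the statistic is invariant under rigid motions of the scene and odd
under mirror reflection.

Baseline subtraction happens per trial *before* the median, so the
statistic remains the paper-standard median-of-angles while normalization
stays exact for additive deviation components.

## Aggregation and bootstrap inference

Trials average within participants; the group mean and SEM (SD of
participant means / √P) summarize each condition. Inference resamples
trials with replacement *within* each participant (preserving every
participant's trial count), averages participant means per replicate, and
repeats 10,000 times; two conditions are compared through the elementwise
difference of their replicate vectors, `p = 2·min(Pr(d≥0), Pr(d≤0))`,
floored at `2/(n_boot+1)`. Resampling trials rather than participant means
keeps the participant-and-condition structure of the data; resampling at
the participant level is available as a manual alternative by feeding
participant means in as "trials". The per-participant median split of
first-saccade latency labels pre-saccadic trials *early*/*late*; ties at
the median alternate toward the smaller group.

## The synthetic-data generator

The generator emulates the recording, not just the statistics: it writes
1 kHz gaze tables with a fixation epoch, a horizontal then a vertical
saccade, and event tables cross-referenced by trial id, with a ground-truth
record per trial (true saccade times, injected curvature components,
artifact flags). Design defaults per participant: 150 trials per
(modality × intended timing × sequence) cell, three modalities, plus
distractor-absent trials amounting to one quarter of the experiment (they
are the normalization baseline). Distractor onsets are drawn in integer
milliseconds inside the experiment's global [−100, +300] ms interval,
stratified into a pre-aimed and an inter-aimed subrange derived from the
latency model; the ground-truth timing class is always read off the
realized saccade times, so boundary trials land in *excluded* exactly as
they would in a real session.

Key modelling choices:

* **Kinematics.** Raised-cosine speed profile along the path; duration
  = 21 ms + 2.2 ms/° of amplitude (main-sequence-like). Analytically
  integrable and symmetric, which makes the statistic's median sit exactly
  at mid-chord.
* **Curvature injection.** A single orthogonal sine bump `h·sin(πs)` of
  normalized progress s. The bump height for a requested angle θ is
  `h = L·tan(θ)/2`, because the per-point deviation angle is monotone in s
  and the sample set is symmetric about s = 0.5, so the median equals the
  mid-chord angle `atan(2h/L)`. This closed form agrees with the
  brute-force statistic to well under 0.05°.
* **Component additivity.** Idiosyncratic baseline curvature (one draw per
  participant × sequence, SD 1°), trial-level curvature scatter (one draw
  per trial, SD 1°), and the distractor effect superpose as deviations
  (heights), each calibrated to its stated angle. Physical deviations add
  linearly; normalization then removes the baseline exactly.
* **Latencies.** Truncated Gaussians per modality with the reported means
  (first saccade: 172.0/160.5/163.9/179.4 ms for visual/auditory/
  audiovisual/absent; second: 497.3/462.9/473.9/481.0 ms), truncated at the
  400/700 ms online caps; trial-level SDs (30/60 ms) are assumptions — the
  study reports only between-participant SEMs.
* **Effects.** The default effect map injects the reported condition means
  (visual/auditory/audiovisual × inter-saccadic: −2.65/−0.52/−3.34°;
  inter-hemifield pre-saccadic: −0.76/−0.58/−1.05°; intra-hemifield:
  −1.38/+0.24/−1.15°), sign-oriented so negative is away from the
  distractor.
* **Artifacts.** Blinks are runs of absent samples, fixation breaks are
  excursions beyond the fixation radius before target onset, landing errors
  displace the first saccade's endpoint by 4–6°. Rates default to zero
  (artifacts only flag trials, never drop rows) and are switched on
  explicitly to exercise the filters.
* **Landing scatter** (0.5° SD per axis) varies saccade endpoints; the
  injected bump is built relative to the realized chord.
* **Measurement noise** (`noise_sd_deg`) defaults to **zero**. This is a
  considered choice, not an omission — see the limitation below.

Fixed seeds make the output tables bit-identical across runs.

### What the generator does not emulate

* **Between-participant heterogeneity of effect size.** Real participants
  differ (the study's SEMs of 0.14–0.53° over 8 participants imply ≈1° SD
  of true effects); the generator injects one population value so that
  recovery is verifiable against a known truth. Passing tests therefore
  show pipeline correctness, not that 8 participants suffice to pin a
  population mean.
* **Instrument noise, by default.** The median-of-angles statistic is not
  noise-neutral for curved trajectories: under white per-sample noise σ the
  per-point angle noise is ≈σ/(L·s), enormous near the saccade start, and
  the sample median slides toward the dense small-angle end of the
  per-point distribution — an attenuation toward zero of roughly 5–10% of
  the effect at σ = 0.05°, several times the group SEM at these trial
  counts (straight saccades are unaffected, by symmetry; this is verified
  in the tests). The injected effect magnitudes are themselves *measured*
  values from recordings, so re-measuring them through a simulated
  instrument would double-count that attenuation. Analyses of real
  recordings should treat absolute curvature magnitudes as
  noise-level-dependent; comparisons between conditions recorded at the
  same noise level are unaffected in sign and ordering.
* Auditory waveforms (a sound distractor is its event metadata), head/torso
  acoustics, the online trial-repetition policy, and pupil/drift dynamics.

## Numerical and degenerate-input choices

Zero-amplitude saccades, degenerate chords, all-undefined velocity,
non-uniform timestamps, empty conditions and mismatched bootstrap lengths
raise errors rather than propagating silently. Baselines built from fewer
than 5 distractor-absent trials are flagged (`low_baseline`). Profiles with
mismatched bin counts are regridded by linear interpolation on relative
position. The p-value floor `2/(n_boot+1)` avoids reporting zero from
finite resampling.

## Problem sizes

The shipped verification runs use the study's scale — 8 participants,
150 trials per design cell (≈250 analyzed trials per condition and
participant, about twice the study's per-condition counts, with the same
1/4 share of distractor-absent trials) — and 1,000 replicate experiments
with 2,000 bootstrap replicates for the type-I calibration; the acceptance
script pools three such experiments per reported mean. These sizes were
chosen so every reported quantity is stable to well under the comparison
tolerances.
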