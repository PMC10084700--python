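# Methods

This note documents the models, parameter choices and numerical decisions
behind `broodetect`, and what the synthetic-data tests do and do not show
about field data.

## Signal model and preprocessing

**Autocalibration.** Accelerometers drift in offset and gain; during static
periods the measured vector should have unit norm (1 g). Static windows are
non-overlapping 10-s segments whose per-axis SD is below 0.013 g on all
three axes (the conventional threshold for this family of methods). Given
the static window means, calibration `a_cal = (a_raw − offset) · gain` is
estimated by an iterative closest-point sphere fit: calibrated vectors are
projected onto the unit sphere and per-axis ordinary least squares updates
offset and gain, iterated to a 1e-10 fixed point. The fit needs at least
10 windows spanning at least 3 orientations more than 15° apart; otherwise
— common for very active chicks — the identity calibration is returned
with `converged=False` and the pipeline continues. Recovery accuracy on
synthetic distortions (offsets ≤ 0.05 g, gains 0.97–1.03) is better than
0.005 g / 0.005 when six or more orientations are present.

**Median filtering and ODBA.** The gravitational component of each axis is
a centered moving median with "cut-off" 0.2 Hz, the dynamic residual is
smoothed with a 2 Hz moving median, and ODBA sums the absolute smoothed
residuals. A moving median has no crisp frequency response, so the cut-off
is mapped to a window of `w = round(fs / fc)` samples, forced odd (125
samples ≈ 5 s at 0.2 Hz; 13 samples at 2 Hz): a median over a window of
duration 1/fc suppresses variation faster than fc. One consequence worth
knowing: signals *above* the low-pass cut-off are attenuated, and a pure
5 Hz tone (window ≈ 2.6 periods) is cancelled almost exactly — ODBA here
measures sub-2-Hz dynamic motion, which is where chick locomotion lives.
Edges use truncated windows (no padding); the 30-min edge trim removes the
affected region anyway, along with handling-disturbance time.

**Aggregation.** ODBA, on-body temperature and light are averaged into 5-s
bins (bins aligned to multiples of 5 s; bins without samples dropped);
ambient temperature is joined by nearest-time interpolation, with gaps over
1 h left missing with a warning; sun elevation is computed at bin midpoints
with the standard low-precision NOAA solar geometry (tested to ±0.5°
against an independently coded algorithm and against equinox/solstice
geometry). Night is civil dark: sun more than 6° below the horizon.

## Two-state segmentation

Per chick, log(ODBA + ε) with ε = 1e-4 g is modeled as a two-state
Gaussian HMM. ε keeps truly motionless bins finite and compresses the
right-skewed ODBA scale; rest and activity then form two well-separated
log-normal-ish clusters. Baum–Welch runs with scaled forward–backward
recursions until the log-likelihood improves by less than 1e-6 or 200
iterations. Initialization is deterministic — state means at the 20th/80th
percentiles of the series, shared SD, 0.95 self-persistence, uniform start
— so fits are reproducible; the user seed only drives the one fallback
re-initialization attempted when decoding leaves a state under 1%
occupancy (a constant series raises a degenerate-fit error instead).
Emission SDs are floored at 1e-4 to avoid variance collapse. Viterbi
decoding breaks ties toward the lower state index; states are re-ordered
so index 0 is always the lower-mean ("non-active") state, making the
labeling invariant to initialization order.

## Post-processing rules

Maximal non-active runs become candidate brooding bouts. The rule chain:

1. **Light rule (50 lx).** A candidate overlapping daylight keeps the
   brooding label only if at least one 5-s bin (configurable
   `min_dark_bins`) reads below 50 lx. Night bouts are exempt. The
   threshold separates parental cover (≈ 0–20 lx) from vegetation shade
   (≈ 200–2,000 lx); it deliberately cannot distinguish a chick *shaded*
   by the parent's body from one pressed against the brood patch — the
   brooding definition used here requires direct contact.
2. **Temperature-difference statistics.** Per chick, the medians of
   consecutive-bin on-body temperature differences pooled within brooding
   and within active bouts (a difference is pooled only when both bins lie
   in the same bout). At least 10 differences per state are required,
   otherwise boundary adjustment is skipped with a warning.
3. **Boundary adjustment.** Chicks often settle before the parent covers
   them and start moving before they actually leave, so bout boundaries
   are re-anchored on the temperature signal: the start moves forward to
   the earliest bin (up to the bout midpoint) whose difference exceeds the
   brooding median and stays above it for `adjust_sustain_bins` = 6
   consecutive bins (30 s); the end moves forward from the bout end to the
   first sustained crossing of the active median (by default falling below
   it — cooling onset; the direction is configurable because warming-based
   readings of this rule are also defensible). The sustain requirement is
   the key numerical safeguard: both medians sit near 0 °C/bin, so a
   single-bin test would fire on sensor noise in roughly half of all bins
   and systematically drag boundaries toward the search-window edge.
   Neighboring intervals are resized so the partition never inverts;
   already-adjusted bouts (tracked by provenance) are left alone, which
   makes the whole chain idempotent.
4. **Pruning (20 s).** Breaks of up to 20 s between brooding bouts are
   merged, then brooding bouts of up to 20 s are relabeled to their
   flanking state, repeated to a fixed point ("up to" read inclusively).
   A final light-rule pass guarantees every surviving daylight brooding
   bout still contains a dark bin even after boundary shifts.

Chicks at or above 65 g are flagged as feathered (light sensor covered;
daytime brooding undetectable) and excluded from summaries. There is no
silent manual-correction stage; instead `qc_report` lists bouts violating
temperature-consistency heuristics for human review.

## Summary tables

Hourly rows use **local standard time** (UTC offset = round(longitude/15):
UTC+1 and UTC+4 at the two default sites, no DST) and clock-hour bins —
"time of day" is a diel covariate, so a solar-proximate clock is the
sensible basis. Minutes are exact fractional interval coverage; a config
flag rounds them to integers at export for strict binomial numerators.
Partial hours are kept and down-weighted by √(observed minutes). The night
flag of an hour is evaluated at its midpoint. Diel time enters as
sin/cos(2πh/24); z-transforms use the sample SD (n−1) and return the
constants for back-transformation. Brooding efficiency takes one row per
brooding bout longer than 5 min and is the median on-body temperature
after the first 5 min, by which time the first-order thermal relaxation
(τ = 120 s) has closed ≥ 92% of any initial gap.

## The simulator

`broodetect.synth` emulates the data-generating process the detector
assumes, with ground truth:

- **Ambient temperature**: diel sinusoid peaking at 15:00 local
  (defaults: 15 ± 8 °C temperate preset, 32 ± 8 °C desert preset) plus
  AR(1) noise; one shared weather realization per cohort.
- **Behavior**: alternating semi-Markov states. After each foraging bout
  the chick's next rest is brooding with probability
  logistic(intercept + slope·z(T_amb) + night·effect), where z uses a
  fixed reference (20 ± 8 °C) so cohorts at different sites genuinely
  differ; otherwise a daytime shade-rest or an other-rest. Durations are
  log-normal per state (median 15 min brooding, 10 min foraging).
- **On-body temperature**: exact discretization of
  dT/dt = (T_target − T)/τ with T_target = T_eq while brooded (37.2 °C
  temperate preset, 35.0 °C desert preset) and T_amb + 1 °C otherwise;
  τ = 120 s so temperature stabilizes well inside the 5-min efficiency
  window; sensor noise SD 0.02 °C, a typical digital-sensor resolution.
- **Light**: daylight base log-uniform 10⁴–10⁵ lx scaled by sun
  elevation; ≈ 0 at night; 200–2,000 lx in shade-rest; 0–20 lx while
  brooded — so the 50 lx rule is informative by construction.
- **Acceleration**: slowly rotating gravity vector (smoothed random walk,
  0.3°/s) plus band-limited dynamic noise with state-dependent amplitude
  (0.25 g foraging, ~0.005 g rest), distorted by a configurable
  miscalibration that the pipeline's autocalibration must undo.

What the simulator does **not** emulate — and what passing tests therefore
do not demonstrate about field data: transitional behaviors with
intermediate ODBA (preening, alert crouching), rain and substrate
conduction in the thermal model, logger detachment or clock drift,
behavioral correlation among siblings, growth during deployment, and
chicks crouching under dense dark shelter (the known failure mode of the
light rule in very hot hours). Recovery scores on synthetic cohorts
(balanced accuracy ≳ 0.98, bout F1 ≳ 0.88, rate error < 1 pp) are
best-case figures for data that match the model's assumptions.

## Problem sizes and numerics

The acceptance tests run the full pipeline on a 10-chick × 48-h cohort
(both species presets, fixed seed) — about 43 million accelerometer
samples — plus dedicated 24-h scenarios for shade-confounder rejection and
efficiency recovery; `scripts/acceptance.py` reports the same quantities
from 24-h cohorts of 3 chicks per species, a size chosen to keep a full
from-scratch reproduction around one minute while leaving every estimate
comfortably inside its tolerance. Forward–backward and Viterbi recursions
are JIT-compiled (numba); filtering uses pandas' rolling median. Degenerate
inputs are handled explicitly: constant ODBA raises a degenerate-fit
error, empty or too-short traces trim to empty with a warning, missing
light makes the light rule error rather than silently pass, and
insufficient temperature statistics skip boundary adjustment.
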