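# Methods

## Scope and data model

The package analyzes trajectory tables exported by video trackers: one row
per sample with subject id, time (s from recording start), x/y (mm) and
optionally an instantaneous velocity (mm/s). Units are fixed at mm / s /
mm/s internally; the reader converts from cm when the dialect declares it.
When the export lacks velocities they are derived from positions using the
actual timestamps (`v_i = ||p_i − p_{i−1}|| / (t_i − t_{i−1})`); the first
sample's velocity is undefined and never counts as an observation. The
declared nominal sampling rate is metadata only — no arithmetic depends on
it.

Time conventions are half-open everywhere: an analysis window covers
`[start, end)`, seconds are aligned to the window start (second *k* is
`[start+k, start+k+1)`), and the lights-off instant belongs to NIGHT. This
avoids double counting at every boundary.

## Sleep scoring

Per-second classification: MOVING iff any sample velocity in the second is
strictly greater than the movement threshold (default 1.0 mm/s — a sample at
exactly the threshold is immobile); IMMOBILE iff all samples are at or
below; MISSING iff the second contains no valid sample. Bout detection:
within each contiguous observed segment, maximal IMMOBILE runs of at least
the sleep-period threshold (default 6 s, integer) are sleep bouts; all
remaining seconds merge into wake bouts. The minimum scoreable sleep bout is
therefore exactly the threshold, which the acceptance script verifies by
exhaustive enumeration of all 4096 twelve-second sequences.

Missing data are handled conservatively: MISSING seconds break immobility
runs (sleep is never scored across unobserved time), belong to no bout, and
are excluded from every denominator. Bouts cut by a window edge or a gap are
flagged truncated; they count toward the sleep/wake ratios (their observed
seconds are real) but are excluded from mean bout durations, whose true
values are unknown for censored bouts. A switch
(`include_truncated_in_means`) restores the inclusive behavior.

Derived parameters per subject and window:

* sleep ratio = sleep seconds / analyzed seconds (analyzed = window −
  missing); wake ratio analogous (they sum to 1 when nothing is missing);
* mean sleep / wake bout duration over non-truncated bouts; when a state has
  no countable bout the mean is reported as NaN, never 0;
* fragmentation = sleep→wake transitions between time-adjacent bouts, per
  analyzed hour (a sleep bout ending at a gap is not an observed awakening);
* swim velocity = path length over the window / analyzed seconds, and total
  distance = summed segment lengths with both endpoints inside the window.

Velocity is defined as distance over time rather than the mean of sample
velocities; this keeps the velocity and distance columns mutually
consistent. These definitions satisfy the identity `fragmentation ≈
sleep_ratio × 3600 / mean_sleep_bout` (exact up to the ±1 bout at the window
edges), which the tests check against the reference cohort means below at
5% tolerance.

## Locomotor metrics

Per light phase (DAY / NIGHT / FULL): total distance (segments with both
endpoints in the phase), average velocity (distance / analyzed phase
seconds), time moving (MOVING seconds, same classifier as sleep scoring) and
stationary/freezing time (IMMOBILE seconds). DAY + NIGHT reproduce FULL
exactly on gap-free input. The hyperactivity flag is a derived convenience,
not an assay-defined statistic: a group is flagged when its mean distance
exceeds the control's in both phases with Tukey-adjusted p < α in both
phases.

## Zone assays

Both assay arenas are rectangular tanks divided into bands along their
length — group / individual / empty for the social-preference test (the
individual zone subdivided into next-to-group / starting-point /
next-to-empty) and starting-point / middle / next-to-mirror for the mirror
test. Physical boundary positions are not prescribed by the assay, so the
default is equal thirds at both levels, overridable in config; the layout
validator requires an exact tiling (no overlap, no gap). Zone membership
uses half-open intervals with the last zone closed at the far wall and a
0.5-mm containment tolerance for tracker jitter; points further outside
count as missing. Occupancy credits each inter-sample interval to the zone
of its starting sample — a piecewise-constant position assumption that is
unbiased at tracking rates of a few Hz and above. The default analysis
window skips a 30-s acclimation period and scores the following 1200 s.

## Group statistics

Mean ± SEM (sample sd, √n), two-sample Student's t (pooled; Welch switch),
one-way fixed-effects ANOVA (scipy; a hand-coded Welch variant behind the
same switch), Tukey HSD via the studentized-range distribution (scipy), and
a Wilks'-lambda MANOVA (statsmodels) whose significant omnibus is followed
by per-metric ANOVAs with Bonferroni correction (multiply by the number of
metrics, cap at 1). α defaults to 0.05. Classical equal-variance tests are
the default because that matches the conventional analysis of these assays;
Welch alternatives are opt-in. The MANOVA metric list is configurable; by
default all six sleep parameters enter.

## Synthetic cohorts

The generator exists so that every stage — parser, scorer, metrics, assays,
statistics — can be tested end to end without real recordings.

**Latent model.** Per-second two-state wake/sleep Markov chain, realised by
alternating geometric bout draws (the exact bout-length law of the chain;
scoring also operates on whole seconds, so nothing finer is needed).
Transition probabilities switch between day and night parameter sets at
light transitions; by memorylessness, truncating a bout at a phase boundary
and redrawing under the new phase's parameters is exact.

**Emission.** Within a sleep second all sample speeds are drawn from a slow
log-normal clipped strictly below the movement threshold. Within a wake
second a fixed fraction of samples (default 12%, at least one per second)
are "bursts" drawn strictly above the threshold (threshold + log-normal),
the rest from the slow baseline. Consequently a wake second is always scored
MOVING and a sleep second never is, so the scored mobility of a second
reflects its latent state exactly, while the mean swim speed stays at the
realistic sub-mm/s level of larval recordings. Positions follow an
isotropic random walk with reflecting walls in a 6.4-mm well (96-well
plate); reflections shorten the realized path negligibly at these step
lengths. Burst counts are rounded per second, so the effective burst
fraction (and hence mean velocity) is quantized at low sampling rates;
velocity-sensitive checks either use rates that divide the fraction evenly
or compare groups against each other.

**Calibration.** Closed forms of the geometric-bout model link parameters to
scored statistics: stationary sleep fraction π = p_fs/(p_fs+p_wu); scored
sleep ratio = π·q^(m−1)·((m−1)p_wu+1); scored mean sleep bout =
(m−1)+1/p_wu; scored mean wake bout merges latent wake bouts with
sub-threshold sleep runs. `calibrate_state_params` inverts these to hit a
target (sleep-bout mean, sleep ratio, velocity) triple. The four shipped
group presets are calibrated to the reference cohort means stored in
`REFERENCE_SLEEP_PARAMS` (control night: sleep ratio 0.445, sleep bout
11.513 s, velocity 0.18 mm/s; the 72-h-exposure group: velocity ×~1.7 and
reduced fragmentation). Day presets use the published day velocities with a
nominal low day sleep ratio of 0.05 and an 8-s bout target, since larvae
sleep little in the light and day sleep structure is not reported.

Two internal inconsistencies of the reference means are worth noting. The
printed night velocity (0.18 mm/s) and night total distance (296.7 mm over
10 h) cannot both hold under velocity = distance/time; the presets calibrate
to velocity, so simulated total distance follows from the definition and
does not match the printed distance column (effect directions are
preserved). Likewise the printed wake-bout means are ~5–10% away from the
values implied by their own sleep ratio and bout counts; presets calibrate
on sleep-bout mean + sleep ratio, and the wake-bout mean follows from the
two-state model.

**Heterogeneity and reproducibility.** Subjects receive a log-normal speed
multiplier (CV 0.30, back-derived from the reference SEMs at n = 30) so
group comparisons face realistic between-subject spread; burst samples are
clamped above threshold after scaling so scoring fidelity is unaffected.
One root seed spawns per-subject substreams (`numpy` `SeedSequence`), making
cohorts reproducible and order-independent; identical seeds give
bit-identical trajectories.

**Zone walks.** The assay simulator is a Metropolis random walk over a
piecewise-constant target density (zone probability spread uniformly within
each zone), started from the stationary distribution. Its long-run zone
occupancy converges to the target without transit bias, which the tests use
to recover the control sociability level (group-zone probability
451.6/1200 = 0.376) across seeds.

**What the generator does not emulate.** Real tracker noise (identity
swaps, reflections, dropped frames are only modelled as missing seconds),
burst kinematics of larval swimming, circadian drift within a phase,
habituation across the test, and inter-individual correlation. Passing the
recovery tests therefore demonstrates the correctness of the scoring
pipeline under the stated model, not the biology of any particular cohort.

## Problem sizes and numerical choices

Heavy checks are sized for a desk run: parameter recovery simulates the
full 10-h dark window for 4 × 30 subjects at 10 Hz (scoring is per-second,
so the sampling rate does not enter scored sleep statistics once every wake
second contains a supra-threshold sample) against a 10⁶-second latent-chain
oracle; effect-detection power uses 100 replicate cohorts of 1800-s night
segments at 2 Hz (the velocity contrast is between-subject and unaffected
by window length at these noise levels); ANOVA calibration uses 2000 null
simulations at the 4 × 30 design. Tolerances: ±0.03 absolute on cohort mean
sleep ratio, 5% relative on bout-duration means, ±1.5 points on the 5%
type-I error, Monte-Carlo confidence intervals for occupancy recovery.

Degenerate inputs raise typed errors rather than returning sentinels: zero
analyzed seconds, all-identical ANOVA values, singular MANOVA covariance,
non-tiling zone layouts, windows outside the recorded span. Undefined
statistics (mean bout duration with no bouts, SEM of a singleton group) are
NaN, never 0. Boundary ties: a point exactly on an internal zone boundary
belongs to the right-hand zone; a sample velocity exactly at the movement
threshold is immobile; the lights-off instant is NIGHT.

## Known limitations

* The parser handles delimited text only; proprietary binary tracker
  formats are out of scope.
* Welch ANOVA is provided but Tukey HSD assumes equal variances; no
  non-parametric alternatives or repeated-measures structure.
* Occupancy's interval-credit rule slightly misassigns time during fast
  zone crossings at very low sampling rates; split-segment crediting was
  deliberately not implemented (the bias is negligible above ~2 Hz).
* The generator's geometric bout lengths have heavier short-bout mass than
  some published larval bout distributions; only the scored first two
  moments are calibrated.
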