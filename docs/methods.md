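# Methods

This note documents the models, conventions, parameter defaults and open
design choices behind `phenocage`.  It is the place to look when a number
or a definition in the code needs justification.

## Assay model and conventions

A home-cage session is a 22-hour recording at 1 frame/s (79,200 frames),
tiled into 10-minute analysis periods (132 at the defaults) and structured
into four light phases: day (hours 0–6), night (6–12), night with stimuli
(12–18) and day (18–22).  Three visual stimuli are presented at elapsed
hours 12, 14 and 16 — i.e. at the starts of assay hours 13, 15 and 17 —
which places their onsets in periods 73, 85 and 97 (12 h / 10 min = 72
elapsed periods, so period numbering is 1-based).

Conventions fixed throughout the package:

- coordinates: origin at the top-left of the cage crop, x rightward,
  y downward, pixel units; 0-based frame index;
- all time intervals (phases, periods, feature windows) are half-open
  `[start, end)`; a boundary instant belongs to the later interval;
- stimulus onsets are stored as elapsed hours; ordinal "assay hour" labels
  are converted once at the timeline boundary;
- `AssayTimeline.scaled(d)` compresses the phase proportions to `d` hours
  while keeping 10-minute periods, so short sessions remain analyzable
  with the same feature definitions.

Cage geometry defaults describe one crop of the 8-cage arena: a 320×240 px
floor at 8 px/cm, a 2×2 quadrant grid, a social window (2.5-inch hole,
radius ≈ 25 px) in the lower inside-facing corner, and a shelter hut
rectangle in the opposite corner.

## Likelihood filter

Pose entries with likelihood < 0.90 are masked.  How masked frames were
handled downstream is not standardized across pipelines; here masked
coordinates are linearly interpolated from the nearest valid neighbours
(edge runs are filled from the nearest valid value) so that speed
computations never see sentinel values.  The audit mask and masked-entry
count are retained on the recording.  Likelihoods are left untouched,
which makes the filter idempotent.  A keypoint with no valid frames at
all is an error, not a silent gap.

## Feature batteries

Two fixed registries are computed per animal; both are versioned and
emitted in output headers.

**track15** (centroid-level): movement in the first hour and the first
night hour; acclimation indices in %SAP and %movement; the moth
habituation index in %moved; four quadrant occupancies (full assay); and —
*registry extensions*, since the full supplementary parameter lists are
not reproduced in the source text — %movement per phase (4), %SAP in the
first hour, and hut occupancy.

**pose52** (keypoint-level): the five speed-class measures (moved, scoot,
burst, escape, mean speed) in the first hour and the first night hour
(10); acclimation in %movement and %SAP (2); per-presentation stimulus
responses in %moved (3); habituation indices for the moth in %moved and
%scoot (2); moving-lines responses in %moved and %scoot for the second
and third presentations (4); distance from any cage wall; time near the
window alone and with the partner present (3); and *registry extensions*:
quadrant occupancy during the stimuli phase (4), hut occupancy, %moved,
mean speed and %SAP per phase (16), plus peeking-from-hut, eating-zone
and grooming proxies, the mean %SAP stimulus response, total distance,
mean elongation, overall %moved and mean nose-to-window distance (8).
The proxies are pose-derived stand-ins (documented below), not grooming
or eating classifiers.

Definitions and defaults:

- **Speed classes.**  Per-frame speed = centroid displacement ×
  frame rate (px/s).  A frame counts as *moved* above 2 px/s; *scoot* is
  the band [2, 8) px/s; *burst* is ≥ 8 px/s; thresholds are absolute
  values in config (convertible via px_per_cm) because no printed
  thresholds exist; the defaults keep all three classes non-degenerate on
  the generator baseline (mean active speed 6 px/frame).  *Escape* frames
  are burst frames within 10 min of a stimulus onset whose velocity
  points toward the hut.  Band nesting (escape ≤ burst ≤ moved ≤ 100) is
  enforced by construction and property-tested.
- **Stretch-attend posture (SAP).**  A frame is SAP when the
  nose-to-tail-base distance exceeds 1.2 × the animal's median body
  length *and* centroid speed is below the move threshold.  The 1.2
  elongation factor is configurable.
- **Acclimation** = metric in period 1 minus period 6 of the first hour
  (first-minus-later difference, not a slope: the simplest monotone index,
  positive when behavior declines as the animal settles).
- **Habituation.**  A stimulus response is the metric in the first
  10-minute period after an onset minus the period immediately before it;
  the habituation index is response(1) − response(3).  The second and
  third presentations carry the "moving lines" responses.
- Missing entries (e.g. the partner channel when no paired-cage recording
  exists) are flagged, kept in the fixed-width vector as NaN, and imputed
  by column median at profile assembly with an audit trail.

## Syllable summaries

Sequences are consumed, never fitted; label ids may be non-contiguous
(unsupervised pipelines renumber freely) and are preserved as given.
Bouts are maximal constant runs.  *Frequency* is bout-based (share of all
bouts), following the MoSeq convention; because the source convention is
not stated, frame-based *occupancy* is emitted alongside.  A bout is
attributed to the window containing its start frame, which makes
per-period bout counts additive to the assay-wide counts.  Syllables with
zero bouts in a window get frequency 0 and an undefined (flagged)
duration.  Transition matrices count bout-to-bout transitions
(self-transitions are impossible by construction); rows without outgoing
transitions are flagged rather than normalized.

## Gait battery

- **Compliance**: a run is kept iff its walkway positions are monotone in
  one direction and its duration (first contact to last release) is
  strictly under 10 s; animals with fewer than three compliant runs are
  flagged in the report.
- **Per-paw parameters**: print length = ‖third toe − heel‖; toe spread =
  ‖toe 1 − toe 5‖; intermediate toe spread = ‖toe 2 − toe 4‖ (computed
  for all paws and left to the analyst to subset, since instrument
  conventions differ on hind-only toe spread); stand = release − contact;
  step cycle = time to the next initial contact of the same paw (the last
  contact of each paw yields none); swing = cycle − stand; paw angle =
  signed angle of the heel→third-toe axis against the body axis, folded
  to [−90°, 90°].  The body axis is the run direction along the walkway,
  since footfall records carry no per-frame trunk orientation.
  Intensities are 0–255 arbitrary units; the body-weight confound on
  intensity is noted, not modeled.
- **Support decomposition**: the run span is classified at each instant
  by the set of paws in contact — zero, single, girdle pair (RF-LF /
  RH-LH), lateral pair (RF-RH / LF-LH), diagonal pair (RF-LH / LF-RH),
  three, four.  The default path discretizes at dt = 1 ms with midpoint
  sampling (fractions sum to exactly 100); an event-driven exact
  integration over contact/release boundaries is the test oracle and is
  available as `method="event"`.
- **NSSP**: the six canonical normal step sequence patterns — alternate
  Aa (RF-RH-LF-LH), Ab (LF-RH-RF-LH), cruciate Ca (RF-LF-RH-LH), Cb
  (LF-RF-LH-RH), rotary Ra (RF-LF-LH-RH), Rb (LF-RF-RH-LH) — matched up
  to rotation of the starting paw over sliding 4-step windows.  The
  pattern identities follow the established instrument convention; with
  rotation invariance the 6 × 4 rotations cover all 24 permutations of
  four distinct paws, so a window is abnormal exactly when a paw is
  skipped or repeated (the regularity-index convention).  %NSSP is
  window-counted by default; a duration-weighted variant
  (`weight="time"`) is emitted alongside because the "percentage of
  time" granularity is not standardized.
- Per-animal gait values are means over that animal's compliant runs.

## Profiles and clustering

Profiles are per-group means over animals of the 125 ordered columns
(15 track + 52 pose + 29 syllable frequencies + 29 syllable durations),
with column provenance encoded in the names (`track15:`, `pose52:`,
`syl_freq:`, `syl_dur:`).  A per-animal mode exists behind a flag.

Weights: columns are z-scored (population sd); zero-variance columns are
excluded from the PCA, flagged, and given weight 0; the weight of a
retained column is the absolute value of its PC1 loading, renormalized to
mean 1.  The sign is discarded because negative weights are meaningless
for distances; whether the original analysis used signed loadings is not
stated, so the choice is documented here.

Clustering: the z-scored matrix is multiplied column-wise by √weight —
the order (scale, then weight) makes the weights the sole source of
differential column influence, and the square root makes squared
Euclidean distance linear in the weights — then Ward linkage is computed
on Euclidean distances.  Rows are processed in lexicographic group-label
order so ties break deterministically.  Ward heights are monotone
non-decreasing; the dendrogram serializes to Newick with merge heights as
node heights; flat clusters default to k = 3.

## Statistics

- Shapiro–Wilk gates normality at α = 0.05 (n ≥ 3, non-constant).
- Gait parameters: two-way ANOVA (age × genotype with interaction, type
  II sums of squares); Tukey HSD pairwise comparisons across the four
  cells run only when the interaction is significant.
- Home-cage parameters: unpaired two-sample Wilcoxon rank-sum,
  two-sided.  Exact null for group sizes ≤ 10 — full permutation
  enumeration when ties are present, the closed-form exact distribution
  otherwise — and the tie-corrected (mid-rank) normal approximation for
  larger groups.
- Syllable frequencies: Kruskal–Wallis with tie correction, then Dunn's
  two-sided pairwise z-tests on pooled mid-ranks.  Dunn p-values are
  Holm-adjusted by default (the adjustment used originally is unstated;
  Holm is conservative and configurable).
- Significance is read per parameter at p < 0.05 with no family-wise
  correction by default, mirroring the per-parameter reporting style of
  the assay's literature; Benjamini–Hochberg is available behind a flag.
- Stars: * p < 0.05, ** p < 0.01, *** p < 0.001; direction arrows are
  reported only for significant cells.

## Synthetic cohorts

The generator's job is parameter recovery, not realism: it reproduces the
statistical structure each feature measures and nothing more (no paw
kinematics, no realistic posture dynamics, no video).  One integer seed
fully determines a cohort via per-animal `SeedSequence` spawns.

Per animal: a two-state (rest/active) semi-Markov process (mean active
bout 20 s) whose active fraction is 0.25 in the day phases, doubled at
night, multiplied by the group's activity effects, inflated by an
exponentially decaying hour-1 arousal factor (τ = 15 min) and boosted for
10 min after each stimulus onset with per-presentation retention 0.5.
Active frames advance the centroid by a correlated random walk (gamma
speeds, mean 6 px/frame; 1.8× and hut-directed during stimulus windows)
reflected into the cage; long rest bouts relocate to the hut with
probability 0.3.  Resting frames enter stretch-attend posture with
probability 0.15 (group-scaled, with its own hour-1 decay), which
stretches the 12-keypoint rigid body template to 1.35× its nose-to-tail
length.  Likelihoods sit in [0.95, 1] with dropout to [0.30, 0.89] at
rate 0.03.  Syllables follow a semi-Markov chain over the codebook
(uniform off-diagonal transitions, mean bout durations spanning 2–4 s,
geometric lengths); group usage tilts multiply transition columns, so a
×2 tilt on one of 29 syllables yields a stationary bout-frequency ratio
of 2 × 29/28 ≈ 2.07, the value recovery tests target.  Gait runs lay
footfalls in the alternate pattern Aa at 0.18 s steps with per-paw print
templates (front/hind print lengths 7/9 mm, intensities 120/105 a.u.),
group-scaled print length, hind-paw intensity gain and step counts, and a
pattern-corruption probability that replaces a step's paw at random
(degrading %NSSP); a non-compliant run (slowed 4× or direction-reversed)
is injected on request.

The default group-effect table plants the study design's qualitative
structure: activity and step counts decline with age; the AD genotype
carries early %NSSP and print-length deficits, elevated SAP, blunted
stimulus responses and, with age, a 1.3× hind-paw intensity gain; old
drug-treated groups sit between old WT and old AD, with the
CsA-treated-old group closest to old WT and the cabozantinib-young group
closest to old AD.  Every knob maps to a named pipeline parameter (table
in `phenocage/synth.py`), and the recovery suite checks each direction
over 20 seeds.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: camera noise and occlusion structure beyond
i.i.d. likelihood dropout, inter-animal interaction through the window
(the partner channel is an independent Bernoulli process), circadian
structure beyond the four phases, posture diversity beyond elongation,
and any correlation between home-cage behavior and gait.

## Numerical and scale choices

- Desk-scale cohorts for the test suite use 2-hour compressed timelines
  (10-minute periods retained) with 2 animals per group; the acceptance
  script runs one full 22-hour cohort for the structural readouts and
  20 seeded 2-hour cohorts for the stochastic rates.  These sizes were
  chosen so the whole suite runs comfortably on a single CPU.
- Support discretization dt = 1 ms; the event-driven oracle bounds the
  discretization error in tests (< 0.5 percentage points in practice).
- ANOVA calibration uses 2,000 null simulations of a balanced 2×2 design
  with n = 4 per cell; the interaction type-I rate is required to sit
  within 0.05 ± 0.02.
- PCA uses the full SVD solver for determinism; Ward linkage and the
  k-cut come from scipy's hierarchy module.
- Newick branch lengths are serialized at 6 significant digits.

## Known limitations

- The grooming, eating and peeking measures are geometric pose proxies,
  not validated classifiers.
- The exact definitions of the original supplementary parameter lists are
  not public; registry extensions are explicit stand-ins, and profile
  columns are named to make the provenance auditable.
- Whether "escape" should be stimulus-locked is not documented in the
  assay literature; here it is stimulus-locked by definition.
- Intensity-based gait measures confound weight with load-bearing; the
  package reports them as-is.
- The Wilcoxon exact path enumerates permutations for tied samples up to
  n = 10 per group; beyond that the tie-corrected normal approximation is
  used without continuity correction.
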