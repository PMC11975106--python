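# Methods

This note records the models behind the measures, the constants that
matter, what the synthetic generator does and does not emulate, and
the design choices made where more than one reasonable definition
exists.

## Note-event model and MIDI I/O

A performance is an onset-ordered list of notes (MIDI pitch 0–127,
onset/offset in seconds, velocity 1–127). All internal computation is
in seconds; tick arithmetic exists only at the Standard MIDI File
boundary. On read, type 0/1 files are accepted, all channels are
merged (the percussion channel 10 is ignored), the tempo map is
applied, and velocity-0 note-ons are treated as note-offs. Note-ons
without a matching note-off are closed at the track's final tick by
default (`unclosed="error"` raises instead). On write, files are
type 0, PPQ 480, fixed 120 BPM, times quantised to the nearest tick
with sub-tick notes stretched to one tick so no note vanishes on a
round trip.

Monophony is enforced by truncating an overlapping earlier note at the
next onset rather than deleting it: the pitch sequence — which the
replication measures privilege over duration — is preserved, and the
operation is idempotent. SMPTE time division, pitch bend and
continuous controllers are out of scope; the material modelled is
single-strand keyboard melody.

## Replication measures

### Subsequence DTW

The alignment is dynamic time warping with unit-weight diagonal,
vertical and horizontal steps, open at both ends of the *reference*
only: a path starts at any reference position, must consume the whole
performance, and may end at any reference position. This realises the
intended semantics that a correctly played fragment is judged against
the segment it renders, with the uncovered remainder charged
separately by the aligned proportion.

- Local cost (pitch-only): min(|Δ semitones|, `COST_CAP` = 12). The cap
  means an octave slip costs no more than any larger leap and bounds
  the normalised distance.
- Normalised distance: cumulative path cost / (path length ×
  `COST_CAP`), hence in [0, 1]. Among equal-cost paths the shortest is
  chosen (lexicographic (cost, length) minimisation in the DP), making
  the normalisation deterministic; remaining ties prefer diagonal
  steps and the latest reference end, so an exact rendition aligns to
  the full diagonal even when the melody ends on a repeated pitch.
- Matched reference positions: distinct reference indices on the
  optimal path whose paired local cost is ≤ `MATCH_TOL` (default 0,
  i.e. exact pitch). `palignedprop` divides their count by the
  reference length.

The joint pitch+timing triple uses per-note features
(pitch, log₂(IOI/median IOI)); the last note, having no IOI, is
dropped. Local cost is min(|Δpitch|, 12)/12 + min(|Δlog₂ ratio|, 2)/2
(equal weighting `JOINT_W_IOI` = 1; both components unit-scaled before
summing) and the aligned-proportion tolerance is combined cost ≤ 0.1.
The log-median normalisation makes every timing-based measure exactly
invariant to uniform tempo rescaling.

### Distributional similarities

`klpitchsim` compares relative-frequency histograms of absolute MIDI
pitch over the union of pitches occurring in either sequence;
`klioisim` compares histograms of log₂(IOI/median IOI) over 13 fixed
half-open bins spanning [−3, 3] with catch-all extremes. Additive
smoothing α = 0.5 is applied at comparison time so supports never
contain zeros. Similarity is exp(−J) with J the symmetrised (Jeffreys)
divergence ½KL(p‖q) + ½KL(q‖p): identical distributions score exactly
1 and the score decays smoothly with divergence. Absolute pitch (not
pitch class) is used: the material spans under two octaves and octave
folding would destroy register information. Distributional measures
are deliberately not length-adjusted — short performances already give
poor distributional information and a length penalty would double-count
the DTW coverage term — and performances shorter than 4 notes
(`KL_MIN_NOTES`) should be treated as low-information. A one-note
performance yields the pitch-only measures with all IOI-based fields
flagged missing (NaN), never zero, so downstream standardisation is
not biased.

## Improvisation measures

Eighteen scoretypes; constants are module-level named values, chosen
once as musically sensible defaults:

- Diversity measures are Shannon entropies (base 2) of the value
  distribution — 0 for degenerate input, log₂ k for k equally frequent
  values; IOIs are discretised by the same 13 log-ratio bins as
  `klioisim`, intervals and pitches used exactly.
- Passing notes: steps of 1–2 semitones (`PASSING_MAX_STEP` = 2) from
  the antecedent, as a proportion of the n−1 transitions.
- Crescendo/diminuendo count: maximal strictly monotone velocity runs
  of ≥ `RUN_MIN` = 3 notes spanning ≥ `VEL_MIN` = 10 velocity units;
  a rise and a fall may share their turning-point note.
- Accents: notes ≥ `ACCENT_DELTA` = 15 velocity units above the mean
  of a centred 5-note context (edge-truncated, self excluded), as a
  proportion of all notes.
- Silence proportion: positive inter-note gaps divided by the span
  from first onset to last offset.
- Windowed IOI statistics: sliding means of `IOI_WINDOW` = 4
  consecutive IOIs (step 1); the range of the means, and the mean
  absolute successive-mean difference, both in seconds.
- Articulation: ratios duration/IOI capped at 1 (1 = legato); the
  population SD of the ratios, and the mean |Δ duration|/IOI over
  adjacent pairs.
- Retrograde and sequence detectors: greedy left-to-right scan for
  non-overlapping contiguous segments of ≥ `PATTERN_MIN_LEN` = 3 notes
  whose pitch sequence exactly reverses — or whose interval pattern
  repeats at a non-zero transposition of — an earlier, disjoint
  segment; at each position the longest claimable segment wins
  (leftmost source on ties) and only the later occurrence's notes are
  counted. A zero-transposition literal repeat is not a sequence. The
  greedy-exact definition was chosen over approximate matching because
  it is deterministic and checkable against exhaustive enumeration.

Each of the 14 taught variation methods maps to one designated
scoretype (several articulation methods share one); the mapping is the
`TASK_SCORETYPE` table. Measures whose preconditions fail on a given
performance (too few notes) are returned as NaN.

## Score combination

Replication measures are min-max scaled to [0, 1] for fair weighting;
improvisation measures are standardised (mean 0, SD 1, population
convention — recorded because both conventions are defensible).
Composites use variance-sharing weights: squared loadings of the
leading eigenvector of the pairwise-complete correlation matrix,
shrunk towards equal weights by s = (λ₁ − 1)/(k − 1), the shared
fraction of variance beyond one column's worth, and normalised to sum
to 1. The shrinkage matters in the boundary case: for mutually
independent columns λ₁ → 1 and the leading eigenvector of a
near-identity matrix is numerically arbitrary, so raw squared loadings
would inherit pure noise where equal weighting is the right answer;
for strongly shared variance (λ₁ → k) the weights are the squared
loadings themselves. The composite's sign is fixed to correlate
positively with the plain column mean. Rows missing any selected
column get a missing composite. The replication composite combines
`pitchdtwladj` with `klpitchsim` after unit scaling.

## Posterior summaries

Evidence ratios are computed from draw counts: (draws on the
hypothesised side)/(draws on the other side), draws exactly at zero
split half-and-half, a unanimous sample reported as infinity. This
makes the conventional strong-evidence threshold exact: ratio ≥ 19 ⟺
≥ 95% of draws favour the hypothesis. Credibility intervals are
equal-tailed sample quantiles with the median. At least 100 draws are
required; density estimation is deliberately avoided.

## Synthetic generator

The generator exists to exercise the measures under controlled,
study-like conditions, with ground-truth edit logs.

- **References**: 3–30 notes, concatenated 3–5-note fragments, pitches
  within the 20-key taught span C4–G5 (MIDI 60–79), mostly stepwise
  motion reflected at the range edges, fragment-uniform IOIs from
  {0.25, 0.5, 1} s, velocities near 64.
- **Replications**: the learner keeps the first ⌈completion × n⌉
  notes, then per note may substitute the pitch (magnitude
  geometrically decaying over ±1..4 semitones), omit it (its time is
  absorbed by the previous note) or insert a neighbouring note; IOIs
  are multiplied by lognormal jitter and velocities perturbed by
  Gaussian noise. Defaults (p_sub 0.1, p_del 0.05, p_ins 0.05,
  completion 1, jitter σ 0.05, velocity σ 5) describe a mildly
  imperfect learner; the cohort uses a harder baseline (below).
- **Improvisations**: a 3–5-note prompt is continued by a freer random
  walk (leaps up to 5 semitones common) to 12 notes, then each
  requested method is planted with frequency/size proportional to its
  intensity in [0, 1]: immediate repeats, passing notes splitting the
  widest leaps, wide leaps, IOI-palette diversification, strict
  velocity ramps, accents, rests, linear tempo drift, articulation
  contrast, and appended retrograde or transposed copies of earlier
  segments. Output is capped at 30 notes, with appended structures
  budgeted for before trimming so planted material survives.
- **Cohorts**: 68 participants in 10 groups by default; sessions m0
  (baseline) through m12 cover four 3-month training blocks, two of
  improvisation (I) and two of replication (R). The six I/R block
  orders cycle across groups and each block alternates instrument,
  half the groups starting on keyboard — with round-robin group
  assignment the instrument indicator is exactly uncorrelated with
  block count. Items 1–3 are replications (item 1 easiest, 2 hardest,
  3 intermediate, emulating pre-rehearsal and short practice); items
  4–5 are improvisations with 1–2 claimed tasks. Replication error
  parameters shrink by a factor `replication_learning_rate` (default
  0.5) per completed R block from a deliberately poor baseline
  (p_sub 0.35, completion 0.6); planted task intensity rises with the
  I-block count (base 0.15, gain 0.35); a lognormal per-participant
  ability factor (σ 0.2) scales both. Setting the rate to 1 and the
  gain to 0 gives a null cohort with no trend. Rhythm learning is not
  planted by default: timing jitter shrinks with training only through
  the shared error scaling, and no rhythmic structure is taught —
  mirroring the view that inter-onset timing is at best modestly
  learnable in this setting.

What the generator does **not** emulate: perceptual or motor realism,
aural-test performance, drop-out, expressive microtiming, or any
correlation structure between error types beyond the shared ability
factor. Passing tests therefore demonstrate that the measures detect
and order the behaviours they target, not that they are calibrated to
real learners.

## Numerical choices and degenerate inputs

- DTW ties: lexicographic (cost, path length), then diagonal-step and
  latest-end preference (see above).
- Histograms: half-open bins, catch-all extremes; `np.digitize`
  semantics.
- Entropy uses base 2 (bits); KL divergence natural log inside
  exp(−J), so the two are internally consistent but not interchangeable.
- Constant columns cannot be scaled or standardised (explicit error);
  missing cells propagate as missing, never as zero.
- Velocity-0 note-ons, unmatched note-ons, and zero-duration notes are
  resolved at the I/O layer as described; empty performances are
  rejected wherever a measure needs notes.

## Problem sizes used in the checks

The test and acceptance runs use sizes chosen to make every property
measurable in seconds to minutes on one CPU: exhaustive DTW oracle
comparison over all sequence pairs of lengths ≤ 3 on a 5-pitch
alphabet plus seeded samples at lengths 4–6 (the full pairwise space
at length 6 is astronomically large; the sampled check covers it
without loss of the exhaustive guarantee at short lengths); exhaustive
pattern-detector enumeration at lengths ≤ 8 over 3 pitches; 100 seeds
per condition for degradation and task-recovery curves; and 24-
participant cohorts over 20 design seeds for sign recovery (the
default design remains 68 participants).

## Known limitations

- The DTW step pattern, cost cap and 0–1 scaling are declared package
  constants; other reasonable choices (slope constraints, windowing)
  would give different absolute values while preserving orderings.
- The aligned proportion counts exact-pitch matches by default, so a
  consistently transposed but otherwise perfect performance scores 0
  coverage; `match_tol` is the configurable escape hatch.
- The sequence detector requires exact interval-pattern identity;
  near-sequences with one altered interval are not counted.
- Variance-sharing weights assume a single dominant shared factor;
  multi-factor composites are out of scope.
- The improvisation prompt is carried as metadata only; no measure
  currently scores prompt usage itself.
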