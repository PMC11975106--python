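# melodymetrics

Objective, computational scoring of musical learning from monophonic
MIDI performances. The package answers two questions a music-education
study needs answered at scale, without human raters:

1. **Replication** — how faithfully does a performance reproduce a
   reference melody played from aural memory?
2. **Improvisation** — how much structured melodic variation does an
   improvisation on a short aural prompt contain, and which taught
   variation methods does it exhibit?

It is aimed at researchers in music cognition and music education who
record short, single-line (monophonic) keyboard performances as
Standard MIDI Files and need reproducible per-performance scores they
can feed into statistical models.

## The measures

**Replication** is scored by eight measures in [0, 1], built around
subsequence dynamic time warping (DTW). With performed pitch sequence
*p* and reference *r*, the DTW alignment is open at both ends of the
reference, so a correctly played fragment aligns to its best reference
segment. The local cost between notes is min(|Δ semitones|, 12) and the
normalised distance divides the optimal path's cumulative cost by
(path length × 12):

- `pitchdtwsim` = 1 − normalised distance;
- `palignedprop` = (reference notes matched exactly under the
  alignment) / (reference length) — DTW alone does not charge for
  playing only part of the tune, this does;
- `pitchdtwladj` = `pitchdtwsim` × `palignedprop`, the headline
  length-adjusted similarity. A perfect 5-note fragment of a 15-note
  piece scores 1 × 5/15 = 1/3.

The `pioidtwsim` / `pioialignedprop` / `pioidtwladj` triple repeats
this jointly on (pitch, log₂(IOI/median IOI)) features, where IOI is
the inter-onset interval; the log-median normalisation makes every
timing measure invariant to a uniform tempo change. `klpitchsim` and
`klioisim` are order-blind distributional similarities,
exp(−J) for the symmetrised (Jeffreys) Kullback–Leibler divergence
between smoothed pitch (resp. binned log-IOI) histograms.

**Improvisation** is scored by 18 feature measures ("scoretypes"):
note count, entropies and ranges of pitches / intervals / IOIs, counts
of immediate repeats, passing notes, crescendos and accents, the
proportion of silent time, windowed tempo-variation statistics,
articulation (duration-to-IOI) variation, and detectors for retrograde
(reversed) and transposed-sequence repetitions of earlier material.
Each of the 14 taught variation methods maps to a designated scoretype
(`TASK_SCORETYPE`).

A synthetic-performance module generates reference melodies (3–5-note
fragments within the taught C4–G5 span), error-perturbed learner
replications, task-driven improvisations with known planted structure,
and fully counterbalanced longitudinal cohorts, so the whole pipeline
is testable end to end with no recorded data. Posterior-summary
helpers (one-sided evidence ratios, credibility intervals) express
results the way Bayesian analyses of such studies report them.

## Worked example

```python
import melodymetrics as mm

ref = mm.generate_reference(15, seed=11)           # 15-note reference
model = mm.ReplicationErrorModel(p_sub=0.2, completion=0.8,
                                 timing_jitter_sd=0.1)
perf, log = mm.simulate_replication(ref, model, seed=3)
print(log)  # {'n_ref': 15, 'n_kept': 12, 'n_sub': 3, 'n_del': 1, 'n_ins': 1}

for name, value in mm.score_replication(perf, ref).as_dict().items():
    print(f"{name:16s} {value:.3f}")
```

prints

```
pitchdtwsim      0.958
palignedprop     0.533
pitchdtwladj     0.511
pioidtwsim       0.944
pioialignedprop  0.500
pioidtwladj      0.472
klpitchsim       0.848
klioisim         0.895
```

The learner attempted 80% of the piece (12 of 15 notes kept) and made
three substitutions, one omission and one insertion: the performed
segment is still highly similar to its best reference match
(`pitchdtwsim` 0.96), but only 8 of the 15 reference notes found an
exact counterpart (`palignedprop` 0.53), so the length-adjusted score
is 0.51. The distributional scores (0.85, 0.90) show the pitch set and
rhythm remained stylistically close.

Improvisation scoring with a planted retrograde:

```python
prompt = mm.generate_reference(4, seed=2)
improv, ilog = mm.simulate_improvisation(
    prompt, [mm.ImprovTaskSpec(task=12, intensity=1.0)], seed=5)
s = mm.score_improvisation(improv)
print(s.NumNotes, s.M13retronotes)   # 17.0 5.0  (5 notes planted, 5 found)
```

The same operations are available from the shell:

```bash
melodymetrics score-replication --perf perf.mid --ref ref.mid --out scores.csv
melodymetrics score-improv --perf improv.mid
melodymetrics simulate-cohort --seed 1 --out cohort/
melodymetrics run --out results/            # full simulate->score->combine
melodymetrics posterior-summary --draws draws.csv --direction positive
```

## Layout

- `src/melodymetrics/` — `midi_io`/`smf` (Standard MIDI File I/O),
  `events` (note-event model), `replication` (8 fidelity measures),
  `improvisation` (18 scoretypes), `combine` (scaling,
  standardisation, variance-sharing composites), `inference`
  (posterior summaries), `simulate` (synthetic generators), `pipeline`
  + `cli` (end-to-end runs).
- `docs/methods.md` — the model, parameter and design notes.
- `tests/` — unit, property and acceptance tests with independent
  brute-force oracles.
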