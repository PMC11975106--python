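"""Synthetic performance generation.

Emulates the study conditions the measures were built for: reference
melodies assembled from 3-5-note fragments inside the taught 20-key
span (C4-G5, MIDI 60-79); learner replications degraded by pitch
substitutions, omissions, insertions, partial completion, timing jitter
and velocity noise; improvisations elaborating a 3-5-note aural prompt
with up to 14 taught variation methods at a controllable intensity; and
full longitudinal cohorts with a counterbalanced cross-over of
improvisation/replication training blocks and two instruments.

Every generator takes a seed (or NumPy Generator) and is deterministic
given it; generators also return an edit log of what was planted, which
the tests use as ground truth for lower bounds on detected structure.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from melodymetrics.errors import DomainError
from melodymetrics.events import NoteEvent, Performance, PerformanceMetadata
from melodymetrics.midi_io import METADATA_COLUMNS, metadata_to_row, write_midi

PITCH_LO, PITCH_HI = 60, 79  # C4-G5, the 20-key taught span
REFERENCE_IOIS = (0.25, 0.5, 1.0)
MAX_REFERENCE_NOTES = 30
MAX_IMPROV_NOTES = 30

# Small steps dominate; occasional leaps of 3-4 semitones.
_STEP_VALUES = np.array([-4, -3, -2, -1, 1, 2, 3, 4])
_STEP_WEIGHTS = np.array([0.025, 0.025, 0.2, 0.25, 0.25, 0.2, 0.025, 0.025])

# Freer motion for improvised continuations: larger leaps are common, so
# stepwise "passing" motion is not already ubiquitous at baseline.
_IMPROV_STEP_VALUES = np.array([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5])
_IMPROV_STEP_WEIGHTS = np.array(
    [0.08, 0.09, 0.10, 0.11, 0.12, 0.12, 0.11, 0.10, 0.09, 0.08]
)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _reflect(pitch: int, lo: int = PITCH_LO, hi: int = PITCH_HI) -> int:
    while pitch < lo or pitch > hi:
        if pitch < lo:
            pitch = 2 * lo - pitch
        if pitch > hi:
            pitch = 2 * hi - pitch
    return pitch


@dataclass(frozen=True)
class ReplicationErrorModel:
    """Per-note error process for a simulated learner replication.

    p_sub / p_del / p_ins   substitution, omission, insertion probabilities
    sub_decay               geometric decay of substitution magnitude over
                            +-1..4 semitones (P(k) ~ sub_decay**(k-1))
    completion              proportion of the reference attempted (0, 1]
    timing_jitter_sd        lognormal sigma of multiplicative IOI jitter
    velocity_sd             SD of additive Gaussian velocity noise (MIDI units)
    """

    p_sub: float = 0.1
    p_del: float = 0.05
    p_ins: float = 0.05
    sub_decay: float = 0.5
    completion: float = 1.0
    timing_jitter_sd: float = 0.05
    velocity_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_del", "p_ins"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DomainError(f"{name} must be a probability")
        if self.p_sub + self.p_del > 1.0:
            raise DomainError("p_sub + p_del must not exceed 1")
        if not 0.0 < self.completion <= 1.0:
            raise DomainError("completion must lie in (0, 1]")
        if self.timing_jitter_sd < 0 or self.velocity_sd < 0:
            raise DomainError("noise SDs must be non-negative")

    def scaled(self, factor: float) -> "ReplicationErrorModel":
        """Error rates multiplied by ``factor``; completion pulled towards 1."""
        return replace(
            self,
            p_sub=min(0.6, self.p_sub * factor),
            p_del=min(0.3, self.p_del * factor),
            p_ins=min(0.3, self.p_ins * factor),
            completion=float(np.clip(1.0 - (1.0 - self.completion) * factor, 0.1, 1.0)),
            timing_jitter_sd=self.timing_jitter_sd * factor,
            velocity_sd=self.velocity_sd * factor,
        )


@dataclass(frozen=True)
class ImprovTaskSpec:
    """One taught variation method applied at a given intensity."""

    task: int
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.task <= 14:
            raise DomainError("task must be one of the 14 taught methods")
        if not 0.0 <= self.intensity <= 1.0:
            raise DomainError("intensity must lie in [0, 1]")


@dataclass
class SimulationDesign:
    """Cohort layout and learning-trajectory parameters.

    Ten groups counterbalance the order of improvisation (I) and
    replication (R) training blocks and which instrument each block
    uses; sessions run from baseline (m0) through the four blocks
    (m3-m12). ``replication_learning_rate`` multiplies error parameters
    per completed replication block (1.0 = no learning);
    ``improv_gain`` raises planted task intensity per improvisation
    block (0 = no learning).
    """

    n_participants: int = 68
    groups: int = 10
    sessions: tuple = ("m0", "m3", "m6", "m9", "m12")
    base_error: ReplicationErrorModel = field(
        default_factory=lambda: ReplicationErrorModel(
            p_sub=0.35,
            p_del=0.12,
            p_ins=0.08,
            completion=0.6,
            timing_jitter_sd=0.15,
            velocity_sd=8.0,
        )
    )
    replication_learning_rate: float = 0.5
    improv_base_intensity: float = 0.15
    improv_gain: float = 0.35
    ability_sd: float = 0.2
    reference_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.groups < 4:
            raise DomainError("counterbalancing needs at least 4 groups")
        if not 0.0 < self.replication_learning_rate <= 1.0:
            raise DomainError("replication_learning_rate must lie in (0, 1]")


# The six orders of two improvisation and two replication blocks.
_BLOCK_ORDERS = ("IIRR", "IRIR", "IRRI", "RIIR", "RIRI", "RRII")


def generate_reference(length: int, seed) -> Performance:
    """Reference melody of ``length`` notes from 3-5-note fragments.

    Pitches stay within MIDI 60-79 with mostly stepwise motion
    (reflecting at the range edges); each fragment is rhythmically
    uniform with its IOI drawn from {0.25, 0.5, 1.0} s.
    """
    if not 3 <= length <= MAX_REFERENCE_NOTES:
        raise DomainError(f"reference length must be 3-{MAX_REFERENCE_NOTES}")
    rng = _rng(seed)
    pitches: list[int] = []
    iois: list[float] = []
    pitch = int(rng.integers(PITCH_LO + 2, PITCH_HI - 2))
    while len(pitches) < length:
        frag_len = min(int(rng.integers(3, 6)), length - len(pitches))
        frag_ioi = float(rng.choice(REFERENCE_IOIS, p=(0.3, 0.5, 0.2)))
        for _ in range(frag_len):
            pitches.append(pitch)
            iois.append(frag_ioi)
            pitch = _reflect(pitch + int(rng.choice(_STEP_VALUES, p=_STEP_WEIGHTS)))
    notes = []
    onset = 0.0
    for p, ioi in zip(pitches, iois):
        velocity = int(np.clip(64 + rng.integers(-3, 4), 1, 127))
        notes.append(NoteEvent(p, onset, onset + 0.9 * ioi, velocity))
        onset += ioi
    return Performance(notes)


def _tokens(perf: Performance) -> list[list]:
    """(pitch, ioi, duration, velocity) tokens; last note's ioi = duration."""
    out = []
    notes = perf.notes
    for i, n in enumerate(notes):
        ioi = notes[i + 1].onset - n.onset if i + 1 < len(notes) else n.duration
        out.append([n.pitch, ioi, n.duration, n.velocity])
    return out


def _untokenize(tokens: Sequence[Sequence], metadata=None) -> Performance:
    notes = []
    onset = 0.0
    for pitch, ioi, dur, vel in tokens:
        dur = max(min(dur, ioi), 1e-3)
        notes.append(
            NoteEvent(
                int(np.clip(pitch, 0, 127)),
                onset,
                onset + dur,
                int(np.clip(round(vel), 1, 127)),
            )
        )
        onset += max(ioi, 1e-3)
    return Performance(notes, metadata or PerformanceMetadata())


def simulate_replication(
    ref: Performance, model: ReplicationErrorModel, seed
) -> tuple[Performance, dict]:
    """Degrade a reference through the learner error model.

    Keeps the first ceil(completion x n) notes, applies per-note
    deletion / substitution / insertion, multiplies IOIs by lognormal
    jitter and adds Gaussian velocity noise. Returns the performance
    and an edit log with ground-truth counts.
    """
    rng = _rng(seed)
    tokens = _tokens(ref)
    kept = max(1, math.ceil(model.completion * len(tokens)))
    tokens = [list(t) for t in tokens[:kept]]

    mags = np.array([model.sub_decay**k for k in range(4)])
    mags = mags / mags.sum()

    log = {"n_ref": len(ref), "n_kept": kept, "n_sub": 0, "n_del": 0, "n_ins": 0}
    out: list[list] = []
    for token in tokens:
        r = rng.random()
        if r < model.p_del:
            log["n_del"] += 1
            if out:
                out[-1][1] += token[1]  # absorb the deleted note's time
            continue
        pitch, ioi, dur, vel = token
        if r < model.p_del + model.p_sub:
            magnitude = 1 + int(rng.choice(4, p=mags))
            pitch = int(np.clip(pitch + rng.choice((-1, 1)) * magnitude, 0, 127))
            log["n_sub"] += 1
        out.append([pitch, ioi, dur, vel])
        if rng.random() < model.p_ins:
            ins_pitch = _reflect(pitch + int(rng.choice(_STEP_VALUES, p=_STEP_WEIGHTS)))
            out.append([ins_pitch, ioi, dur, vel])
            log["n_ins"] += 1
    if not out:
        out = [list(tokens[0])]

    for token in out:
        jitter = float(rng.lognormal(0.0, model.timing_jitter_sd)) if model.timing_jitter_sd else 1.0
        ratio = token[2] / token[1]
        token[1] *= jitter
        token[2] = ratio * token[1]
        if model.velocity_sd:
            token[3] = token[3] + rng.normal(0.0, model.velocity_sd)
    return _untokenize(out, ref.metadata), log


def _insert_positions(rng, n_tokens: int, count: int) -> list[int]:
    if count <= 0 or n_tokens < 2:
        return []
    hi = max(1, n_tokens - 1)
    return sorted(rng.integers(1, hi + 1, size=count).tolist(), reverse=True)


def simulate_improvisation(
    prompt: Performance,
    tasks: Sequence[ImprovTaskSpec],
    max_notes: int = MAX_IMPROV_NOTES,
    seed=None,
    base_length: int = 12,
) -> tuple[Performance, dict]:
    """Elaborate a 3-5-note aural prompt, planting the requested methods.

    The prompt is continued by stepwise motion to ``base_length`` notes,
    then each task's transformation is applied with frequency/size
    proportional to its intensity: repeats and passing notes are
    inserted, leaps widened, rhythms diversified, crescendo ramps and
    accents imposed on velocity, rests opened, tempo drifted,
    articulation contrasted, and retrograde/transposed copies of earlier
    segments appended. Output never exceeds ``max_notes``. The edit log
    records what was planted per task.
    """
    if not 3 <= len(prompt) <= 5:
        raise DomainError("prompt must have 3-5 notes")
    if len(tasks) > 14:
        raise DomainError("at most 14 tasks")
    rng = _rng(seed)
    tokens = [list(t) for t in _tokens(prompt)]
    for t in tokens:  # normalise prompt rhythm to the improvising pulse
        t[1], t[2] = 0.5, 0.45
    pitch = tokens[-1][0]
    while len(tokens) < base_length:
        pitch = _reflect(
            pitch + int(rng.choice(_IMPROV_STEP_VALUES, p=_IMPROV_STEP_WEIGHTS))
        )
        tokens.append([pitch, 0.5, 0.45, 64])

    log: dict = {spec.task: {} for spec in tasks}
    specs = sorted(tasks, key=lambda s: s.task)
    by_task = {s.task: s.intensity for s in specs}

    # --- pitch-inserting methods -------------------------------------
    if 1 in by_task:  # immediate repeats
        n = round(by_task[1] * 4)
        for pos in _insert_positions(rng, len(tokens), n):
            tokens.insert(pos, list(tokens[pos - 1]))
        log[1]["repeats"] = n
    if 2 in by_task:  # passing/neighbour notes
        n = round(by_task[2] * 6)
        for _ in range(n):
            # split the widest remaining leap with a true passing note
            gaps = [abs(tokens[i][0] - tokens[i - 1][0]) for i in range(1, len(tokens))]
            pos = 1 + int(np.argmax(gaps))
            prev, nxt = tokens[pos - 1][0], tokens[pos][0]
            if abs(nxt - prev) >= 2:
                between = prev + (nxt - prev) // 2
            else:
                between = prev + int(rng.choice((-1, 1)))
            tokens.insert(pos, [_reflect(between, 50, 90), 0.5, 0.45, 64])
        log[2]["passing"] = n
    for task in (3, 14):  # wide leaps / out-of-set pitches
        if task in by_task and by_task[task] > 0:
            intensity = by_task[task]
            n = max(1, round(intensity * 3))
            leap = 6 + round(10 * intensity)
            for pos in _insert_positions(rng, len(tokens), n):
                target = tokens[pos - 1][0] + int(rng.choice((-1, 1))) * leap
                tokens.insert(pos, [_reflect(target, 50, 90), 0.5, 0.45, 64])
            log[task]["leaps"] = n
            log[task]["leap_size"] = leap

    # --- appended structures (retrograde / sequence) ------------------
    append_budget = 0
    planned: list[tuple[int, int]] = []
    for task in (12, 13):
        if task in by_task and by_task[task] > 0:
            seg_len = 3 + round(2 * by_task[task])
            planned.append((task, seg_len))
            append_budget += seg_len
    if append_budget:
        tokens = tokens[: max(6, max_notes - append_budget)]
    for task, seg_len in planned:
        seg_len = min(seg_len, len(tokens))
        start = int(rng.integers(0, len(tokens) - seg_len + 1))
        segment = [list(t) for t in tokens[start : start + seg_len]]
        if task == 12:
            addition = [list(t) for t in reversed(segment)]
        else:
            shift = int(rng.choice((-4, -3, -2, 2, 3, 4)))
            addition = [[t[0] + shift, t[1], t[2], t[3]] for t in segment]
        tokens.extend(addition)
        log[task]["planted_len"] = seg_len

    # --- rhythm and tempo ---------------------------------------------
    if 4 in by_task:  # IOI diversity
        k = 1 + round(by_task[4] * 3)
        palette = (0.5, 0.25, 1.0, 0.75)[:k]
        for t in tokens:
            ratio = t[2] / t[1]
            t[1] = float(rng.choice(palette))
            t[2] = ratio * t[1]
        log[4]["ioi_palette"] = k
    if 8 in by_task:  # gradual tempo change
        drift = by_task[8] * 1.5
        n = len(tokens)
        for i, t in enumerate(tokens):
            factor = 1.0 + drift * i / max(1, n - 1)
            ratio = t[2] / t[1]
            t[1] *= factor
            t[2] = ratio * t[1]
        log[8]["drift"] = drift

    # --- rests and articulation ---------------------------------------
    if 7 in by_task:  # rests between notes
        frac = 0.6 * by_task[7]
        idx = rng.permutation(len(tokens))[: round(frac * len(tokens))]
        for i in idx:
            tokens[i][2] = tokens[i][1] * 0.25
        log[7]["rests"] = len(idx)
    for task in (9, 10, 11):  # legato / staccato / slurred contrast
        if task in by_task and by_task[task] > 0:
            contrast = 0.8 * by_task[task]
            long_r, short_r = 1.0, 1.0 - contrast
            if task == 10:  # staccato-centred
                long_r, short_r = 0.2 + contrast, 0.2
            for i, t in enumerate(tokens):
                if task == 11:
                    ratio = long_r if rng.random() < 0.5 else short_r
                else:
                    ratio = long_r if i % 2 == 0 else short_r
                t[2] = t[1] * max(ratio, 0.05)
            log[task]["contrast"] = contrast

    # --- dynamics ------------------------------------------------------
    if 5 in by_task and by_task[5] > 0:  # crescendos / diminuendos
        n_ramps = 1 + round(by_task[5] * 2)
        span = 10 + round(30 * by_task[5])
        length = 4
        starts = [
            int(s)
            for s in rng.permutation(max(1, len(tokens) - length))[:n_ramps]
        ]
        placed = 0
        used: list[int] = []
        for s in sorted(starts):
            if any(abs(s - u) < length + 1 for u in used):
                continue
            direction = int(rng.choice((-1, 1)))
            base_vel = 60 - direction * span // 2
            for k in range(length):
                tokens[s + k][3] = int(
                    np.clip(base_vel + direction * span * k / (length - 1), 1, 127)
                )
            used.append(s)
            placed += 1
        log[5]["ramps"] = placed
        log[5]["span"] = span
    if 6 in by_task:  # accents
        n = round(by_task[6] * 5)
        idx = rng.permutation(len(tokens))[:n]
        for i in idx:
            tokens[i][3] = min(127, tokens[i][3] + 25)
        log[6]["accents"] = len(idx)

    tokens = tokens[:max_notes]
    tasks_meta = tuple(s.task for s in specs)
    meta = PerformanceMetadata(
        nimptasks=len(tasks_meta) or None, claimed_tasks=tasks_meta
    )
    return _untokenize(tokens, meta), log


@dataclass
class CohortRecord:
    """One simulated performance with its provenance."""

    performance: Performance
    metadata: PerformanceMetadata
    kind: str  # "replication" | "improvisation"
    reference: Optional[Performance]
    edit_log: dict


@dataclass
class Cohort:
    records: list[CohortRecord]
    references: dict[tuple[str, int], Performance]
    design: SimulationDesign

    def write(self, out_dir) -> Path:
        """Write all MIDI files plus the sidecar metadata CSV."""
        out_dir = Path(out_dir)
        midi_dir = out_dir / "midi"
        midi_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, rec in enumerate(self.records):
            m = rec.metadata
            name = f"{m.participant_id}_{m.session}_item{m.item}.mid"
            write_midi(rec.performance, midi_dir / name)
            rows.append(metadata_to_row(m, Path("midi") / name))
        for (session, item), ref in self.references.items():
            write_midi(ref, midi_dir / f"reference_{session}_item{item}.mid")
        csv_path = out_dir / "metadata.csv"
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=METADATA_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
        return csv_path


def _group_plan(design: SimulationDesign) -> list[dict]:
    plans = []
    for g in range(design.groups):
        order = _BLOCK_ORDERS[g % len(_BLOCK_ORDERS)]
        first_instrument = "kbipK" if g % 2 == 0 else "kbipI"
        instruments = [
            first_instrument if b % 2 == 0 else
            ("kbipI" if first_instrument == "kbipK" else "kbipK")
            for b in range(4)
        ]
        plans.append({"order": order, "instruments": instruments})
    return plans


def generate_cohort(design: SimulationDesign) -> Cohort:
    """Simulate the full longitudinal corpus.

    Each participant performs 5 items per session: items 1-3 are
    replications of session/item-specific reference melodies (item 1
    rendered best, item 2 worst, item 3 intermediate, mirroring
    pre-rehearsal and short practice), items 4-5 improvisations on a
    3-5-note prompt with 1-2 claimed tasks. Replication error rates
    shrink with the replication block count (repct) and planted task
    intensity grows with the improvisation count (imprct); instrument
    and block orders are counterbalanced across groups so the
    instrument indicator is uncorrelated with block count by
    construction.
    """
    rng = np.random.default_rng(design.seed)
    plans = _group_plan(design)
    item_effect = {1: 0.6, 2: 1.2, 3: 0.9}

    references: dict[tuple[str, int], Performance] = {}
    for session in design.sessions:
        for item in (1, 2, 3):
            references[(session, item)] = generate_reference(
                design.reference_length, rng
            )
    prompts: dict[str, Performance] = {
        session: generate_reference(int(rng.integers(3, 6)), rng)
        for session in design.sessions
    }

    records: list[CohortRecord] = []
    for pid in range(design.n_participants):
        group = pid % design.groups
        plan = plans[group]
        ability = float(rng.lognormal(0.0, design.ability_sd))
        for k, session in enumerate(design.sessions):
            blocks = plan["order"][:k]
            imprct, repct = blocks.count("I"), blocks.count("R")
            instrument = plan["instruments"][min(k, 3)]
            error = design.base_error.scaled(
                ability * design.replication_learning_rate**repct
            )
            intensity = float(
                np.clip(
                    design.improv_base_intensity
                    + design.improv_gain * imprct / ability,
                    0.0,
                    1.0,
                )
            )
            for item in (1, 2, 3):
                ref = references[(session, item)]
                model = error.scaled(item_effect[item])
                perf, log = simulate_replication(ref, model, rng)
                meta = PerformanceMetadata(
                    participant_id=f"p{pid:03d}",
                    group=f"g{group}",
                    session=session,
                    item=item,
                    instrument=instrument,
                    imprct=imprct,
                    repct=repct,
                )
                perf.metadata = meta
                records.append(
                    CohortRecord(perf, meta, "replication", ref, log)
                )
            for item in (4, 5):
                n_tasks = 1 if item == 5 else int(rng.integers(1, 3))
                chosen = rng.choice(14, size=n_tasks, replace=False) + 1
                specs = [ImprovTaskSpec(int(t), intensity) for t in chosen]
                perf, log = simulate_improvisation(prompts[session], specs, seed=rng)
                meta = PerformanceMetadata(
                    participant_id=f"p{pid:03d}",
                    group=f"g{group}",
                    session=session,
                    item=item,
                    instrument=instrument,
                    imprct=imprct,
                    repct=repct,
                    nimptasks=n_tasks,
                    claimed_tasks=tuple(int(t) for t in chosen),
                )
                perf.metadata = meta
                records.append(
                    CohortRecord(perf, meta, "improvisation", None, log)
                )
    return Cohort(records, references, design)
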