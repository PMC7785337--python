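"""Stimulus paradigm design for auditory oddball experiments.

Generates the six tone-sequence paradigms used to dissect mismatch
responses: oddball (ascending/descending), cascade (ascending/descending),
many-standards, and DEV-alone. All paradigms present 400 tones at
2 stimuli/s (75 ms tones, 5 ms ramps) drawn from a 10-tone set spaced at
0.5 octaves, so that the deviant probability (10%) is matched by the
per-tone probability in both no-repetition controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Paradigm",
    "Direction",
    "ToneSet",
    "StimulusEvent",
    "StimulusSequence",
    "ValidationReport",
    "make_tone_set",
    "make_oddball",
    "make_cascade",
    "make_many_standards",
    "make_dev_alone",
    "validate_sequence",
    "events_to_frame",
    "sequence_metadata",
]


class Role(str, Enum):
    STD = "STD"
    DEV = "DEV"
    CASCADE = "CASCADE"
    MANY_STD = "MANY_STD"
    DEV_ALONE = "DEV_ALONE"
    MUTED = "MUTED"


class Paradigm(str, Enum):
    ODDBALL_ASCENDING = "oddball_ascending"
    ODDBALL_DESCENDING = "oddball_descending"
    CASCADE_ASCENDING = "cascade_ascending"
    CASCADE_DESCENDING = "cascade_descending"
    MANY_STANDARDS = "many_standards"
    DEV_ALONE = "dev_alone"


class Direction(str, Enum):
    ASCENDING = "ascending"
    DESCENDING = "descending"
    NONE = "none"


@dataclass(frozen=True)
class ToneSet:
    """An ordered set of pure-tone frequencies presented at one level."""

    frequencies_hz: tuple
    intensity_db: float = 60.0
    octave_step: float = 0.5

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.size < 2:
            raise ValueError("a tone set needs at least 2 frequencies")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly ascending")

    def __len__(self) -> int:
        return len(self.frequencies_hz)


@dataclass(frozen=True)
class StimulusEvent:
    """One timed tone slot; a muted slot has ``tone_index`` None."""

    onset_s: float
    role: Role
    tone_index: Optional[int]
    duration_s: float = 0.075
    ramp_s: float = 0.005

    def __post_init__(self):
        if self.duration_s <= 2 * self.ramp_s:
            raise ValueError("duration must exceed twice the ramp")
        if (self.tone_index is None) != (self.role is Role.MUTED):
            raise ValueError("tone_index is None iff role is MUTED")


@dataclass(frozen=True)
class StimulusSequence:
    paradigm: Paradigm
    events: tuple
    tones: ToneSet
    soa_s: float = 0.5
    target_tone: Optional[int] = None
    direction: Direction = Direction.NONE
    seed: Optional[int] = None

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration_s(self) -> float:
        return self.n_events * self.soa_s

    def onsets(self, role: Optional[Role] = None) -> np.ndarray:
        return np.array(
            [e.onset_s for e in self.events if role is None or e.role is role]
        )

    def tone_indices(self) -> np.ndarray:
        """Tone index per event; -1 marks muted slots."""
        return np.array(
            [-1 if e.tone_index is None else e.tone_index for e in self.events]
        )

    def role_mask(self, role: Role) -> np.ndarray:
        """Boolean mask of events with the given role."""
        return np.array([e.role is role for e in self.events])

    def role_positions(self, role: Role) -> np.ndarray:
        return np.nonzero(self.role_mask(role))[0]


def make_tone_set(
    base_hz: float,
    octave_step: float = 0.5,
    n: int = 10,
    intensity_db: float = 60.0,
) -> ToneSet:
    """Build ``n`` tones at ``f[i] = base_hz * 2**(i*octave_step)``."""
    if base_hz <= 0:
        raise ValueError("base frequency must be positive")
    if n < 2:
        raise ValueError("need at least 2 tones")
    freqs = tuple(base_hz * 2.0 ** (i * octave_step) for i in range(n))
    return ToneSet(freqs, intensity_db=intensity_db, octave_step=octave_step)


def _oddball_dev_positions(
    n_events: int, n_dev: int, first_std: int, min_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw of DEV positions with the first-``first_std`` slots STD and
    at least ``min_gap`` STDs between consecutive DEVs.

    Uses the stars-and-bars bijection: position sets p_0 < ... < p_{k-1} in
    [first_std, n_events-1] with p_{i+1} - p_i >= min_gap correspond
    one-to-one to sets of distinct q_i = p_i - (min_gap-1)*i in a shrunken
    range, so a uniform sample of the q's is a uniform sample over all
    valid placements.
    """
    shrink = min_gap - 1
    lo = first_std
    hi = n_events - 1 - shrink * (n_dev - 1)
    n_avail = hi - lo + 1
    if n_avail < n_dev:
        raise ValueError(
            f"cannot place {n_dev} deviants with gap {min_gap} in {n_events} slots"
        )
    q = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_dev, replace=False))
    return q + shrink * np.arange(n_dev)


def make_oddball(
    tones: ToneSet,
    target_tone: int,
    direction: Direction = Direction.ASCENDING,
    n_events: int = 400,
    dev_prob: float = 0.10,
    soa_s: float = 0.5,
    seed: int = 0,
    min_std_gap: int = 3,
    n_initial_std: int = 10,
) -> StimulusSequence:
    """Oddball sequence: a repeated standard tone with rare deviants.

    The deviant is ``target_tone``; the standard is the adjacent tone below
    (ascending: DEV higher than STD) or above it (descending). The deviant
    count is enforced exactly at ``round(dev_prob * n_events)``, the first
    ``n_initial_std`` events are standards, and at least ``min_std_gap``
    standards separate consecutive deviants.
    """
    direction = Direction(direction)
    n_dev_f = dev_prob * n_events
    n_dev = int(round(n_dev_f))
    if abs(n_dev_f - n_dev) > 1e-9:
        raise ValueError("dev_prob * n_events must be an integer")
    if direction is Direction.ASCENDING:
        std_tone = target_tone - 1
    elif direction is Direction.DESCENDING:
        std_tone = target_tone + 1
    else:
        raise ValueError("oddball direction must be ascending or descending")
    if not (0 <= target_tone < len(tones) and 0 <= std_tone < len(tones)):
        raise ValueError("target tone or its standard partner out of range")

    rng = np.random.default_rng(seed)
    tone_idx = np.full(n_events, std_tone, dtype=int)
    roles = [Role.STD] * n_events
    if n_dev > 0:
        dev_pos = _oddball_dev_positions(
            n_events, n_dev, n_initial_std, min_std_gap + 1, rng
        )
        tone_idx[dev_pos] = target_tone
        for p in dev_pos:
            roles[p] = Role.DEV

    events = tuple(
        StimulusEvent(onset_s=i * soa_s, role=roles[i], tone_index=int(tone_idx[i]))
        for i in range(n_events)
    )
    paradigm = (
        Paradigm.ODDBALL_ASCENDING
        if direction is Direction.ASCENDING
        else Paradigm.ODDBALL_DESCENDING
    )
    return StimulusSequence(
        paradigm=paradigm,
        events=events,
        tones=tones,
        soa_s=soa_s,
        target_tone=target_tone,
        direction=direction,
        seed=seed,
    )


def make_cascade(
    tones: ToneSet,
    direction: Direction = Direction.ASCENDING,
    n_events: int = 400,
    soa_s: float = 0.5,
    target_tone: Optional[int] = None,
) -> StimulusSequence:
    """Cascade control: a deterministic cyclic frequency ramp.

    Every tone occurs ``n_events / len(tones)`` times, matching the deviant
    probability, and the tone preceding any tone of interest is its ramp
    predecessor — the same local transition as in the same-direction oddball.
    """
    direction = Direction(direction)
    n_tones = len(tones)
    if n_events % n_tones != 0:
        raise ValueError("n_events must be divisible by the number of tones")
    if direction is Direction.ASCENDING:
        ramp = np.arange(n_tones)
        paradigm = Paradigm.CASCADE_ASCENDING
    elif direction is Direction.DESCENDING:
        ramp = np.arange(n_tones)[::-1]
        paradigm = Paradigm.CASCADE_DESCENDING
    else:
        raise ValueError("cascade direction must be ascending or descending")
    tone_idx = np.tile(ramp, n_events // n_tones)
    events = tuple(
        StimulusEvent(onset_s=i * soa_s, role=Role.CASCADE, tone_index=int(tone_idx[i]))
        for i in range(n_events)
    )
    return StimulusSequence(
        paradigm=paradigm,
        events=events,
        tones=tones,
        soa_s=soa_s,
        target_tone=target_tone,
        direction=direction,
    )


def make_many_standards(
    tones: ToneSet,
    n_events: int = 400,
    soa_s: float = 0.5,
    seed: int = 0,
    target_tone: Optional[int] = None,
) -> StimulusSequence:
    """Many-standards control: random assorted tones at equal probability.

    Built from per-block random permutations of the tone set with no
    immediate repetition across block boundaries, so no tone ever repeats
    back-to-back (no stimulus-specific adaptation is induced).
    """
    n_tones = len(tones)
    if n_events % n_tones != 0:
        raise ValueError("n_events must be divisible by the number of tones")
    rng = np.random.default_rng(seed)
    blocks = []
    prev_last = -1
    for _ in range(n_events // n_tones):
        while True:
            perm = rng.permutation(n_tones)
            if perm[0] != prev_last:
                break
        blocks.append(perm)
        prev_last = perm[-1]
    tone_idx = np.concatenate(blocks)
    events = tuple(
        StimulusEvent(
            onset_s=i * soa_s, role=Role.MANY_STD, tone_index=int(tone_idx[i])
        )
        for i in range(n_events)
    )
    return StimulusSequence(
        paradigm=Paradigm.MANY_STANDARDS,
        events=events,
        tones=tones,
        soa_s=soa_s,
        target_tone=target_tone,
        direction=Direction.NONE,
        seed=seed,
    )


def make_dev_alone(oddball: StimulusSequence) -> StimulusSequence:
    """Mute the standard train of an oddball, leaving deviants over silence.

    Deviant onsets are preserved; with a minimum of ``min_std_gap`` muted
    standards between deviants, consecutive audible tones are separated by a
    silent offset-to-onset gap of at least ``4*soa - duration`` (1.925 s at
    the defaults).
    """
    if oddball.paradigm not in (
        Paradigm.ODDBALL_ASCENDING,
        Paradigm.ODDBALL_DESCENDING,
    ):
        raise ValueError("DEV-alone is derived from an oddball sequence")
    events = []
    for e in oddball.events:
        if e.role is Role.DEV:
            events.append(
                StimulusEvent(
                    onset_s=e.onset_s,
                    role=Role.DEV_ALONE,
                    tone_index=e.tone_index,
                    duration_s=e.duration_s,
                    ramp_s=e.ramp_s,
                )
            )
        else:
            events.append(
                StimulusEvent(
                    onset_s=e.onset_s,
                    role=Role.MUTED,
                    tone_index=None,
                    duration_s=e.duration_s,
                    ramp_s=e.ramp_s,
                )
            )
    return StimulusSequence(
        paradigm=Paradigm.DEV_ALONE,
        events=tuple(events),
        tones=oddball.tones,
        soa_s=oddball.soa_s,
        target_tone=oddball.target_tone,
        direction=oddball.direction,
        seed=oddball.seed,
    )


@dataclass
class ValidationReport:
    """Per-invariant pass/fail record with offending event indices."""

    checks: dict = field(default_factory=dict)
    offenders: dict = field(default_factory=dict)

    def record(self, name: str, passed: bool, offending=()):
        self.checks[name] = bool(passed)
        if not passed:
            self.offenders[name] = list(offending)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())


def validate_sequence(
    seq: StimulusSequence,
    dev_prob: float = 0.10,
    min_std_gap: int = 3,
    n_initial_std: int = 10,
) -> ValidationReport:
    """Check a sequence against its paradigm's design invariants."""
    rep = ValidationReport()
    onsets = seq.onsets()
    grid = onsets / seq.soa_s
    off_grid = np.nonzero(np.abs(grid - np.round(grid)) > 1e-9)[0]
    rep.record("onsets_on_soa_grid", off_grid.size == 0, off_grid)
    not_increasing = np.nonzero(np.diff(onsets) <= 0)[0]
    rep.record("onsets_strictly_increasing", not_increasing.size == 0, not_increasing)

    idx = seq.tone_indices()
    is_std = seq.role_mask(Role.STD)

    if seq.paradigm in (Paradigm.ODDBALL_ASCENDING, Paradigm.ODDBALL_DESCENDING):
        dev_pos = seq.role_positions(Role.DEV)
        n_dev_expected = int(round(dev_prob * seq.n_events))
        rep.record("dev_count", dev_pos.size == n_dev_expected, dev_pos)
        head = np.nonzero(~is_std[:n_initial_std])[0]
        rep.record("first_events_are_std", head.size == 0, head)
        bad_gap = dev_pos[np.nonzero(np.diff(dev_pos) < min_std_gap + 1)[0] + 1]
        # also require min_std_gap STDs immediately before every DEV
        lead_bad = [
            p
            for p in dev_pos
            if p < min_std_gap or not np.all(is_std[p - min_std_gap : p])
        ]
        offending = sorted(set(bad_gap.tolist()) | set(lead_bad))
        rep.record("min_std_gap_before_dev", len(offending) == 0, offending)
        if seq.target_tone is not None and dev_pos.size:
            wrong = dev_pos[idx[dev_pos] != seq.target_tone]
            rep.record("dev_is_target_tone", wrong.size == 0, wrong)
    elif seq.paradigm in (Paradigm.CASCADE_ASCENDING, Paradigm.CASCADE_DESCENDING):
        n_tones = len(seq.tones)
        step = 1 if seq.paradigm is Paradigm.CASCADE_ASCENDING else -1
        expected = (idx[0] + step * np.arange(seq.n_events)) % n_tones
        wrong = np.nonzero(idx != expected)[0]
        rep.record("cyclic_ramp", wrong.size == 0, wrong)
        counts = np.bincount(idx, minlength=n_tones)
        rep.record("equal_tone_counts", np.all(counts == seq.n_events // n_tones))
    elif seq.paradigm is Paradigm.MANY_STANDARDS:
        n_tones = len(seq.tones)
        counts = np.bincount(idx, minlength=n_tones)
        rep.record("equal_tone_counts", np.all(counts == seq.n_events // n_tones))
        rep_pos = np.nonzero(np.diff(idx) == 0)[0] + 1
        rep.record("no_adjacent_repeats", rep_pos.size == 0, rep_pos)
    elif seq.paradigm is Paradigm.DEV_ALONE:
        muted = seq.role_positions(Role.MUTED)
        audible = seq.role_positions(Role.DEV_ALONE)
        rep.record("all_slots_classified", muted.size + audible.size == seq.n_events)
        bad_gap = audible[np.nonzero(np.diff(audible) < min_std_gap + 1)[0] + 1]
        rep.record("min_muted_gap", bad_gap.size == 0, bad_gap)
    return rep


def events_to_frame(seq: StimulusSequence, sequence_id: str = "seq0") -> pd.DataFrame:
    """One row per event, the on-disk CSV schema."""
    rows = []
    for i, e in enumerate(seq.events):
        freq = (
            "" if e.tone_index is None else seq.tones.frequencies_hz[e.tone_index]
        )
        rows.append(
            {
                "sequence_id": sequence_id,
                "paradigm": seq.paradigm.value,
                "event_index": i,
                "onset_s": e.onset_s,
                "duration_s": e.duration_s,
                "ramp_s": e.ramp_s,
                "tone_index": -1 if e.tone_index is None else e.tone_index,
                "frequency_hz": freq,
                "role": e.role.value,
                "target_flag": int(
                    seq.target_tone is not None and e.tone_index == seq.target_tone
                ),
            }
        )
    return pd.DataFrame(rows)


def sequence_metadata(seq: StimulusSequence) -> dict:
    return {
        "paradigm": seq.paradigm.value,
        "soa_s": seq.soa_s,
        "n_events": seq.n_events,
        "seed": seq.seed,
        "direction": seq.direction.value,
        "target_tone": seq.target_tone,
        "tones": {
            "frequencies_hz": list(seq.tones.frequencies_hz),
            "intensity_db": seq.tones.intensity_db,
            "octave_step": seq.tones.octave_step,
        },
    }
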