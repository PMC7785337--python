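"""Build and validate the six stimulus paradigms.

Generates a 10-tone set (0.5-octave steps), the ascending/descending
oddballs (40 deviants among 360 standards, >=3 standards before every
deviant), both cascades, the many-standards control, and the DEV-alone
sequence, validates every design invariant, and writes the event tables.

Findings at the defaults: every paradigm runs at exactly 2 tones/s, the
deviant and both controls present the tone of interest at probability 0.10,
and muting the standards leaves a minimum silent gap of 1.925 s between
audible tones.
"""

import json
from pathlib import Path

import numpy as np

from oddball_mismatch.sequence_design import (
    Direction,
    Role,
    events_to_frame,
    make_cascade,
    make_dev_alone,
    make_many_standards,
    make_oddball,
    make_tone_set,
    sequence_metadata,
    validate_sequence,
)

OUT = Path("results/01_sequences")
OUT.mkdir(parents=True, exist_ok=True)

tones = make_tone_set(1000.0, 0.5, 10, 60.0)
print(f"tone set: {tones.frequencies_hz[0]:.0f}-{tones.frequencies_hz[-1]:.0f} Hz "
      f"({np.log2(tones.frequencies_hz[-1] / tones.frequencies_hz[0]):.1f} octaves)")

sequences = {
    "oddball_ascending": make_oddball(tones, 5, Direction.ASCENDING, seed=1),
    "oddball_descending": make_oddball(tones, 5, Direction.DESCENDING, seed=2),
    "cascade_ascending": make_cascade(tones, Direction.ASCENDING),
    "cascade_descending": make_cascade(tones, Direction.DESCENDING),
    "many_standards": make_many_standards(tones, seed=3),
}
sequences["dev_alone"] = make_dev_alone(sequences["oddball_ascending"])

meta = {}
for name, seq in sequences.items():
    report = validate_sequence(seq)
    assert report.ok, (name, report.offenders)
    events_to_frame(seq, sequence_id=name).to_csv(OUT / f"{name}.csv", index=False)
    meta[name] = sequence_metadata(seq)
    print(f"{name:22s} {seq.n_events} events, all design checks pass")

odd = sequences["oddball_ascending"]
print(f"deviants: {odd.role_positions(Role.DEV).size} "
      f"(probability {odd.role_positions(Role.DEV).size / odd.n_events:.2f})")
da = sequences["dev_alone"]
gap = np.diff(da.onsets(Role.DEV_ALONE)).min() - 0.075
print(f"DEV-alone minimum silent gap: {gap:.3f} s")

(OUT / "metadata.json").write_text(json.dumps(meta, indent=2))
print(f"wrote event tables to {OUT}")
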