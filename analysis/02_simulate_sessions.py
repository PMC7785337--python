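"""Simulate synthetic multiunit sessions under both regional presets.

One session per preset: matched oddball/cascade/many-standards sequences
with inhomogeneous-Poisson spiking and colored-noise LFP. Reports the
response-latency contrast the presets encode — prefrontal-like responses
peak hundreds of milliseconds after the fast auditory-cortex-like ones —
and writes spike/LFP extracts for inspection.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from oddball_mismatch.spike_metrics import compute_sdf, extract_condition_trials
from oddball_mismatch.synthetic_session import SessionConfig, simulate_session

OUT = Path("results/02_sessions")
OUT.mkdir(parents=True, exist_ok=True)

for preset in ("mPFC", "AC"):
    session = simulate_session(SessionConfig(preset=preset, seed=42))
    eps = extract_condition_trials(session.spike_times, session.sequences, 5)
    sdf = compute_sdf(eps["DEV"], kernel_sd_s=0.02)
    peak_ms = 1000 * sdf.peak_latency_s(0.0, 0.7)
    n_spikes = sum(len(v) for v in session.spike_times.values())
    print(f"{preset:5s}: {n_spikes} spikes across "
          f"{len(session.sequences)} sequences; deviant SDF peak at {peak_ms:.0f} ms")

    rows = []
    for cond in ("DEV", "STD", "CTR"):
        for i, trial in enumerate(eps[cond].trials):
            rows.extend(
                {"condition": cond, "trial_index": i, "relative_time_s": t}
                for t in trial
            )
    pd.DataFrame(rows).to_csv(OUT / f"{preset}_epoch_spikes.csv", index=False)
    pd.DataFrame(
        {"time_s": sdf.time_s, "rate_hz": sdf.rate_hz, "sem_hz": sdf.sem_hz}
    ).to_csv(OUT / f"{preset}_dev_sdf.csv", index=False)

print(f"wrote epoch extracts to {OUT}")
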