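"""Spike-count analysis: inclusion testing, normalization, and the
iMM/iRS/iPE decomposition across a simulated multiunit sample.

Runs the full spike-side pipeline for the prefrontal preset (12 multiunits),
printing the per-condition median counts, the median indices, and the
prediction-error share of the mismatch response. Under the prefrontal
conditions the decomposition attributes nearly all of the mismatch response
to prediction error (iPE/iMM around 0.9) with near-zero repetition
suppression, and the time-resolved iPE turns significant only late.
"""

from pathlib import Path

import pandas as pd

from oddball_mismatch.pipeline import PipelineConfig, analyze_sessions, write_report

OUT = Path("results/03_spike_indices")

cfg = PipelineConfig(seed=7, preset="mPFC", n_units=12, out_dir=str(OUT))
res = analyze_sessions(cfg)
write_report(res, plots=False)

med = res["summary"].medians["median"]
print("median raw counts   DEV/STD/CTR: "
      f"{med['raw_DEV']:.3f} / {med['raw_STD']:.3f} / {med['raw_CTR']:.3f}")
print("median normalized   DEV/STD/CTR: "
      f"{med['norm_DEV']:.3f} / {med['norm_STD']:.3f} / {med['norm_CTR']:.3f}")
print(f"median indices      iMM={med['iMM']:.3f} iPE={med['iPE']:.3f} "
      f"iRS={med['iRS']:.3f}")
print(f"prediction-error share of the mismatch response: "
      f"{100 * med['iPE'] / med['iMM']:.0f}%")
print(f"omnibus p (Friedman over normalized counts): "
      f"{res['summary'].omnibus['omnibus_p']:.2e}")

w = res["windowed_ipe"]
onset = w.onset_s()
print(f"windowed iPE: {int(w.significant.sum())}/35 windows significant"
      + (f", first at {1000 * onset:.0f} ms" if onset is not None else ""))
print(f"all {cfg.n_units} multiunits passed the sound-driven inclusion test: "
      f"{bool(res['index_table']['included'].all())}")
print(f"artifacts in {OUT}")
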