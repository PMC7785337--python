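"""LFP filtering, epoching, and the prediction-error potential.

The raw trace is band-passed (2.2-50 Hz, second-order Butterworth, applied
forward-backward so latencies are preserved), cut into onset-aligned epochs
per condition, and averaged. The prediction-error potential (PE-LFP) is the
difference wave between the deviant and control condition means; its
significance is assessed pointwise with two-tailed paired t-tests at a
fixed number of evenly spaced test points, corrected across points
(Bonferroni by default, Benjamini-Hochberg optionally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal, stats

from .mismatch_indices import bh_fdr
from .sequence_design import Role, StimulusSequence
from .spike_metrics import extract_condition_trials  # noqa: F401 (parallel API)

__all__ = [
    "LFP_EPOCH_WINDOW",
    "LfpEpochSet",
    "PeLfpResult",
    "bandpass_lfp",
    "epoch_lfp",
    "extract_lfp_condition_epochs",
    "pe_lfp",
]

LFP_EPOCH_WINDOW = (-0.050, 0.650)


@dataclass
class LfpEpochSet:
    fs_hz: float
    time_s: np.ndarray  # onset-relative grid
    trials: np.ndarray  # (n_trials, n_samples)
    condition: str

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)


@dataclass
class PeLfpResult:
    time_s: np.ndarray
    mean_dev: np.ndarray
    mean_ctr: np.ndarray
    pe_lfp: np.ndarray
    test_times_s: np.ndarray
    p_pointwise: np.ndarray
    corrected_significant: np.ndarray
    intervals_s: list  # [(start, stop), ...] maximal significant runs
    onset_s: Optional[float]
    correction: str
    alpha: float


def bandpass_lfp(
    trace: np.ndarray,
    fs_hz: float,
    low_hz: float = 2.2,
    high_hz: float = 50.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; removes DC and slow drift."""
    if fs_hz <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper cutoff")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def epoch_lfp(
    trace: np.ndarray,
    fs_hz: float,
    onsets_s: np.ndarray,
    condition: str,
    window: Tuple[float, float] = LFP_EPOCH_WINDOW,
) -> LfpEpochSet:
    """Onset-aligned epochs; trials running past the trace are dropped."""
    trace = np.asarray(trace, dtype=float)
    i_lo = int(round(window[0] * fs_hz))
    i_hi = int(round(window[1] * fs_hz))
    n_samp = i_hi - i_lo + 1
    time_s = (np.arange(n_samp) + i_lo) / fs_hz
    rows = []
    n_dropped = 0
    for onset in np.asarray(onsets_s, dtype=float):
        c = int(round(onset * fs_hz))
        a, b = c + i_lo, c + i_hi + 1
        if a < 0 or b > trace.size:
            n_dropped += 1
            continue
        rows.append(trace[a:b])
    if not rows:
        raise ValueError("no epoch fits within the trace")
    ep = LfpEpochSet(
        fs_hz=fs_hz, time_s=time_s, trials=np.vstack(rows), condition=condition
    )
    ep.n_dropped = n_dropped
    return ep


def extract_lfp_condition_epochs(
    session_lfp: Dict[str, np.ndarray],
    sequences: Dict[str, StimulusSequence],
    target_tone: int,
    fs_hz: float,
    direction: str = "ascending",
    window: Tuple[float, float] = LFP_EPOCH_WINDOW,
    bandpass: bool = True,
) -> Dict[str, LfpEpochSet]:
    """DEV/STD/CTR LFP epoch sets matching the spike-trial selection
    (STD = last standard before each deviant; CTR = same-direction cascade)."""
    odd_key = f"oddball_{direction}"
    cas_key = f"cascade_{direction}"
    odd, cas = sequences[odd_key], sequences[cas_key]

    odd_trace = session_lfp[odd_key]
    cas_trace = session_lfp[cas_key]
    if bandpass:
        odd_trace = bandpass_lfp(odd_trace, fs_hz)
        cas_trace = bandpass_lfp(cas_trace, fs_hz)

    onsets = odd.onsets()
    dev_pos = odd.role_positions(Role.DEV)
    ctr_pos = np.nonzero(cas.tone_indices() == target_tone)[0]
    return {
        "DEV": epoch_lfp(odd_trace, fs_hz, onsets[dev_pos], "DEV", window),
        "STD": epoch_lfp(odd_trace, fs_hz, onsets[dev_pos - 1], "STD", window),
        "CTR": epoch_lfp(cas_trace, fs_hz, cas.onsets()[ctr_pos], "CTR", window),
    }


def _significant_runs(times: np.ndarray, mask: np.ndarray) -> list:
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = times[i]
        elif not flag and start is not None:
            runs.append((float(start), float(times[i - 1])))
            start = None
    if start is not None:
        runs.append((float(start), float(times[-1])))
    return runs


def pe_lfp(
    dev: LfpEpochSet,
    ctr: LfpEpochSet,
    n_test_points: int = 428,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> PeLfpResult:
    """Difference wave between deviant and control mean LFPs with pointwise
    significance.

    Paired two-tailed t-tests are run at ``n_test_points`` evenly spaced
    samples of the epoch grid; when trial counts differ across conditions
    (paired per trial order) an unpaired Welch test is used instead. The
    family of tests is corrected by Bonferroni (default) or
    Benjamini-Hochberg, and maximal runs of corrected-significant points
    give the significance intervals and onset.
    """
    if dev.time_s.size != ctr.time_s.size or not np.allclose(dev.time_s, ctr.time_s):
        raise ValueError("epoch grids must match")
    mean_dev = dev.mean()
    mean_ctr = ctr.mean()
    diff = mean_dev - mean_ctr

    idx = np.unique(
        np.round(np.linspace(0, dev.time_s.size - 1, n_test_points)).astype(int)
    )
    test_times = dev.time_s[idx]
    if dev.n_trials == ctr.n_trials:
        p = stats.ttest_rel(dev.trials[:, idx], ctr.trials[:, idx], axis=0).pvalue
    else:
        p = stats.ttest_ind(
            dev.trials[:, idx], ctr.trials[:, idx], axis=0, equal_var=False
        ).pvalue
    p = np.nan_to_num(np.asarray(p), nan=1.0)

    if correction == "bonferroni":
        sig = p < alpha / idx.size
    elif correction in ("bh_fdr", "fdr_bh"):
        sig, _ = bh_fdr(p, q=alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    intervals = _significant_runs(test_times, sig)
    onset = intervals[0][0] if intervals else None
    return PeLfpResult(
        time_s=dev.time_s,
        mean_dev=mean_dev,
        mean_ctr=mean_ctr,
        pe_lfp=diff,
        test_times_s=test_times,
        p_pointwise=p,
        corrected_significant=sig,
        intervals_s=intervals,
        onset_s=onset,
        correction=correction,
        alpha=alpha,
    )
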