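"""Per-condition trial extraction, PSTH/SDF estimation, windowed spike
counts, and the Monte Carlo response-significance test.

The comparison is always the matched triplet for one tone of interest:
DEV = the 40 deviant trials of the oddball, STD = the 40 standards
immediately preceding each deviant (same trial count), CTR = the 40
occurrences of the same tone in the same-direction cascade control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .sequence_design import Paradigm, Role, StimulusSequence

__all__ = [
    "EPOCH_WINDOW",
    "RESPONSE_WINDOW",
    "BASELINE_WINDOW_POST",
    "BASELINE_WINDOW_PRE",
    "SpikeEpochSet",
    "Psth",
    "Sdf",
    "MonteCarloResult",
    "extract_epochs",
    "extract_condition_trials",
    "count_spikes",
    "compute_psth",
    "compute_sdf",
    "estimate_baseline_rate",
    "monte_carlo_response_test",
]

EPOCH_WINDOW = (-0.100, 0.700)
RESPONSE_WINDOW = (0.100, 0.600)  # 500 ms span, delayed 100 ms from onset
BASELINE_WINDOW_POST = (0.0, 0.050)
BASELINE_WINDOW_PRE = (-0.100, 0.0)


@dataclass
class SpikeEpochSet:
    """Per-trial spike times relative to tone onset for one condition."""

    condition: str
    trials: list  # list of np.ndarray, onset-relative times (s)
    tone_index: Optional[int] = None
    sequence_id: Optional[str] = None
    trial_positions: Optional[np.ndarray] = None  # 1-based absolute positions

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class Psth:
    bin_edges: np.ndarray  # 1-ms grid over the epoch window
    counts: np.ndarray  # summed spikes per bin, across trials
    n_trials: int


@dataclass
class Sdf:
    """Trial-averaged Gaussian-smoothed firing rate (spikes/s)."""

    time_s: np.ndarray
    rate_hz: np.ndarray
    sem_hz: np.ndarray
    kernel_sd_s: float = 0.006

    def peak_latency_s(self, t_min: float = 0.0, t_max: float = 0.7) -> float:
        m = (self.time_s >= t_min) & (self.time_s <= t_max)
        return float(self.time_s[m][np.argmax(self.rate_hz[m])])


@dataclass
class MonteCarloResult:
    statistic: float
    g: int
    n_sim: int
    p_value: float
    significant: bool
    baseline_rate_hz: float


def extract_epochs(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    window: Tuple[float, float] = EPOCH_WINDOW,
) -> list:
    """Onset-relative spike times per trial, half-open window [lo, hi)."""
    spike_times = np.asarray(spike_times)
    lo, hi = window
    out = []
    for onset in np.asarray(onsets, dtype=float):
        i0, i1 = np.searchsorted(spike_times, (onset + lo, onset + hi))
        out.append(spike_times[i0:i1] - onset)
    return out


def extract_condition_trials(
    session_spikes: Dict[str, np.ndarray],
    sequences: Dict[str, StimulusSequence],
    target_tone: int,
    direction: str = "ascending",
    window: Tuple[float, float] = EPOCH_WINDOW,
) -> Dict[str, SpikeEpochSet]:
    """Build the matched DEV/STD/CTR epoch sets for one tone of interest.

    Only the same-direction oddball and cascade are compared. The STD set
    takes the last standard before each deviant so all three conditions
    carry the same number of trials. DEV-alone trials are added when the
    session includes that sequence.
    """
    odd_key = f"oddball_{direction}"
    cas_key = f"cascade_{direction}"
    if odd_key not in sequences:
        raise KeyError(f"missing oddball sequence {odd_key!r}")
    if cas_key not in sequences:
        raise KeyError(f"missing matched-direction cascade {cas_key!r}")

    odd = sequences[odd_key]
    cas = sequences[cas_key]
    onsets = odd.onsets()
    dev_pos = odd.role_positions(Role.DEV)
    std_pos = dev_pos - 1  # the last standard before each deviant
    cas_idx = cas.tone_indices()
    ctr_pos = np.nonzero(cas_idx == target_tone)[0]
    cas_onsets = cas.onsets()

    out = {
        "DEV": SpikeEpochSet(
            "DEV",
            extract_epochs(session_spikes[odd_key], onsets[dev_pos], window),
            tone_index=target_tone,
            sequence_id=odd_key,
            trial_positions=dev_pos + 1,
        ),
        "STD": SpikeEpochSet(
            "STD",
            extract_epochs(session_spikes[odd_key], onsets[std_pos], window),
            tone_index=target_tone,
            sequence_id=odd_key,
            trial_positions=std_pos + 1,
        ),
        "CTR": SpikeEpochSet(
            "CTR",
            extract_epochs(session_spikes[cas_key], cas_onsets[ctr_pos], window),
            tone_index=target_tone,
            sequence_id=cas_key,
            trial_positions=ctr_pos + 1,
        ),
    }
    if "dev_alone" in sequences and "dev_alone" in session_spikes:
        da = sequences["dev_alone"]
        da_pos = da.role_positions(Role.DEV_ALONE)
        out["DEV_ALONE"] = SpikeEpochSet(
            "DEV_ALONE",
            extract_epochs(session_spikes["dev_alone"], da.onsets()[da_pos], window),
            tone_index=target_tone,
            sequence_id="dev_alone",
            trial_positions=da_pos + 1,
        )
    return out


def count_spikes(
    epochs: SpikeEpochSet, window: Tuple[float, float] = RESPONSE_WINDOW
) -> float:
    """Mean per-trial spike count in the half-open window [start, end)."""
    if epochs.n_trials == 0:
        raise ValueError("empty trial set: spike count undefined")
    lo, hi = window
    counts = [np.count_nonzero((t >= lo) & (t < hi)) for t in epochs.trials]
    return float(np.mean(counts))


def per_trial_counts(
    epochs: SpikeEpochSet, window: Tuple[float, float] = RESPONSE_WINDOW
) -> np.ndarray:
    lo, hi = window
    return np.array(
        [np.count_nonzero((t >= lo) & (t < hi)) for t in epochs.trials], dtype=float
    )


def compute_psth(
    epochs: SpikeEpochSet,
    window: Tuple[float, float] = EPOCH_WINDOW,
    bin_s: float = 0.001,
) -> Psth:
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    all_spikes = (
        np.concatenate(epochs.trials) if epochs.trials else np.empty(0)
    )
    counts, _ = np.histogram(all_spikes, bins=edges)
    return Psth(bin_edges=edges, counts=counts, n_trials=epochs.n_trials)


def compute_sdf(
    epochs: SpikeEpochSet,
    window: Tuple[float, float] = EPOCH_WINDOW,
    step_s: float = 0.001,
    kernel_sd_s: float = 0.006,
) -> Sdf:
    """Gaussian-kernel spike-density function on a 1-ms grid.

    Each spike contributes a unit-area Gaussian (sigma = 6 ms), so per-trial
    traces are instantaneous rates in spikes/s; the SDF is their mean and
    the SEM is taken across trials at each time point.
    """
    if epochs.n_trials == 0:
        raise ValueError("need at least one trial")
    t = np.arange(window[0], window[1] + step_s / 2, step_s)
    norm = 1.0 / (np.sqrt(2 * np.pi) * kernel_sd_s)
    per_trial = np.zeros((epochs.n_trials, t.size))
    for i, spikes in enumerate(epochs.trials):
        if spikes.size:
            d = (t[None, :] - np.asarray(spikes)[:, None]) / kernel_sd_s
            per_trial[i] = norm * np.exp(-0.5 * d**2).sum(axis=0)
    rate = per_trial.mean(axis=0)
    sem = (
        per_trial.std(axis=0, ddof=1) / np.sqrt(epochs.n_trials)
        if epochs.n_trials > 1
        else np.zeros_like(rate)
    )
    return Sdf(time_s=t, rate_hz=rate, sem_hz=sem, kernel_sd_s=kernel_sd_s)


def estimate_baseline_rate(
    epochs: SpikeEpochSet, mode: str = "post"
) -> float:
    """Baseline spontaneous rate (Hz) from the epochs themselves.

    ``post`` uses the 0-50 ms window after tone onset (the default: the
    late-response geometry of the prefrontal data leaves it response-free);
    ``pre`` uses the 100 ms before onset.
    """
    win = BASELINE_WINDOW_POST if mode == "post" else BASELINE_WINDOW_PRE
    mean_count = count_spikes(epochs, win)
    return mean_count / (win[1] - win[0])


def monte_carlo_response_test(
    epochs: SpikeEpochSet,
    baseline_rate_hz: Optional[float] = None,
    window: Tuple[float, float] = RESPONSE_WINDOW,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    baseline_mode: str = "post",
) -> MonteCarloResult:
    """Monte Carlo test of a sound-driven response against a Poisson null.

    The statistic is the mean baseline-corrected spike count in the response
    window. The null simulates ``n_sim`` trial sets of homogeneous Poisson
    spiking at the baseline rate and reduces each the same way; because a
    sum of independent Poisson counts is Poisson, each null trial set is
    drawn as a single Poisson total. The p-value is ``(g + 1) / (n_sim + 1)``
    with ``g`` the number of null statistics >= the observed one.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive length")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if baseline_rate_hz is None:
        baseline_rate_hz = estimate_baseline_rate(epochs, baseline_mode)
    if baseline_rate_hz < 0:
        raise ValueError("baseline rate must be non-negative")

    span = hi - lo
    expected = baseline_rate_hz * span
    observed = count_spikes(epochs, window) - expected

    rng = np.random.default_rng(seed)
    n_trials = epochs.n_trials
    null_totals = rng.poisson(n_trials * expected, size=n_sim)
    null_stats = null_totals / n_trials - expected
    g = int(np.count_nonzero(null_stats >= observed))
    p = (g + 1) / (n_sim + 1)
    return MonteCarloResult(
        statistic=float(observed),
        g=g,
        n_sim=n_sim,
        p_value=float(p),
        significant=bool(p < alpha),
        baseline_rate_hz=float(baseline_rate_hz),
    )
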