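"""Synthetic multiunit sessions with known ground truth.

Emulates the statistical structure the downstream analyses assume:
inhomogeneous-Poisson multiunit spiking with condition-dependent evoked
profiles (deviant responses much larger than control, control at or above
standard), power-law trial-wise suppression of the standard (and, more
mildly, the control), and condition-scaled biphasic evoked deflections in
1/f background noise for the LFP.

Two presets bracket the regional contrast the pipeline is built to expose:

* ``mPFC`` — slow, late multiunit responses (onset ~150 ms, peak ~400 ms
  post-onset), near-equal standard and control responses, so the mismatch
  response is almost pure prediction error.
* ``AC`` — fast auditory-cortex-like responses (onset <20 ms, peak <75 ms)
  with a substantial repetition-suppression component (control well above
  standard).

Preset effect sizes are chosen so that the expected window counts reproduce
the published median response ratios per condition (see docs/methods.md for
the derivation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .sequence_design import (
    Direction,
    Paradigm,
    Role,
    StimulusSequence,
    ToneSet,
    make_cascade,
    make_dev_alone,
    make_many_standards,
    make_oddball,
    make_tone_set,
)

__all__ = [
    "ResponseProfile",
    "AdaptationLaw",
    "ConditionGainModel",
    "LfpModel",
    "SessionConfig",
    "SyntheticSession",
    "PRESETS",
    "evoked_kernel",
    "simulate_spike_trains",
    "simulate_lfp",
    "simulate_session",
]


@dataclass(frozen=True)
class ResponseProfile:
    """Shape of the evoked firing-rate kernel for one multiunit.

    The kernel rises alpha-like from ``onset_s`` to a unit peak at
    ``onset_s + peak_s`` and then decays exponentially with time constant
    ``decay_s``; ``peak_rate_hz`` scales it to spikes/s on top of the
    homogeneous ``baseline_rate_hz``.
    """

    onset_s: float
    peak_s: float
    decay_s: float
    peak_rate_hz: float
    baseline_rate_hz: float

    def __post_init__(self):
        for name in ("onset_s", "peak_s", "decay_s", "peak_rate_hz", "baseline_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AdaptationLaw:
    """Power-law trial gain ``(a * t**b + c)`` over 1-based trial position."""

    a: float = 0.7
    b: float = -1.4
    c: float = 0.3

    def __post_init__(self):
        if self.b > 0:
            raise ValueError("b must be <= 0 for suppression")
        if not 0 <= self.c <= 1:
            raise ValueError("c must lie in [0, 1]")

    def factor(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * t**self.b + self.c


@dataclass(frozen=True)
class ConditionGainModel:
    """Multiplicative evoked-rate gain per condition, with optional
    trial-position adaptation of the standard and control trains."""

    gain_dev: float = 1.0
    gain_ctr: float = 0.4
    gain_std: float = 0.6
    std_adaptation: Optional[AdaptationLaw] = AdaptationLaw()
    ctr_adaptation: Optional[AdaptationLaw] = None

    def gain_for(self, role: Role, trial_position: int) -> float:
        """Gain for one event; ``trial_position`` is 1-based within the
        sequence (absolute position, matching the trial-course analysis)."""
        if role in (Role.DEV, Role.DEV_ALONE):
            return self.gain_dev
        if role is Role.STD:
            g = self.gain_std
            if self.std_adaptation is not None:
                g *= float(self.std_adaptation.factor(trial_position))
            return g
        if role in (Role.CASCADE, Role.MANY_STD):
            g = self.gain_ctr
            if self.ctr_adaptation is not None:
                g *= float(self.ctr_adaptation.factor(trial_position))
            return g
        return 0.0  # MUTED


@dataclass(frozen=True)
class LfpModel:
    """Evoked LFP deflection model: a one-cycle biphasic wave per tone
    (latency ``lat_s``, full width ``width_s``) scaled per condition, on a
    Gaussian 1/f^noise_exponent background."""

    fs_hz: float = 1000.0
    lat_s: float = 0.14
    width_s: float = 0.40
    noise_exponent: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.fs_hz < 200:
            raise ValueError("fs_hz must be at least 200")

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Unit-amplitude biphasic deflection (negative then positive lobe)."""
        tau = t - self.lat_s
        out = np.zeros_like(t)
        inside = (tau >= 0) & (tau < self.width_s)
        out[inside] = -np.sin(2 * np.pi * tau[inside] / self.width_s)
        return out


@dataclass(frozen=True)
class SessionConfig:
    preset: str = "mPFC"
    base_hz: float = 1000.0
    n_tones: int = 10
    octave_step: float = 0.5
    target_tone: int = 5
    n_events: int = 400
    soa_s: float = 0.5
    dev_prob: float = 0.10
    include_dev_alone: bool = False
    seed: int = 0


@dataclass
class SyntheticSession:
    """One simulated multiunit recording: matched sequences, one spike
    train per sequence, one LFP trace per sequence, and the ground truth."""

    config: SessionConfig
    sequences: Dict[str, StimulusSequence]
    spike_times: Dict[str, np.ndarray]
    lfp: Dict[str, np.ndarray]
    profile: ResponseProfile
    gains: ConditionGainModel
    lfp_model: LfpModel
    lfp_amplitudes: Dict[Role, float]
    seed: int = 0


def _preset_mpfc():
    profile = ResponseProfile(
        onset_s=0.150, peak_s=0.250, decay_s=0.200, peak_rate_hz=30.0,
        baseline_rate_hz=4.0,
    )
    gains = ConditionGainModel(
        gain_dev=1.0,
        gain_ctr=0.40,
        gain_std=0.60,
        std_adaptation=AdaptationLaw(0.7, -1.4, 0.3),
        ctr_adaptation=AdaptationLaw(0.35, -0.7, 0.65),
    )
    lfp_model = LfpModel(lat_s=0.14, width_s=0.40)
    # STD amplitude equals CTR so the tone preceding a deviant evokes the
    # same deflection as the tone preceding a control trial; the difference
    # wave then reflects only the deviant's own deflection.
    amplitudes = {
        Role.DEV: 2.0,
        Role.DEV_ALONE: 2.0,
        Role.CASCADE: 1.0,
        Role.MANY_STD: 1.0,
        Role.STD: 1.0,
        Role.MUTED: 0.0,
    }
    windows = {"count_window": (0.100, 0.600), "baseline_window": (0.0, 0.050)}
    return profile, gains, lfp_model, amplitudes, windows


def _preset_ac():
    profile = ResponseProfile(
        onset_s=0.005, peak_s=0.030, decay_s=0.025, peak_rate_hz=80.0,
        baseline_rate_hz=5.0,
    )
    gains = ConditionGainModel(
        gain_dev=1.0,
        gain_ctr=0.68,
        gain_std=0.20,
        std_adaptation=AdaptationLaw(0.7, -1.0, 0.2),
        ctr_adaptation=AdaptationLaw(0.15, -0.7, 0.85),
    )
    lfp_model = LfpModel(lat_s=0.03, width_s=0.12)
    amplitudes = {
        Role.DEV: 1.5,
        Role.DEV_ALONE: 1.5,
        Role.CASCADE: 1.0,
        Role.MANY_STD: 1.0,
        Role.STD: 1.0,
        Role.MUTED: 0.0,
    }
    windows = {"count_window": (0.0, 0.200), "baseline_window": (-0.100, 0.0)}
    return profile, gains, lfp_model, amplitudes, windows


PRESETS = {"mPFC": _preset_mpfc, "AC": _preset_ac}


def evoked_kernel(t: np.ndarray, profile: ResponseProfile) -> np.ndarray:
    """Unit-peak evoked-rate kernel: alpha-like rise, exponential decay.

    ``t`` is time from stimulus onset (s). Zero before ``onset_s``; rises as
    ``(tau/peak_s) * exp(1 - tau/peak_s)`` to 1 at ``tau = peak_s``; decays
    as ``exp(-(tau - peak_s)/decay_s)`` afterwards.
    """
    tau = np.asarray(t, dtype=float) - profile.onset_s
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau <= profile.peak_s)
    if profile.peak_s > 0:
        u = tau[rising] / profile.peak_s
        out[rising] = u * np.exp(1.0 - u)
    else:
        rising = np.zeros_like(tau, dtype=bool)
    falling = tau > profile.peak_s
    if profile.decay_s > 0:
        out[falling] = np.exp(-(tau[falling] - profile.peak_s) / profile.decay_s)
    return out


# support of the evoked kernel used for sampling: rise + 8 decay constants
def _kernel_support(profile: ResponseProfile) -> float:
    return profile.onset_s + profile.peak_s + 8.0 * profile.decay_s


def simulate_spike_trains(
    seq: StimulusSequence,
    profile: ResponseProfile,
    gains: ConditionGainModel,
    seed: int = 0,
    pad_s: float = 1.0,
) -> np.ndarray:
    """Sample one multiunit spike train for a sequence.

    The rate is ``baseline + sum_events gain(role, trial) * peak_rate *
    kernel(t - onset)``. By Poisson superposition the baseline and each
    event's evoked component are sampled independently: the evoked count is
    Poisson with mean ``gain * peak_rate * integral(kernel)`` and spike times
    are drawn from the normalized kernel by inverse-CDF on a 1-ms grid.
    """
    rng = np.random.default_rng(seed)
    t_end = seq.duration_s + pad_s

    n_base = rng.poisson(profile.baseline_rate_hz * t_end)
    spikes = [rng.uniform(0.0, t_end, size=n_base)]

    support = _kernel_support(profile)
    grid = np.arange(0.0, support + 1e-3, 1e-3)
    kern = evoked_kernel(grid, profile)
    area = np.trapezoid(kern, grid)
    if area > 0 and profile.peak_rate_hz > 0:
        cdf = np.concatenate([[0.0], np.cumsum((kern[1:] + kern[:-1]) / 2) * 1e-3])
        cdf /= cdf[-1]
        for pos, e in enumerate(seq.events, start=1):
            g = gains.gain_for(e.role, pos)
            if g <= 0:
                continue
            mean_count = g * profile.peak_rate_hz * area
            n_ev = rng.poisson(mean_count)
            if n_ev:
                u = rng.uniform(0, 1, size=n_ev)
                rel = np.interp(u, cdf, grid)
                spikes.append(e.onset_s + rel)
    out = np.sort(np.concatenate(spikes))
    return out[(out >= 0) & (out <= t_end)]


def _powerlaw_noise(n: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent (FFT shaping)."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    colored = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
    s = colored.std()
    return colored * (sd / s) if s > 0 else colored


def simulate_lfp(
    seq: StimulusSequence,
    model: LfpModel,
    condition_amplitudes: Dict[Role, float],
    seed: int = 0,
    pad_s: float = 1.0,
) -> np.ndarray:
    """Continuous LFP trace: colored noise plus per-event biphasic deflections."""
    rng = np.random.default_rng(seed)
    n = int(round((seq.duration_s + pad_s) * model.fs_hz))
    trace = _powerlaw_noise(n, model.noise_exponent, model.noise_sd, rng)

    k_len = int(round((model.lat_s + model.width_s) * model.fs_hz)) + 1
    k_t = np.arange(k_len) / model.fs_hz
    kern = model.kernel(k_t)
    for e in seq.events:
        amp = condition_amplitudes.get(e.role, 0.0)
        if amp == 0.0:
            continue
        i0 = int(round(e.onset_s * model.fs_hz))
        i1 = min(i0 + k_len, n)
        trace[i0:i1] += amp * kern[: i1 - i0]
    return trace


def simulate_session(config: SessionConfig) -> SyntheticSession:
    """Simulate the full per-multiunit protocol for one tone set.

    Generates matched oddball (both directions), cascade (both directions),
    many-standards, and optionally DEV-alone sequences, with one spike train
    and one LFP trace per sequence, all derived from ``config.seed``.
    """
    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}; use one of {sorted(PRESETS)}")
    profile, gains, lfp_model, amplitudes, _ = PRESETS[config.preset]()
    tones = make_tone_set(
        config.base_hz, config.octave_step, config.n_tones
    )
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=32)

    sequences: Dict[str, StimulusSequence] = {
        "oddball_ascending": make_oddball(
            tones, config.target_tone, Direction.ASCENDING, config.n_events,
            config.dev_prob, config.soa_s, seed=int(seeds[0]),
        ),
        "oddball_descending": make_oddball(
            tones, config.target_tone, Direction.DESCENDING, config.n_events,
            config.dev_prob, config.soa_s, seed=int(seeds[1]),
        ),
        "cascade_ascending": make_cascade(
            tones, Direction.ASCENDING, config.n_events, config.soa_s,
            target_tone=config.target_tone,
        ),
        "cascade_descending": make_cascade(
            tones, Direction.DESCENDING, config.n_events, config.soa_s,
            target_tone=config.target_tone,
        ),
        "many_standards": make_many_standards(
            tones, config.n_events, config.soa_s, seed=int(seeds[2]),
            target_tone=config.target_tone,
        ),
    }
    if config.include_dev_alone:
        sequences["dev_alone"] = make_dev_alone(sequences["oddball_ascending"])

    spike_times = {}
    lfp = {}
    for i, (name, seq) in enumerate(sequences.items()):
        spike_times[name] = simulate_spike_trains(
            seq, profile, gains, seed=int(seeds[3 + 2 * i])
        )
        lfp[name] = simulate_lfp(
            seq, lfp_model, amplitudes, seed=int(seeds[4 + 2 * i])
        )

    return SyntheticSession(
        config=config,
        sequences=sequences,
        spike_times=spike_times,
        lfp=lfp,
        profile=profile,
        gains=gains,
        lfp_model=lfp_model,
        lfp_amplitudes=amplitudes,
        seed=config.seed,
    )


def preset_windows(preset: str) -> dict:
    """Analysis windows appropriate to a preset's response latencies."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    return PRESETS[preset]()[4]
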