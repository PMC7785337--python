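"""Trial-course construction, block-wise STD-vs-CTR comparison, model
fitting over six families, and decay summaries.

The trial course orders per-trial normalized spike counts at their absolute
position within the 400-tone sequence (all standards, not just pre-deviant
ones) and averages across multiunits. Six model families are fitted by
nonlinear least squares and compared by adjusted R²; for the data this
pipeline targets, the three-parameter power law ``y(t) = a*t**b + c`` wins,
and its exponent alone fixes how many repetitions halve the initial
response, since the decayable remaining fraction at trial t is ``t**b``
regardless of a and c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TrialCourse",
    "ModelFit",
    "DecaySummary",
    "MODEL_FAMILIES",
    "trial_course",
    "block_compare_std_ctr",
    "fit_models",
    "select_best",
    "decay_summary",
]


@dataclass
class TrialCourse:
    condition: str
    trial_positions: np.ndarray  # 1-based absolute positions
    mean_norm_counts: np.ndarray

    def __post_init__(self):
        self.trial_positions = np.asarray(self.trial_positions, dtype=int)
        self.mean_norm_counts = np.asarray(self.mean_norm_counts, dtype=float)
        if self.trial_positions.shape != self.mean_norm_counts.shape:
            raise ValueError("positions and values must align")


@dataclass
class ModelFit:
    family: str
    params: Dict[str, float]
    ci95: Dict[str, Tuple[float, float]]
    adj_r2: float
    n_params: int
    converged: bool = True
    sse: float = np.inf


@dataclass
class DecaySummary:
    half_decay_trial: int
    steady_state_trial: int
    steady_level: float
    repetitions_to_half: int


# family name -> callable(t, *params), param names, start points for multi-start
def _starts_power3(t, y):
    a0 = y[0] - y[-1]
    c0 = y[-1]
    return [[a0 if a0 != 0 else 1.0, b0, c0] for b0 in (-0.5, -1.0, -2.0)]


MODEL_FAMILIES: Dict[str, dict] = {
    "linear": {
        "f": lambda t, a, c: a * t + c,
        "names": ["a", "c"],
        "starts": lambda t, y: [list(np.polyfit(t, y, 1))],
    },
    "exponential": {
        "f": lambda t, a, b, c: a * np.exp(b * t) + c,
        "names": ["a", "b", "c"],
        "starts": lambda t, y: [
            [y[0] - y[-1], b0, y[-1]] for b0 in (-0.1, -0.5, -1.0)
        ],
    },
    "double_exponential": {
        "f": lambda t, a, b, c, d: a * np.exp(b * t) + c * np.exp(d * t),
        "names": ["a", "b", "c", "d"],
        "starts": lambda t, y: [
            [y[0] - y[-1], -1.0, y[-1], -0.001],
            [y[0] - y[-1], -0.3, y[-1], -0.01],
        ],
    },
    "inverse_polynomial": {
        "f": lambda t, a, c: a / t + c,
        "names": ["a", "c"],
        "starts": lambda t, y: [[y[0] - y[-1], y[-1]]],
    },
    "power2": {
        "f": lambda t, a, b: a * np.power(t, b),
        "names": ["a", "b"],
        "starts": lambda t, y: [[max(y[0], 1e-6), b0] for b0 in (-0.5, -1.0, -2.0)],
    },
    "power3": {
        "f": lambda t, a, b, c: a * np.power(t, b) + c,
        "names": ["a", "b", "c"],
        "starts": _starts_power3,
    },
}


def trial_course(
    per_unit_values: Sequence[np.ndarray],
    trial_positions: np.ndarray,
    condition: str,
) -> TrialCourse:
    """Average per-trial normalized counts across multiunits per position.

    ``per_unit_values`` holds, for each multiunit, the normalized spike
    count at every trial position where the condition occurred; positions
    must be shared across units (the design fixes them for the cascade, and
    the standard course uses every standard slot).
    """
    mat = np.vstack([np.asarray(v, dtype=float) for v in per_unit_values])
    positions = np.asarray(trial_positions, dtype=int)
    if mat.shape[1] != positions.size:
        raise ValueError("value columns must match trial positions")
    return TrialCourse(condition, positions, mat.mean(axis=0))


def block_compare_std_ctr(
    std_course: TrialCourse,
    ctr_course: TrialCourse,
    block_size: int = 10,
    n_events: int = 400,
):
    """Paired block-wise comparison of standard and control trial courses.

    Positions 1..n_events are partitioned into consecutive blocks of
    ``block_size`` (40 blocks at the defaults); each condition's values are
    averaged within each block, and the paired block differences (STD - CTR)
    are tested against zero with a two-sided Wilcoxon signed-rank test.
    Blocks lacking trials of either condition are dropped pairwise.
    """
    n_blocks = n_events // block_size
    edges = np.arange(n_blocks + 1) * block_size  # blocks (e, e+block_size]

    def block_means(course: TrialCourse) -> np.ndarray:
        means = np.full(n_blocks, np.nan)
        blk = (course.trial_positions - 1) // block_size
        for b in range(n_blocks):
            sel = blk == b
            if np.any(sel):
                means[b] = course.mean_norm_counts[sel].mean()
        return means

    std_m = block_means(std_course)
    ctr_m = block_means(ctr_course)
    valid = ~(np.isnan(std_m) | np.isnan(ctr_m))
    diffs = std_m[valid] - ctr_m[valid]
    n_dropped = int(n_blocks - valid.sum())
    if np.allclose(diffs, 0):
        p = 1.0
        statistic = 0.0
    else:
        res = stats.wilcoxon(diffs, alternative="two-sided")
        p, statistic = float(res.pvalue), float(res.statistic)
    return {
        "n_blocks": int(valid.sum()),
        "n_dropped": n_dropped,
        "diffs": diffs,
        "statistic": statistic,
        "p_value": p,
    }


def _adjusted_r2(y: np.ndarray, resid: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1 - ss_res / ss_tot
    if n - n_params - 1 <= 0:
        return -np.inf
    return 1 - (1 - r2) * (n - 1) / (n - n_params - 1)


def fit_models(
    course: TrialCourse, families: Optional[Sequence[str]] = None
) -> List[ModelFit]:
    """Nonlinear least-squares fits of the trial course, one per family.

    Each family is fitted from several starting points (multi-start guards
    against local minima in the curved families) and the lowest-SSE solution
    kept; 95% coefficient intervals come from the local covariance with
    t-quantiles. Families that fail to converge are returned flagged rather
    than raised.
    """
    t = course.trial_positions.astype(float)
    y = course.mean_norm_counts
    if t.size < 8:
        raise ValueError("need at least 8 points to fit trial-course models")
    fits: List[ModelFit] = []
    for name in families or MODEL_FAMILIES:
        spec = MODEL_FAMILIES[name]
        f, names = spec["f"], spec["names"]
        best = None
        for p0 in spec["starts"](t, y):
            try:
                with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
                    # near-degenerate starts (e.g. a collapsing second
                    # exponential) produce singular covariances; the start
                    # is still usable if its SSE wins
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, pcov = optimize.curve_fit(f, t, y, p0=p0, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = y - f(t, *popt)
            sse = float(np.sum(resid**2))
            if best is None or sse < best[2]:
                best = (popt, pcov, sse, resid)
        if best is None:
            fits.append(
                ModelFit(name, {}, {}, -np.inf, len(names), converged=False)
            )
            continue
        popt, pcov, sse, resid = best
        dof = max(t.size - len(names), 1)
        tq = stats.t.ppf(0.975, dof)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        ci = {
            nm: (float(p - tq * s), float(p + tq * s))
            for nm, p, s in zip(names, popt, se)
        }
        fits.append(
            ModelFit(
                family=name,
                params={nm: float(p) for nm, p in zip(names, popt)},
                ci95=ci,
                adj_r2=_adjusted_r2(y, resid, len(names)),
                n_params=len(names),
                sse=sse,
            )
        )
    return fits


def select_best(fits: Sequence[ModelFit]) -> ModelFit:
    """Highest adjusted R²; ties go to the family with fewer parameters."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no model family converged")
    return max(converged, key=lambda f: (f.adj_r2, -f.n_params))


def decay_summary(fit: ModelFit, steady_fraction: float = 0.25) -> DecaySummary:
    """Repetition counts to half decay and steady state from a power-law fit.

    The decayable remaining fraction at 1-based trial t is ``t**b`` (the
    fitted a and c cancel against the trial-1 value), so the half-decay
    trial is the smallest t with ``t**b <= 0.5`` and the steady-state trial
    the smallest t with ``t**b <= steady_fraction``.
    """
    if fit.family != "power3":
        raise ValueError("decay summary is defined for the power3 family")
    b = fit.params["b"]
    if b >= 0:
        raise ValueError("fit does not decay (b >= 0)")

    def first_trial_below(frac: float) -> int:
        # t**b <= frac  <=>  t >= frac**(1/b); scan from the bound down-safe
        t = max(1, int(np.floor(frac ** (1.0 / b))))
        while t**b > frac:
            t += 1
        while t > 1 and (t - 1) ** b <= frac:
            t -= 1
        return t

    half = first_trial_below(0.5)
    steady = first_trial_below(steady_fraction)
    return DecaySummary(
        half_decay_trial=half,
        steady_state_trial=steady,
        steady_level=fit.params.get("c", 0.0),
        repetitions_to_half=half - 1,
    )
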