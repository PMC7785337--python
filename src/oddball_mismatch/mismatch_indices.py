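"""Euclidean-norm normalization and the mismatch index decomposition.

For one tone of interest the DEV/STD/CTR mean spike counts form a 3-vector.
Dividing by its Euclidean norm puts every multiunit on the unit sphere
(coordinates in [0, 1]) without changing the proportions among conditions.
Differences of the normalized coordinates decompose the total mismatch
response into its repetition-suppression and prediction-error parts:

    iMM = DEV_n - STD_n    (total neuronal mismatch)
    iRS = CTR_n - STD_n    (repetition suppression / adaptation share)
    iPE = DEV_n - CTR_n    (genuine deviance detection / prediction error)

so iMM = iRS + iPE by construction and every index lies in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spike_metrics import RESPONSE_WINDOW, SpikeEpochSet, per_trial_counts

__all__ = [
    "NormalizedTriplet",
    "IndexSet",
    "WindowedIpe",
    "normalize_triplet",
    "compute_indices",
    "indices_from_counts",
    "windowed_ipe",
    "bh_fdr",
    "ipe_window_grid",
]


@dataclass(frozen=True)
class NormalizedTriplet:
    dev_n: float
    std_n: float
    ctr_n: float
    norm: float


@dataclass(frozen=True)
class IndexSet:
    iMM: float
    iRS: float
    iPE: float


@dataclass
class WindowedIpe:
    """Time-resolved prediction-error index with per-window significance."""

    window_centers_s: np.ndarray
    width_s: float
    ipe: np.ndarray  # mean across tones per window
    sem: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray

    def onset_s(self):
        """Center of the first significant window, or None."""
        idx = np.nonzero(self.significant)[0]
        return float(self.window_centers_s[idx[0]]) if idx.size else None


def normalize_triplet(dev: float, std: float, ctr: float) -> NormalizedTriplet:
    """Project a raw (DEV, STD, CTR) count vector onto the unit sphere."""
    n = float(np.sqrt(dev**2 + std**2 + ctr**2))
    if n == 0:
        raise ValueError("all-zero triplet has no direction to normalize")
    return NormalizedTriplet(dev / n, std / n, ctr / n, n)


def compute_indices(t: NormalizedTriplet) -> IndexSet:
    return IndexSet(
        iMM=t.dev_n - t.std_n,
        iRS=t.ctr_n - t.std_n,
        iPE=t.dev_n - t.ctr_n,
    )


def indices_from_counts(dev: float, std: float, ctr: float) -> Tuple[NormalizedTriplet, IndexSet]:
    t = normalize_triplet(dev, std, ctr)
    return t, compute_indices(t)


def bh_fdr(p_values: Sequence[float], q: float = 0.1):
    """Benjamini–Hochberg step-up over a family of p-values.

    Returns (reject, p_adjusted). Thin wrapper over statsmodels'
    ``multipletests(method="fdr_bh")``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def ipe_window_grid(
    t_start: float = -0.050, t_stop: float = 0.650, width_s: float = 0.020
) -> np.ndarray:
    """Centers of the contiguous analysis windows (35 of 20 ms by default)."""
    n = int(round((t_stop - t_start) / width_s))
    return t_start + width_s * (np.arange(n) + 0.5)


def windowed_ipe(
    per_tone_epochs: List[Dict[str, SpikeEpochSet]],
    t_start: float = -0.050,
    t_stop: float = 0.650,
    width_s: float = 0.020,
    alpha: float = 0.05,
    norm_window: Tuple[float, float] = RESPONSE_WINDOW,
    zero_method: str = "wilcox",
) -> WindowedIpe:
    """Average prediction-error index in short contiguous time windows.

    For each tone of interest, DEV and CTR spike counts are computed per
    window and normalized by that tone's whole-response-window Euclidean
    norm (one norm per tone, keeping windows comparable); the per-window
    iPE values are averaged across tones and each window's distribution is
    tested against zero with a two-sided Wilcoxon signed-rank test,
    corrected across windows by Benjamini–Hochberg at ``alpha``.
    """
    if len(per_tone_epochs) < 2:
        raise ValueError("need at least 2 tones for a signed-rank test")
    centers = ipe_window_grid(t_start, t_stop, width_s)
    n_win = centers.size

    edges = np.concatenate([centers - width_s / 2, [centers[-1] + width_s / 2]])
    ipe_mat = np.zeros((len(per_tone_epochs), n_win))
    for i, cond in enumerate(per_tone_epochs):
        dev_mean = per_trial_counts(cond["DEV"], norm_window).mean()
        std_mean = per_trial_counts(cond["STD"], norm_window).mean()
        ctr_mean = per_trial_counts(cond["CTR"], norm_window).mean()
        norm = np.sqrt(dev_mean**2 + std_mean**2 + ctr_mean**2)
        if norm == 0:
            norm = 1.0  # silent tone: windowed counts are all zero anyway

        def mean_window_counts(eps):
            spikes = np.concatenate(eps.trials) if eps.trials else np.empty(0)
            counts, _ = np.histogram(spikes, bins=edges)
            return counts / eps.n_trials

        ipe_mat[i] = (
            mean_window_counts(cond["DEV"]) - mean_window_counts(cond["CTR"])
        ) / norm

    ipe_mean = ipe_mat.mean(axis=0)
    ipe_sem = ipe_mat.std(axis=0, ddof=1) / np.sqrt(ipe_mat.shape[0])
    p_raw = np.ones(n_win)
    for j in range(n_win):
        col = ipe_mat[:, j]
        if np.allclose(col, 0):
            p_raw[j] = 1.0
        else:
            p_raw[j] = stats.wilcoxon(
                col, zero_method=zero_method, alternative="two-sided"
            ).pvalue
    reject, p_fdr = bh_fdr(p_raw, q=alpha)
    return WindowedIpe(
        window_centers_s=centers,
        width_s=width_s,
        ipe=ipe_mean,
        sem=ipe_sem,
        p_raw=p_raw,
        p_fdr=p_fdr,
        significant=reject,
    )
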