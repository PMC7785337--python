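"""End-to-end orchestration: simulate sessions, analyze spikes and LFPs,
fit adaptation, and emit a summary table in the style of a per-field
median-and-index report.

Every stage is deterministic given the config seed, and each analysis
decision (inclusion test outcome, correction method, dropped trials) is
appended to a structured log so the paradigm-level choices stay auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import adaptation_dynamics as adapt
from . import lfp_mismatch as lfp
from . import mismatch_indices as mmi
from . import spike_metrics as spk
from .sequence_design import Role, events_to_frame, sequence_metadata
from .synthetic_session import (
    SessionConfig,
    SyntheticSession,
    preset_windows,
    simulate_session,
)

__all__ = [
    "PipelineConfig",
    "SummaryTable",
    "run_pipeline",
    "analyze_sessions",
    "compare_conditions",
    "write_report",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    preset: str = "mPFC"
    field_label: str = "M2"
    n_units: int = 10
    n_events: int = 400
    soa_s: float = 0.5
    dev_prob: float = 0.10
    target_tone: int = 5
    direction: str = "ascending"
    include_dev_alone: bool = False
    count_window: Optional[Tuple[float, float]] = None  # preset default if None
    baseline_mode: Optional[str] = None  # "post" | "pre"; preset default if None
    alpha: float = 0.05
    fdr_q: float = 0.1
    n_mc_sim: int = 10_000
    n_ipe_windows: int = 35
    lfp_correction: str = "bonferroni"
    n_lfp_test_points: int = 428
    out_dir: str = "results/run"

    def resolved_windows(self) -> dict:
        w = preset_windows(self.preset)
        count = self.count_window or w["count_window"]
        baseline = self.baseline_mode or (
            "post" if w["baseline_window"][0] >= 0 else "pre"
        )
        return {"count_window": tuple(count), "baseline_mode": baseline}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        if data.get("count_window") is not None:
            data["count_window"] = tuple(data["count_window"])
        return cls(**data)


@dataclass
class SummaryTable:
    field_label: str
    preset: str
    n_multiunits: int
    n_tested_tones: int
    medians: pd.DataFrame  # rows: metric, single column of medians
    omnibus: dict

    def to_frame(self) -> pd.DataFrame:
        df = self.medians.copy()
        df.insert(0, "field", self.field_label)
        return df


def compare_conditions(values: Dict[str, np.ndarray], alpha: float = 0.05, fdr_q: float = 0.1) -> dict:
    """Within-field omnibus and pairwise comparison of paired condition data.

    Delegates to the standard Friedman test across the three paired columns
    and to pairwise two-sided Wilcoxon signed-rank tests, with
    Benjamini-Hochberg correction over the pairwise family.
    """
    keys = list(values)
    cols = [np.asarray(values[k], dtype=float) for k in keys]
    n = {len(c) for c in cols}
    if len(n) != 1:
        raise ValueError("conditions must be paired (equal lengths)")
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        omnibus_p = 1.0
    else:
        omnibus_p = float(stats.friedmanchisquare(*cols).pvalue)
    pair_p = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            d = cols[i] - cols[j]
            pair_p[f"{keys[i]}_vs_{keys[j]}"] = (
                1.0 if np.allclose(d, 0) else float(stats.wilcoxon(d).pvalue)
            )
    reject, p_adj = mmi.bh_fdr(list(pair_p.values()), q=fdr_q)
    pairwise = {
        k: {"p_raw": p_raw, "p_fdr": float(pa), "significant": bool(r)}
        for (k, p_raw), pa, r in zip(pair_p.items(), p_adj, reject)
    }
    return {"omnibus_p": omnibus_p, "pairwise": pairwise}


def _unit_analysis(session: SyntheticSession, cfg: PipelineConfig, log: list) -> dict:
    """Spike-side analysis of one simulated multiunit."""
    win = cfg.resolved_windows()
    epochs = spk.extract_condition_trials(
        session.spike_times, session.sequences, cfg.target_tone, cfg.direction
    )
    mc = spk.monte_carlo_response_test(
        epochs["DEV"],
        window=win["count_window"],
        n_sim=cfg.n_mc_sim,
        alpha=cfg.alpha,
        seed=session.seed + 101,
        baseline_mode=win["baseline_mode"],
    )
    log.append(
        {
            "stage": "inclusion",
            "unit_seed": session.seed,
            "p_value": mc.p_value,
            "included": mc.significant,
            "baseline_mode": win["baseline_mode"],
        }
    )
    counts = {
        c: spk.count_spikes(epochs[c], win["count_window"]) for c in ("DEV", "STD", "CTR")
    }
    triplet, idx = mmi.indices_from_counts(counts["DEV"], counts["STD"], counts["CTR"])
    return {
        "epochs": epochs,
        "mc": mc,
        "counts": counts,
        "triplet": triplet,
        "indices": idx,
        "included": mc.significant,
    }


def _trial_courses(
    sessions: List[SyntheticSession], cfg: PipelineConfig, norms: List[float]
) -> Dict[str, adapt.TrialCourse]:
    """Per-condition average normalized count at each absolute trial position.

    All standards are included (not only pre-deviant ones); each unit's
    counts are normalized by its own whole-window Euclidean norm, then
    averaged across units position by position.
    """
    win = cfg.resolved_windows()["count_window"]
    n_events = cfg.n_events
    sums = {c: np.zeros(n_events) for c in ("DEV", "STD", "CTR")}
    hits = {c: np.zeros(n_events) for c in ("DEV", "STD", "CTR")}
    for session, norm in zip(sessions, norms):
        odd = session.sequences[f"oddball_{cfg.direction}"]
        cas = session.sequences[f"cascade_{cfg.direction}"]
        odd_spikes = session.spike_times[f"oddball_{cfg.direction}"]
        cas_spikes = session.spike_times[f"cascade_{cfg.direction}"]
        for cond, seqname, positions in (
            ("DEV", "odd", odd.role_positions(Role.DEV)),
            ("STD", "odd", odd.role_positions(Role.STD)),
            ("CTR", "cas", np.nonzero(cas.tone_indices() == cfg.target_tone)[0]),
        ):
            seq, train = (odd, odd_spikes) if seqname == "odd" else (cas, cas_spikes)
            trials = spk.extract_epochs(train, seq.onsets()[positions])
            eps = spk.SpikeEpochSet(cond, trials)
            vals = spk.per_trial_counts(eps, win) / norm
            sums[cond][positions] += vals
            hits[cond][positions] += 1
    out = {}
    for cond in sums:
        mask = hits[cond] > 0
        out[cond] = adapt.TrialCourse(
            cond,
            np.nonzero(mask)[0] + 1,
            sums[cond][mask] / hits[cond][mask],
        )
    return out


def analyze_sessions(cfg: PipelineConfig, log: Optional[list] = None) -> dict:
    """Simulate ``cfg.n_units`` multiunit sessions and run every analysis."""
    log = log if log is not None else []
    root = np.random.default_rng(cfg.seed)
    unit_seeds = root.integers(0, 2**31 - 1, size=cfg.n_units)

    sessions, units = [], []
    for s in unit_seeds:
        session = simulate_session(
            SessionConfig(
                preset=cfg.preset,
                target_tone=cfg.target_tone,
                n_events=cfg.n_events,
                soa_s=cfg.soa_s,
                dev_prob=cfg.dev_prob,
                include_dev_alone=cfg.include_dev_alone,
                seed=int(s),
            )
        )
        sessions.append(session)
        units.append(_unit_analysis(session, cfg, log))

    index_rows = []
    for u, s in zip(units, unit_seeds):
        t, idx = u["triplet"], u["indices"]
        index_rows.append(
            {
                "multiunit_id": int(s),
                "tone_index": cfg.target_tone,
                "field_label": cfg.field_label,
                "raw_DEV": u["counts"]["DEV"],
                "raw_STD": u["counts"]["STD"],
                "raw_CTR": u["counts"]["CTR"],
                "dev_n": t.dev_n,
                "std_n": t.std_n,
                "ctr_n": t.ctr_n,
                "iMM": idx.iMM,
                "iRS": idx.iRS,
                "iPE": idx.iPE,
                "included": u["included"],
            }
        )
    index_table = pd.DataFrame(index_rows)

    win = cfg.resolved_windows()["count_window"]
    wipe = mmi.windowed_ipe(
        [u["epochs"] for u in units], alpha=cfg.alpha, norm_window=win
    )

    norms = [u["triplet"].norm for u in units]
    courses = _trial_courses(sessions, cfg, norms)
    block_cmp = adapt.block_compare_std_ctr(
        courses["STD"], courses["CTR"], n_events=cfg.n_events
    )
    fits = adapt.fit_models(courses["STD"])
    best = adapt.select_best(fits)
    power3 = next((f for f in fits if f.family == "power3" and f.converged), None)
    decay = None
    if power3 is not None and power3.params.get("b", 0) < 0:
        decay = adapt.decay_summary(power3)

    # site-level LFP: per unit mean DEV and CTR waves, tested across units
    fs = sessions[0].lfp_model.fs_hz
    dev_means, ctr_means, time_grid = [], [], None
    for session in sessions:
        eps = lfp.extract_lfp_condition_epochs(
            session.lfp, session.sequences, cfg.target_tone, fs, cfg.direction
        )
        dev_means.append(eps["DEV"].mean())
        ctr_means.append(eps["CTR"].mean())
        time_grid = eps["DEV"].time_s
    dev_site = lfp.LfpEpochSet(fs, time_grid, np.vstack(dev_means), "DEV")
    ctr_site = lfp.LfpEpochSet(fs, time_grid, np.vstack(ctr_means), "CTR")
    pe = lfp.pe_lfp(
        dev_site,
        ctr_site,
        n_test_points=cfg.n_lfp_test_points,
        correction=cfg.lfp_correction,
        alpha=cfg.alpha,
    )
    log.append(
        {
            "stage": "pe_lfp",
            "correction": cfg.lfp_correction,
            "n_test_points": cfg.n_lfp_test_points,
            "onset_s": pe.onset_s,
            "n_intervals": len(pe.intervals_s),
        }
    )

    omnibus = compare_conditions(
        {
            "DEV": index_table["dev_n"].to_numpy(),
            "STD": index_table["std_n"].to_numpy(),
            "CTR": index_table["ctr_n"].to_numpy(),
        },
        alpha=cfg.alpha,
        fdr_q=cfg.fdr_q,
    )

    med = index_table.median(numeric_only=True)
    medians = pd.DataFrame(
        {
            "median": {
                "raw_DEV": med["raw_DEV"],
                "raw_STD": med["raw_STD"],
                "raw_CTR": med["raw_CTR"],
                "norm_DEV": med["dev_n"],
                "norm_STD": med["std_n"],
                "norm_CTR": med["ctr_n"],
                "iMM": med["iMM"],
                "iRS": med["iRS"],
                "iPE": med["iPE"],
            }
        }
    )
    summary = SummaryTable(
        field_label=cfg.field_label,
        preset=cfg.preset,
        n_multiunits=cfg.n_units,
        n_tested_tones=cfg.n_units,
        medians=medians,
        omnibus=omnibus,
    )
    return {
        "config": cfg,
        "sessions": sessions,
        "units": units,
        "index_table": index_table,
        "windowed_ipe": wipe,
        "trial_courses": courses,
        "block_compare": block_cmp,
        "fits": fits,
        "best_fit": best,
        "power3_fit": power3,
        "decay": decay,
        "pe_lfp": pe,
        "summary": summary,
        "log": log,
    }


def write_report(results: dict, out_dir: Optional[str] = None, plots: bool = True) -> Path:
    """Write CSV/JSON artifacts (and overview plots) for a completed run."""
    cfg: PipelineConfig = results["config"]
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "config.json").write_text(cfg.to_json())
    results["index_table"].to_csv(out / "indices.csv", index=False)

    for name, seq in results["sessions"][0].sequences.items():
        events_to_frame(seq, sequence_id=name).to_csv(
            out / f"sequence_{name}.csv", index=False
        )
    (out / "sequence_metadata.json").write_text(
        json.dumps(
            {n: sequence_metadata(s) for n, s in results["sessions"][0].sequences.items()},
            indent=2,
        )
    )

    w = results["windowed_ipe"]
    pd.DataFrame(
        {
            "window_center_s": w.window_centers_s,
            "ipe_mean": w.ipe,
            "p_raw": w.p_raw,
            "p_fdr": w.p_fdr,
            "significant": w.significant,
        }
    ).to_csv(out / "windowed_ipe.csv", index=False)

    fit_report = {
        "condition": "STD",
        "best_family": results["best_fit"].family,
        "block_compare_p": results["block_compare"]["p_value"],
        "families": [
            {
                "family": f.family,
                "params": f.params,
                "ci95": {k: list(v) for k, v in f.ci95.items()},
                "adj_r2": f.adj_r2,
                "converged": f.converged,
            }
            for f in results["fits"]
        ],
    }
    if results["decay"] is not None:
        d = results["decay"]
        fit_report["decay"] = {
            "half_decay_trial": d.half_decay_trial,
            "steady_state_trial": d.steady_state_trial,
            "steady_level": d.steady_level,
            "repetitions_to_half": d.repetitions_to_half,
        }
    (out / "adaptation_fits.json").write_text(json.dumps(fit_report, indent=2))

    pe = results["pe_lfp"]
    sig_at = {float(t): bool(s) for t, s in zip(pe.test_times_s, pe.corrected_significant)}
    praw_at = {float(t): float(p) for t, p in zip(pe.test_times_s, pe.p_pointwise)}
    pd.DataFrame(
        {
            "time_s": pe.time_s,
            "mean_dev": pe.mean_dev,
            "mean_ctr": pe.mean_ctr,
            "pe_lfp": pe.pe_lfp,
            "p_raw": [praw_at.get(float(t), np.nan) for t in pe.time_s],
            "significant": [sig_at.get(float(t), False) for t in pe.time_s],
        }
    ).to_csv(out / "pe_lfp.csv", index=False)

    summary = results["summary"]
    summary.to_frame().to_csv(out / "summary_medians.csv")
    (out / "summary.json").write_text(
        json.dumps(
            {
                "field": summary.field_label,
                "preset": summary.preset,
                "n_multiunits": summary.n_multiunits,
                "n_tested_tones": summary.n_tested_tones,
                "medians": summary.medians["median"].to_dict(),
                "omnibus": summary.omnibus,
            },
            indent=2,
        )
    )
    with (out / "decision_log.jsonl").open("w") as fh:
        for entry in results["log"]:
            fh.write(json.dumps(entry) + "\n")

    if plots:
        _plots(results, out)
    return out


def _plots(results: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = results["config"]
    unit = results["units"][0]
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"DEV": "crimson", "STD": "steelblue", "CTR": "seagreen"}
    for cond in ("DEV", "STD", "CTR"):
        sdf = spk.compute_sdf(unit["epochs"][cond])
        ax.plot(sdf.time_s, sdf.rate_hz, label=cond, color=colors[cond])
        ax.fill_between(
            sdf.time_s, sdf.rate_hz - sdf.sem_hz, sdf.rate_hz + sdf.sem_hz,
            alpha=0.2, color=colors[cond],
        )
    ax.set(xlabel="time from tone onset (s)", ylabel="rate (spikes/s)",
           title=f"{cfg.preset} example multiunit: spike-density functions")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "sdf_overlay.png", dpi=110)
    plt.close(fig)

    pe = results["pe_lfp"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(pe.time_s, pe.mean_dev, color="crimson", label="DEV")
    ax.plot(pe.time_s, pe.mean_ctr, color="seagreen", label="CTR")
    ax.plot(pe.time_s, pe.pe_lfp, color="black", label="PE-LFP")
    for a, b in pe.intervals_s:
        ax.axvspan(a, b, color="0.85", zorder=0)
    ax.set(xlabel="time from tone onset (s)", ylabel="amplitude (a.u.)",
           title="Prediction-error potential (shaded: significant)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pe_lfp.png", dpi=110)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, plots: bool = True) -> dict:
    """Full deterministic run: simulate, analyze, and write artifacts."""
    results = analyze_sessions(cfg)
    write_report(results, plots=plots)
    return results
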