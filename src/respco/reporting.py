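"""Summaries and cohort-level analyses: phase-binned behaviour, the
fast/slow-breather split, the between-participant average-phase comparison,
the breathing-rate/PLV correlation, and the all-in-one pipeline driver."""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import comodulation as cm
from . import events as ev
from . import locking as lk
from .preprocess import PhaseSeries, RespCycle, process_trace
from .synth import SessionSpec, generate_session, trial_centred

__all__ = ["phase_bin_summary", "breather_split_analysis",
           "between_participant_phase_analysis", "rate_plv_correlation",
           "run_pipeline", "N_PHASE_BINS"]

N_PHASE_BINS = 6
#: phase bins counted as "around inhalation onset" vs "exhalation side" in
#: the between-participant comparison (bin 0 covers [0, pi/3) and so on);
#: adjust when comparing against a different bin/colour convention.
INHALE_ONSET_BINS = (5, 0)
EXHALE_BINS = (2, 3)


def _bin_of(phase: np.ndarray, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    b = np.floor(np.asarray(phase) / (2 * np.pi / n_bins))
    return np.clip(b, 0, n_bins - 1).astype(float)


def phase_bin_summary(trials: pd.DataFrame, phase: np.ndarray,
                      n_bins: int = N_PHASE_BINS) -> pd.DataFrame:
    """Mean-normalised behaviour per equal-width phase bin.

    Per participant and bin: median sqrt(RT) and fraction correct, each
    centred by subtracting the participant's mean across its populated
    bins, then averaged over participants (mean and SEM per bin).  Bins a
    participant never visited stay missing rather than zero.
    """
    df = trials.copy()
    df["phase_bin"] = _bin_of(phase, n_bins)
    df["sqrt_rt"] = np.sqrt(df["rt_s"])
    per = df.groupby(["participant_id", "phase_bin"]).agg(
        sqrt_rt=("sqrt_rt", "median"), frac_correct=("correct", "mean"),
        n=("rt_s", "size")).reset_index()
    for col in ("sqrt_rt", "frac_correct"):
        per[col] = per[col] - per.groupby("participant_id")[col].transform("mean")
    out = per.groupby("phase_bin").agg(
        sqrt_rt_mean=("sqrt_rt", "mean"),
        sqrt_rt_sem=("sqrt_rt", "sem"),
        frac_correct_mean=("frac_correct", "mean"),
        frac_correct_sem=("frac_correct", "sem"),
        n_participants=("participant_id", "nunique"),
    ).reindex(np.arange(n_bins, dtype=float))
    out.index.name = "phase_bin"
    centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    out.insert(0, "bin_center_rad", centers)
    return out.reset_index()


def _ols_aic(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = y.size
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return float("nan"), beta
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = X.shape[1] + 1
    return float(2 * k - 2 * ll), beta


@dataclass
class BreatherSplit:
    """Fast vs slow breathers (median split on mean cycle duration)."""

    fast: list
    slow: list
    threshold_s: float
    lags: np.ndarray
    summed_daic_fast: np.ndarray
    summed_daic_slow: np.ndarray
    degenerate: bool = False


def mean_cycle_duration(cycles_by_participant: dict[int, list[RespCycle]]) -> pd.Series:
    out = {pid: float(np.mean([c.duration for c in cyc if c.valid]))
           for pid, cyc in cycles_by_participant.items()}
    return pd.Series(out, name="cycle_duration_s")


def breather_split_analysis(trials: pd.DataFrame,
                            cycles_by_participant: dict[int, list[RespCycle]],
                            phases: ev.PhaseSampleMatrix,
                            outcome: str = "sqrt_rt",
                            min_group: int = 4) -> BreatherSplit:
    """Per-group evidence curves from participant-wise fixed-effects models.

    Participants are split at the cohort median of their mean cycle
    duration (the median participant of an odd cohort goes to the slow
    group).  For each participant and lag an ordinary least-squares model
    (intercept, stimulus level, trial number, sine, cosine) is compared to
    the same model without the phase pair; the AIC differences are summed
    within group.  Note this per-participant sum is a different statistic
    from the cohort mixed-model delta-AIC and the two need not agree.
    """
    dur = mean_cycle_duration(cycles_by_participant)
    thr = float(dur.median())
    if np.allclose(dur, dur.iloc[0]):
        warnings.warn("all participants share one cycle duration: split is "
                      "degenerate", RuntimeWarning)
        return BreatherSplit([], sorted(dur.index), thr, phases.lags,
                             np.full(phases.lags.size, np.nan),
                             np.full(phases.lags.size, np.nan), degenerate=True)
    fast = sorted(dur.index[dur < thr].tolist())
    slow = sorted(dur.index[dur >= thr].tolist())
    if min(len(fast), len(slow)) < min_group:
        raise ValueError(f"need >= {min_group} participants per breather group")

    lags = phases.lags
    sums = {"fast": np.zeros(lags.size), "slow": np.zeros(lags.size)}
    for name, members in (("fast", fast), ("slow", slow)):
        for pid in members:
            rows = trials["participant_id"] == pid
            sub_all = trials[rows]
            for j, lag in enumerate(lags):
                phi = phases.lag_column(lag)[rows.to_numpy()]
                flagged = ev.apply_trial_exclusions(
                    sub_all.assign(), _single_matrix(phases, rows, lag, phi), lag)
                keep = ~flagged["excluded"].to_numpy()
                if keep.sum() < 20:
                    sums[name][j] += np.nan
                    continue
                sub = sub_all[keep]
                p = phi[keep]
                y = (np.sqrt(sub["rt_s"].to_numpy()) if outcome == "sqrt_rt"
                     else sub["correct"].to_numpy(dtype=float))
                lvl = sub["stim_level"].to_numpy(dtype=float)
                tc = trial_centred(sub["trial_nr"].to_numpy(),
                                   int(sub_all["trial_nr"].max()))
                ones = np.ones(len(sub))
                X_full = np.column_stack([ones, lvl - lvl.mean(), tc,
                                          np.sin(p), np.cos(p)])
                aic_full, _ = _ols_aic(y, X_full)
                aic_red, _ = _ols_aic(y, X_full[:, :3])
                sums[name][j] += aic_red - aic_full
    return BreatherSplit(fast, slow, thr, lags, sums["fast"], sums["slow"])


def _single_matrix(phases, rows, lag, phi):
    """A one-lag PhaseSampleMatrix restricted to one participant's rows."""
    return ev.PhaseSampleMatrix(alignment=phases.alignment,
                                lags=np.array([lag]),
                                phase=phi[:, None],
                                trial_index=rows.index[rows])


def between_participant_phase_analysis(trials: pd.DataFrame,
                                       mean_phase: pd.DataFrame,
                                       max_median_rt_s: float = 2.0,
                                       n_bins: int = N_PHASE_BINS,
                                       group_a_bins=INHALE_ONSET_BINS,
                                       group_b_bins=EXHALE_BINS) -> dict:
    """Does a participant's average phase predict their overall behaviour?

    Each participant contributes one overall median RT and fraction
    correct, and is assigned to a phase bin by their trial-average phase
    (from :func:`respco.locking.participant_mean_phase`).  Participants in
    the bins around inhalation onset are compared with those in the
    exhalation-side bins by two-sample t-tests.  Participants with a median
    RT at or above ``max_median_rt_s`` are excluded as outliers.
    """
    per = trials.groupby("participant_id").agg(
        median_rt=("rt_s", "median"), frac_correct=("correct", "mean"))
    per = per.join(mean_phase.set_index("participant_id")["mean_phase"])
    per = per[per["median_rt"] < max_median_rt_s].dropna(subset=["mean_phase"])
    per["phase_bin"] = _bin_of(per["mean_phase"].to_numpy(), n_bins)
    in_a = per["phase_bin"].isin(group_a_bins)
    in_b = per["phase_bin"].isin(group_b_bins)
    result = {"per_participant": per.reset_index(),
              "group_a_bins": tuple(group_a_bins),
              "group_b_bins": tuple(group_b_bins),
              "n_a": int(in_a.sum()), "n_b": int(in_b.sum())}
    for col in ("median_rt", "frac_correct"):
        if in_a.sum() < 2 or in_b.sum() < 2:
            warnings.warn("fewer than 2 participants in a phase-bin group; "
                          "t-test skipped", RuntimeWarning)
            result[col] = {"t": float("nan"), "p": float("nan")}
            continue
        t, p = stats.ttest_ind(per.loc[in_a, col], per.loc[in_b, col])
        result[col] = {"t": float(t), "p": float(p)}
    return result


def rate_plv_correlation(cycle_durations: pd.Series, plv_at_zero: pd.Series,
                         n_boot: int = 1000, seed: int | None = 0) -> dict:
    """Spearman correlation between mean cycle duration and PLV at t = 0.

    Ties get average ranks (scipy default).  The bootstrap CI resamples
    participants.
    """
    joined = pd.concat([cycle_durations.rename("dur"),
                        plv_at_zero.rename("plv")], axis=1).dropna()
    if len(joined) < 5:
        raise ValueError("need at least 5 participants")
    r, p = stats.spearmanr(joined["dur"], joined["plv"])
    rng = np.random.default_rng(seed)
    n = len(joined)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        if joined["dur"].iloc[idx].nunique() < 2:
            boots[i] = np.nan
            continue
        boots[i] = stats.spearmanr(joined["dur"].iloc[idx],
                                   joined["plv"].iloc[idx]).statistic
    return {"r": float(r), "p": float(p),
            "ci": (float(np.nanquantile(boots, 0.025)),
                   float(np.nanquantile(boots, 0.975))),
            "n": n}


DEFAULT_CONFIG = {
    "seed": 0,
    "n_participants": 10,
    "n_trials": 200,
    "alignments": ["stimulus", "response"],
    "lag_of_interest": -2.1,
    "max_lag": -4.5,
    "n_surrogates": 200,
    "n_shuffles": 200,
    "plv_window": [-6.0, 2.0],
    "figures": False,
}


def run_pipeline(config: dict | None = None, outdir: str | Path = "out",
                 session=None) -> dict:
    """Chain synthesis, preprocessing, phase sampling, phase locking,
    model comparison and reporting; write tidy TSV/JSON outputs.

    ``config`` overrides :data:`DEFAULT_CONFIG`; pass a pre-built
    ``session`` to analyse existing data instead of synthesising.  Returns
    a dict of the in-memory results; all tables also land in ``outdir``
    together with a run manifest.  Identical config and seed give
    byte-identical outputs.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    if session is None:
        spec = SessionSpec(n_participants=int(cfg["n_participants"]),
                           n_trials=int(cfg["n_trials"]), seed=seed)
        session = generate_session(spec)
    trials = session.trials

    # preprocessing
    cycles_by, phase_by = {}, {}
    for pid, raw in session.traces.items():
        _, cycles, phase = process_trace(raw)
        cycles_by[pid] = cycles
        phase_by[pid] = phase
    cyc_rows = [{"participant_id": pid, "cycle_idx": i,
                 "t_inhale_on_s": c.inhale_onset, "t_peak_s": c.peak,
                 "t_exhale_end_s": c.exhale_end, "valid": int(c.valid),
                 "distance": c.distance_to_centroid}
                for pid, cyc in cycles_by.items() for i, c in enumerate(cyc)]
    pd.DataFrame(cyc_rows).to_csv(outdir / "cycles.tsv", sep="\t", index=False)

    lag0 = float(cfg["lag_of_interest"])
    lag_grid = ev.default_lag_grid(float(cfg["max_lag"]))
    results: dict = {"config": cfg}
    scan_frames, plv_frames = [], []
    for alignment in cfg["alignments"]:
        pm = ev.sample_phase(trials, phase_by, alignment, lag_grid)
        flagged = ev.apply_trial_exclusions(trials, pm, lag0)
        kept_participants = ev.participant_retention(flagged)
        retained = flagged[~flagged["excluded"]
                           & flagged["participant_id"].isin(kept_participants)]
        results[f"exclusions_{alignment}"] = ev.exclusion_summary(flagged).to_dict()

        curve = lk.plv_timecourse(retained, phase_by, alignment,
                                  times=lk.default_time_grid(*cfg["plv_window"]),
                                  seed=seed)
        surr = lk.surrogate_test(retained, phase_by, alignment,
                                 times=curve.times,
                                 n_surrogates=int(cfg["n_surrogates"]), seed=seed)
        cdf = curve.to_frame()
        cdf["p"] = surr["p"]
        plv_frames.append(cdf)
        results[f"plv_{alignment}"] = {"curve": curve, "surrogate": surr}

        scan = cm.lag_scan(trials, pm, outcome="sqrt_rt")
        scan_frames.append(scan.to_frame())
        results[f"lag_scan_{alignment}"] = scan

        if alignment == cfg["alignments"][-1]:
            keep = ~flagged["excluded"].to_numpy()
            phi = pm.lag_column(lag0)[keep]
            sub = flagged[keep]
            sh = cm.shuffle_test(sub, phi, n_shuffles=int(cfg["n_shuffles"]),
                                 seed=seed)
            results["shuffle"] = {"p": sh["p"], "v": sh["v_observed"]}
            results["phase_bins"] = phase_bin_summary(sub, phi)
            results["phase_bins"].to_csv(outdir / "phase_bins.tsv", sep="\t",
                                         index=False)
            mp = lk.participant_mean_phase(retained, phase_by, alignment, lag0)
            results["between_participant"] = between_participant_phase_analysis(
                retained, mp)
            dur = mean_cycle_duration(cycles_by)
            plv0 = lk.participant_mean_phase(retained, phase_by, alignment, 0.0)
            try:
                results["rate_plv"] = rate_plv_correlation(
                    dur, plv0.set_index("participant_id")["plv"], seed=seed)
            except ValueError as exc:
                warnings.warn(f"rate/PLV correlation skipped: {exc}",
                              RuntimeWarning)
                results["rate_plv"] = None

    pd.concat(plv_frames, ignore_index=True).to_csv(
        outdir / "plv_curves.tsv", sep="\t", index=False, float_format="%.6f")
    pd.concat(scan_frames, ignore_index=True).to_csv(
        outdir / "lag_scan.tsv", sep="\t", index=False, float_format="%.6f")

    if cfg.get("figures"):
        _write_figures(results, outdir)

    manifest = {
        "seed": seed, "config": {k: v for k, v in cfg.items()},
        "n_participants": int(trials["participant_id"].nunique()),
        "n_trials_total": int(len(trials)),
        "outputs": ["cycles.tsv", "plv_curves.tsv", "lag_scan.tsv",
                    "phase_bins.tsv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return results


def _write_figures(results: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for alignment in ("stimulus", "response"):
        key = f"plv_{alignment}"
        if key in results:
            c = results[key]["curve"]
            axes[0].plot(c.times, c.median, label=alignment)
        key = f"lag_scan_{alignment}"
        if key in results:
            s = results[key]
            axes[1].plot(s.lags, s.delta_aic, label=alignment)
    axes[0].set(xlabel="time around event (s)", ylabel="group-median PLV")
    axes[1].axhline(cm.EVIDENCE_DAIC, color="grey", ls=":")
    axes[1].set(xlabel="lag (s)", ylabel="delta AIC (favouring phase model)")
    for ax in axes:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(outdir / "summary.png", dpi=120)
    plt.close(fig)
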