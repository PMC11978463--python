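"""Study-condition validation runs.

Each function simulates cohorts at the conditions the analysis is meant to
operate under (cycle durations 3.6 +- 0.7 s, ~3 s trial pacing, sqrt(RT)
coupling amplitudes of order 0.02 sqrt-s) and pushes them through the full
pipeline: trace synthesis, preprocessing, phase sampling, exclusions and
the statistics under test.  They back both the acceptance test suite and
``scripts/acceptance.py``; problem sizes are chosen so a complete pass runs
in a few minutes on one CPU.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import comodulation as cm
from . import events as ev
from . import locking as lk
from .preprocess import process_trace
from .synth import SessionSpec, generate_session

__all__ = ["cohort_seeds", "lag_recovery_run", "null_evidence_run",
           "shuffle_calibration_run", "surrogate_fwer_run",
           "timing_oracle_run", "plv_closed_form_checks",
           "rotation_invariance_check", "parameter_recovery_summary"]

TRUE_LAG = -2.1
LAG_TOL = 0.31          # one 0.3 s grid step


def cohort_seeds(master_seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(int(master_seed))
    return rng.integers(0, 2**31 - 1, size=n)


def _pipeline_phases(session):
    phase_by = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, raw in session.traces.items():
            phase_by[pid] = process_trace(raw)[2]
    return phase_by


def _scan_cohort(seed: int, n_participants: int, n_trials: int,
                 beta: float, lam: float):
    spec = SessionSpec(n_participants=n_participants, n_trials=n_trials,
                       seed=int(seed), cycle_between_sd=0.0,
                       entrainment_strength=lam,
                       coupling_amplitude_rt=(beta, 0.0),
                       coupling_lag=TRUE_LAG, coupling_reference="response")
    session = generate_session(spec)
    phase_by = _pipeline_phases(session)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pm = ev.sample_phase(session.trials, phase_by, "response",
                             ev.default_lag_grid(-4.5))
        scan = cm.lag_scan(session.trials, pm, "sqrt_rt")
        # full-model coefficients at the generative lag
        flagged = ev.apply_trial_exclusions(session.trials, pm, TRUE_LAG)
        keep = ~flagged["excluded"].to_numpy()
        fit = cm.fit_model(flagged[keep], pm.lag_column(TRUE_LAG)[keep],
                           cm.ModelSpec("sqrt_rt", True))
    return scan, fit


def lag_recovery_run(master_seed: int, n_cohorts: int = 20,
                     n_participants: int = 20, n_trials: int = 300,
                     beta: float = 0.02, lam: float = 0.4) -> dict:
    """Simulate coupled cohorts and scan for the generative lag.

    Returns per-cohort peak lags, the number recovered within one grid
    step of -2.1 s, and the fitted sine/cosine pair at the true lag (used
    for the parameter-recovery summary when ``lam = 0``).
    """
    peaks, hits, betas, daic_at_true = [], 0, [], []
    for seed in cohort_seeds(master_seed, n_cohorts):
        scan, fit = _scan_cohort(seed, n_participants, n_trials, beta, lam)
        peaks.append(scan.peak_lag)
        hits += abs(scan.peak_lag - TRUE_LAG) <= LAG_TOL
        betas.append((fit.coef("resp_sin"), fit.coef("resp_cos")))
        j = int(np.argmin(np.abs(scan.lags - TRUE_LAG)))
        daic_at_true.append(scan.delta_aic[j])
    return {"peak_lags": np.asarray(peaks), "hits": int(hits),
            "n_cohorts": n_cohorts, "betas": np.asarray(betas),
            "true_beta": (beta, 0.0),
            "delta_aic_at_true_lag": np.asarray(daic_at_true)}


def null_evidence_run(master_seed: int, n_cohorts: int = 20,
                      n_participants: int = 20, n_trials: int = 300) -> dict:
    """Null configuration (no entrainment, no coupling): the maximal
    delta-AIC over the lag grid should stay below the 9.2 evidence bar in
    nearly all cohorts."""
    maxima = []
    for seed in cohort_seeds(master_seed + 1, n_cohorts):
        scan, _ = _scan_cohort(seed, n_participants, n_trials, 0.0, 0.0)
        maxima.append(float(np.nanmax(scan.delta_aic)))
    maxima = np.asarray(maxima)
    return {"max_delta_aic": maxima,
            "n_exceeding": int(np.sum(maxima > cm.EVIDENCE_DAIC)),
            "n_cohorts": n_cohorts}


def shuffle_calibration_run(master_seed: int, n_replicates: int = 100,
                            n_shuffles: int = 200, n_participants: int = 5,
                            n_trials: int = 60) -> dict:
    """Permutation p-values under the null are uniform.

    Each replicate is a small uncoupled cohort; the vector-strength shuffle
    test yields one p-value; the collection is compared against U(0, 1) by
    a Kolmogorov-Smirnov test.
    """
    ps = []
    for seed in cohort_seeds(master_seed + 2, n_replicates):
        spec = SessionSpec(n_participants=n_participants, n_trials=n_trials,
                           seed=int(seed), entrainment_strength=0.0,
                           coupling_amplitude_rt=(0.0, 0.0),
                           coupling_amplitude_acc=(0.0, 0.0))
        session = generate_session(spec)
        phase_by = _pipeline_phases(session)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pm = ev.sample_phase(session.trials, phase_by, "response",
                                 np.array([TRUE_LAG]))
            flagged = ev.apply_trial_exclusions(session.trials, pm, TRUE_LAG)
            keep = ~flagged["excluded"].to_numpy()
            res = cm.shuffle_test(flagged[keep],
                                  pm.lag_column(TRUE_LAG)[keep],
                                  n_shuffles=n_shuffles, seed=int(seed))
        ps.append(res["p"])
    ps = np.asarray(ps)
    ks = stats.kstest(ps, "uniform")
    return {"p_values": ps, "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue), "n_replicates": n_replicates}


def surrogate_fwer_run(master_seed: int, n_sessions: int = 200,
                       n_surrogates: int = 200, n_participants: int = 6,
                       n_trials: int = 60, alpha: float = 0.05) -> dict:
    """Family-wise error of the max-statistic surrogate test under the
    no-entrainment null: the fraction of sessions with any time point
    significant at ``alpha`` should not exceed ``alpha``."""
    times = lk.default_time_grid(-6.0, 2.0)
    n_pos = 0
    for seed in cohort_seeds(master_seed + 3, n_sessions):
        spec = SessionSpec(n_participants=n_participants, n_trials=n_trials,
                           seed=int(seed), entrainment_strength=0.0,
                           coupling_amplitude_rt=(0.0, 0.0))
        session = generate_session(spec)
        phase_by = _pipeline_phases(session)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lk.surrogate_test(session.trials, phase_by, "stimulus",
                                    times=times, n_surrogates=n_surrogates,
                                    seed=int(seed))
        n_pos += bool((res["p"] <= alpha).any())
    return {"n_positive": int(n_pos), "n_sessions": n_sessions,
            "fwer": n_pos / n_sessions, "alpha": alpha}


def timing_oracle_run(master_seed: int, n_participants: int = 5,
                      n_trials: int = 40) -> dict:
    """Landmark recovery on noise-free traces against generator truth.

    Reports the median, 95th-percentile and maximal absolute error (ms)
    across inhale onsets, peaks and exhale ends, pooled over participants.
    """
    errs, missed, total = [], 0, 0
    for seed in cohort_seeds(master_seed + 4, n_participants):
        spec = SessionSpec(n_participants=1, n_trials=n_trials,
                           seed=int(seed), entrainment_strength=0.0,
                           noise_sd=0.0, pause_prob=0.0)
        session = generate_session(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, cycles, _ = process_trace(session.traces[0])
        truth = session.truth["participants"][0]["true_cycles"]
        det = [c for c in cycles if c.valid and not c.truncated]
        for _, row in truth.iterrows():
            total += 1
            near = [c for c in det if abs(c.peak - row.t_peak_s) < 0.3]
            if not near:
                missed += 1
                continue
            b = near[0]
            errs.append([abs(b.inhale_onset - row.t_inhale_on_s),
                         abs(b.peak - row.t_peak_s),
                         abs(b.exhale_end - row.t_exhale_end_s)])
    errs_ms = 1000 * np.asarray(errs)
    return {"errors_ms": errs_ms,
            "median_ms": np.median(errs_ms, axis=0),
            "p95_ms": np.quantile(errs_ms, 0.95, axis=0),
            "max_ms": errs_ms.max(axis=0),
            "n_cycles": len(errs_ms), "n_missed": missed, "n_true": total}


def plv_closed_form_checks() -> dict:
    """The three closed-form PLV cases, against the complex-mean oracle."""
    r_same, _, _ = lk.plv(np.full(10, np.pi / 3))
    r_anti, _, _ = lk.plv([0.0, np.pi])
    r_pair, _, _ = lk.plv([0.0, np.pi / 2])
    oracle = abs(np.mean(np.exp(1j * np.array([0.0, np.pi / 2]))))
    return {"identical": float(r_same), "antipodal": float(r_anti),
            "quarter_pair": float(r_pair), "quarter_pair_oracle": float(oracle)}


def rotation_invariance_check(master_seed: int, n: int = 2000) -> float:
    """Max |V(rotated) - V| over phase-origin rotations of a refitted model."""
    import pandas as pd
    rng = np.random.default_rng(master_seed + 5)
    ph = rng.uniform(0, 2 * np.pi, n)
    srt = 1.0 + 0.03 * np.sin(ph) + 0.02 * np.cos(ph) \
        + 0.1 * rng.standard_normal(n)
    df = pd.DataFrame({"participant_id": np.repeat(np.arange(4), n // 4),
                       "trial_nr": np.tile(np.arange(1, n // 4 + 1), 4),
                       "stim_level": rng.integers(1, 6, n),
                       "rt_s": srt ** 2, "correct": 1})
    v0 = cm.vector_strength(cm.fit_model(df, ph, cm.ModelSpec()))
    worst = 0.0
    for rot in (0.5, 1.7, 3.0):
        v = cm.vector_strength(
            cm.fit_model(df, (ph + rot) % (2 * np.pi), cm.ModelSpec()))
        worst = max(worst, abs(v - v0))
    return worst


def parameter_recovery_summary(recovery: dict) -> dict:
    """Bias of the fitted coupling amplitude relative to the truth."""
    betas = recovery["betas"]
    true_amp = float(np.hypot(*recovery["true_beta"]))
    amps = np.hypot(betas[:, 0], betas[:, 1])
    mean_bias = float(np.mean(amps) - true_amp)
    return {"true_amplitude": true_amp,
            "mean_fitted_amplitude": float(np.mean(amps)),
            "bias": mean_bias,
            "bias_pct": 100.0 * mean_bias / true_amp}
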