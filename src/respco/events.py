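"""Event-relative phase sampling and trial/participant exclusion rules.

Respiratory phase is looked up at event-relative lags on a 0.3 s grid
(nearest-sample lookup on the 100 Hz phase series).  Trials are excluded
when the participant pressed a wrong button, when the reaction time is an
outlier (< 200 ms or > 3 s), or when the respiratory phase is undefined at
the time point of interest; participants keep their data only if these
rules removed less than 30% of their trials.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PhaseSeries

__all__ = ["PhaseSampleMatrix", "default_lag_grid", "sample_phase",
           "apply_trial_exclusions", "participant_retention",
           "classify_lag_epoch", "RT_MIN_S", "RT_MAX_S", "LAG_STEP_S"]

RT_MIN_S = 0.2
RT_MAX_S = 3.0
RETENTION_MAX_EXCLUDED = 0.30
LAG_STEP_S = 0.3

#: exclusion reason codes, in precedence order
REASONS = ("WRONG_BUTTON", "RT_SHORT", "RT_LONG", "PHASE_UNDEFINED")


def default_lag_grid(max_lag: float = -4.5) -> np.ndarray:
    """Non-positive lags from 0 back to ``max_lag`` in 0.3 s steps."""
    n = int(round(-max_lag / LAG_STEP_S))
    return -LAG_STEP_S * np.arange(n + 1)


@dataclass
class PhaseSampleMatrix:
    """Trial x lag grid of respiratory phases relative to one event.

    ``phase[i, j]`` is the phase of trial ``trials.index[i]`` at
    (alignment event + ``lags[j]``); NaN marks undefined samples.
    """

    alignment: str
    lags: np.ndarray
    phase: np.ndarray
    trial_index: pd.Index

    def lag_column(self, lag: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.lags - lag)))
        if abs(self.lags[j] - lag) > 1e-6:
            raise KeyError(f"lag {lag} not on the sampled grid")
        return self.phase[:, j]

    def defined_fraction(self, lag: float) -> float:
        return float(np.mean(np.isfinite(self.lag_column(lag))))

    def to_long_frame(self, trials: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for j, lag in enumerate(self.lags):
            rows.append(pd.DataFrame({
                "participant_id": trials.loc[self.trial_index, "participant_id"].to_numpy(),
                "trial_nr": trials.loc[self.trial_index, "trial_nr"].to_numpy(),
                "alignment": self.alignment,
                "lag_s": lag,
                "phase_rad": self.phase[:, j],
                "defined": np.isfinite(self.phase[:, j]).astype(int),
            }))
        return pd.concat(rows, ignore_index=True)


def sample_phase(trials: pd.DataFrame, phase_by_participant: dict[int, PhaseSeries],
                 alignment: str = "response",
                 lags: np.ndarray | None = None) -> PhaseSampleMatrix:
    """Phase at (event + lag) for every trial and lag.

    ``alignment`` selects the reference event ('stimulus' or 'response').
    Events falling outside a participant's trace yield NaN and are counted
    in a warning.
    """
    if alignment not in ("stimulus", "response"):
        raise ValueError("alignment must be 'stimulus' or 'response'")
    if lags is None:
        lags = default_lag_grid()
    lags = np.asarray(lags, dtype=float)
    col = "t_stimulus_s" if alignment == "stimulus" else "t_response_s"
    phase = np.full((len(trials), lags.size), np.nan)
    n_outside = 0
    for pid, grp in trials.groupby("participant_id", sort=False):
        ps = phase_by_participant[pid]
        ev = grp[col].to_numpy()
        t = ev[:, None] + lags[None, :]
        outside = (t < ps.t0) | (t >= ps.t0 + ps.duration)
        n_outside += int(outside.sum())
        rows = trials.index.get_indexer(grp.index)
        phase[rows] = ps.phase_at(t)
    if n_outside:
        warnings.warn(f"{n_outside} event/lag samples fall outside the trace span",
                      RuntimeWarning)
    return PhaseSampleMatrix(alignment=alignment, lags=lags, phase=phase,
                             trial_index=trials.index)


def apply_trial_exclusions(trials: pd.DataFrame, phases: PhaseSampleMatrix,
                           lag_of_interest: float) -> pd.DataFrame:
    """Flag excluded trials with a single reason code each.

    Precedence: WRONG_BUTTON > RT_SHORT / RT_LONG > PHASE_UNDEFINED, so the
    per-reason counts are mutually exclusive and sum to the number of
    excluded trials.
    """
    out = trials.copy()
    rt = out["rt_s"].to_numpy(dtype=float)
    phi = phases.lag_column(lag_of_interest)
    wrong = out["wrong_button"].to_numpy(dtype=bool) if "wrong_button" in out \
        else np.zeros(len(out), dtype=bool)

    reason = np.full(len(out), "", dtype=object)
    undef = ~np.isfinite(phi)
    reason[undef] = "PHASE_UNDEFINED"
    reason[rt > RT_MAX_S] = "RT_LONG"
    reason[rt < RT_MIN_S] = "RT_SHORT"
    reason[wrong] = "WRONG_BUTTON"

    out["excluded"] = reason != ""
    out["exclusion_reason"] = reason
    return out


def exclusion_summary(trials: pd.DataFrame) -> pd.Series:
    """Counts per exclusion reason plus the retained count."""
    counts = {r: int((trials["exclusion_reason"] == r).sum()) for r in REASONS}
    counts["retained"] = int((~trials["excluded"]).sum())
    return pd.Series(counts)


def participant_retention(trials: pd.DataFrame) -> list:
    """Participants for whom strictly less than 30% of trials were excluded."""
    frac = trials.groupby("participant_id")["excluded"].mean()
    return sorted(frac.index[frac < RETENTION_MAX_EXCLUDED].tolist())


def classify_lag_epoch(trials: pd.DataFrame, t_point: np.ndarray) -> pd.Series:
    """Assign each trial's probe time to a trial epoch.

    Epochs, judged against the trial's own and the previous trial's events:
    ``response_period_same_trial`` (between stimulus and response),
    ``fixation_current``, ``previous_iti`` (between the previous response
    and the current fixation onset), ``previous_stim_response`` and
    ``other``.  The first trial of each participant has no previous trial,
    so only its own events are used there.
    """
    t_point = np.asarray(t_point, dtype=float)
    if t_point.shape[0] != len(trials):
        raise ValueError("t_point must have one entry per trial")
    labels = np.full(len(trials), "other", dtype=object)
    pos = 0
    for _, grp in trials.groupby("participant_id", sort=False):
        f = grp["t_fixation_s"].to_numpy()
        s = grp["t_stimulus_s"].to_numpy()
        r = grp["t_response_s"].to_numpy()
        p = t_point[pos:pos + len(grp)]
        prev_s = np.concatenate(([np.nan], s[:-1]))
        prev_r = np.concatenate(([np.nan], r[:-1]))
        lab = np.full(len(grp), "other", dtype=object)
        lab[(p >= prev_s) & (p <= prev_r)] = "previous_stim_response"
        lab[(p > prev_r) & (p < f)] = "previous_iti"
        lab[np.isnan(prev_r) & (p < f)] = "other"
        lab[(p >= f) & (p <= s)] = "fixation_current"
        lab[(p > s) & (p <= r)] = "response_period_same_trial"
        labels[pos:pos + len(grp)] = lab
        pos += len(grp)
    return pd.Series(labels, index=trials.index, name="epoch")


def epoch_proportions(labels: pd.Series) -> pd.Series:
    order = ["response_period_same_trial", "fixation_current", "previous_iti",
             "previous_stim_response", "other"]
    frac = labels.value_counts(normalize=True)
    return frac.reindex(order, fill_value=0.0)
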