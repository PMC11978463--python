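"""Synthetic multi-participant sessions with known ground truth.

Generates (i) trial event sequences with the standard pacing of a
self-paced forced-choice experiment (fixation 0.4-1.0 s, response, then an
inter-trial interval of 1.2-1.5 s, all uniform draws, so stimulus onsets
repeat every ~3-4 s); (ii) a pseudo-periodic respiratory trace built from
raised-cosine half cycles (inhalation rising, exhalation falling, the
inhalation the shorter fraction of the cycle) whose durations jitter around
a per-participant mean, with optional end-expiratory pauses, partial phase
resets at fixation onsets (entrainment) and additive measurement noise; and
(iii) trial behaviour whose sqrt(reaction time) and logit(accuracy) are
coupled to the respiratory phase at a configurable lag relative to the
stimulus or the response.

Everything is deterministic given the master seed: each participant and
generation stage draws from its own `numpy` seed-sequence stream.  The
parameters actually used per participant are recorded as ground truth so
downstream stages can be tested for parameter recovery.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RespTrace, PhaseSeries

__all__ = ["SessionSpec", "SyntheticSession", "generate_trial_sequence",
           "generate_resp_trace", "generate_behaviour", "generate_session",
           "write_session", "read_session"]

TWO_PI = 2.0 * np.pi

# RNG stream labels (third entry of the seed sequence)
_S_SUBJECT, _S_TRIALS, _S_TRACE, _S_BEHAV = 0, 1, 2, 3


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic cohort.

    Durations are in seconds; reaction-time coefficients live on the
    sqrt(RT) scale (sqrt-seconds) and accuracy coefficients on the logit
    scale.  ``entrainment_strength`` (lambda) mixes the ongoing respiratory
    phase with ``entrainment_target_phase`` at every fixation onset:
    0 = free-running, 1 = full phase reset.  ``coupling_lag`` places the
    phase that drives behaviour relative to ``coupling_reference``
    (negative = before the event).
    """

    n_participants: int = 20
    n_trials: int = 300
    fixation_range: tuple[float, float] = (0.4, 1.0)
    iti_range: tuple[float, float] = (1.2, 1.5)
    stimulus_duration: float = 0.5
    n_stim_levels: int = 5

    # behaviour (sqrt(RT) in sqrt-seconds; accuracy on the logit scale)
    sqrt_rt_intercept: float = 1.0
    stim_level_beta: float = 0.03
    resid_sd: float = 0.12
    participant_sd: float = 0.08
    trial_slope_sd: float = 0.04
    acc_intercept: float = 1.6
    acc_level_beta: float = 0.35
    wrong_button_prob: float = 0.0

    # respiration
    cycle_duration_mean: float = 3.6
    cycle_duration_sd: float = 0.7
    cycle_between_sd: float = 0.45
    inhale_fraction: float = 0.46
    pause_prob: float = 0.10
    pause_range: tuple[float, float] = (0.2, 0.8)
    noise_sd: float = 0.05
    fs_raw: float = 200.0

    # entrainment and phase-behaviour coupling
    entrainment_strength: float = 0.4
    entrainment_target_phase: float = np.pi / 2
    coupling_amplitude_rt: tuple[float, float] = (0.02, 0.0)
    coupling_amplitude_acc: tuple[float, float] = (0.1, 0.0)
    coupling_lag: float = -2.1
    coupling_reference: str = "response"

    pad_start: float = 8.0
    pad_end: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("fixation_range", "iti_range", "pause_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")
        for name in ("stimulus_duration", "cycle_duration_mean", "fs_raw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.entrainment_strength <= 1.0:
            raise ValueError("entrainment_strength must lie in [0, 1]")
        if not 0.0 < self.inhale_fraction < 1.0:
            raise ValueError("inhale_fraction must lie in (0, 1)")
        if self.coupling_reference not in ("stimulus", "response"):
            raise ValueError("coupling_reference must be 'stimulus' or 'response'")


@dataclass
class SyntheticSession:
    """One generated cohort: traces, trials and the generating ground truth."""

    spec: SessionSpec
    traces: dict[int, RespTrace]
    true_phase: dict[int, PhaseSeries]
    trials: pd.DataFrame
    truth: dict


def _rng(spec: SessionSpec, participant: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(participant), int(stream)])
    )


def _subject_params(spec: SessionSpec, participant: int) -> dict:
    rng = _rng(spec, participant, _S_SUBJECT)
    u0 = spec.participant_sd * rng.standard_normal()
    u_trial = spec.trial_slope_sd * rng.standard_normal()
    if spec.cycle_between_sd > 0:
        mu = float(np.clip(
            rng.normal(spec.cycle_duration_mean, spec.cycle_between_sd), 2.0, 6.5))
    else:
        mu = spec.cycle_duration_mean
    within_sd = float(np.sqrt(max(spec.cycle_duration_sd ** 2
                                  - spec.cycle_between_sd ** 2, 0.0)))
    return {"u0": float(u0), "u_trial": float(u_trial),
            "cycle_mean": mu, "cycle_within_sd": within_sd}


def trial_centred(trial_nr: np.ndarray, n_trials: int) -> np.ndarray:
    """Trial number mapped to [-0.5, 0.5] (the random-slope covariate)."""
    if n_trials <= 1:
        return np.zeros_like(np.asarray(trial_nr, dtype=float))
    return (np.asarray(trial_nr, dtype=float) - 1) / (n_trials - 1) - 0.5


def generate_trial_sequence(spec: SessionSpec, participant: int) -> pd.DataFrame:
    """Event times for one participant, before phase coupling.

    Each trial: fixation onset, stimulus onset after a uniform fixation
    duration, a provisional response from the non-respiratory part of the
    reaction-time model, then a uniform inter-trial interval to the next
    fixation onset.  The provisional sqrt(RT) draw is kept in the table
    (column ``sqrt_rt0``) so :func:`generate_behaviour` can add the phase
    term without redrawing noise.
    """
    sub = _subject_params(spec, participant)
    rng = _rng(spec, participant, _S_TRIALS)
    n = spec.n_trials
    levels = rng.integers(1, spec.n_stim_levels + 1, size=n)
    fix_dur = rng.uniform(*spec.fixation_range, size=n)
    itis = rng.uniform(*spec.iti_range, size=n)
    eps = rng.standard_normal(n)

    lvl_c = levels - (spec.n_stim_levels + 1) / 2.0
    tc = trial_centred(np.arange(1, n + 1), n)
    sqrt_rt0 = (spec.sqrt_rt_intercept + spec.stim_level_beta * lvl_c
                + sub["u0"] + sub["u_trial"] * tc + spec.resid_sd * eps)
    sqrt_rt0 = np.maximum(sqrt_rt0, 0.1)
    rt0 = sqrt_rt0 ** 2

    t_fix = np.empty(n)
    t_stim = np.empty(n)
    t_resp = np.empty(n)
    t = spec.pad_start
    for i in range(n):
        t_fix[i] = t
        t_stim[i] = t_fix[i] + fix_dur[i]
        t_resp[i] = t_stim[i] + rt0[i]
        t = t_resp[i] + itis[i]

    return pd.DataFrame({
        "participant_id": participant,
        "trial_nr": np.arange(1, n + 1),
        "t_fixation_s": t_fix,
        "t_stimulus_s": t_stim,
        "t_response_s": t_resp,
        "stim_level": levels,
        "correct": np.nan,
        "rt_s": rt0,
        "sqrt_rt0": sqrt_rt0,
        "wrong_button": False,
    })


def _circular_mix(phi: float, target: float, lam: float) -> float:
    """Partial phase reset: angle of (1-lam)*e^{i phi} + lam*e^{i target}."""
    z = (1.0 - lam) * np.exp(1j * phi) + lam * np.exp(1j * target)
    if np.abs(z) < 1e-12:          # exactly antipodal at lam=0.5: keep current
        return phi % TWO_PI
    return float(np.angle(z) % TWO_PI)


def generate_resp_trace(spec: SessionSpec, trials: pd.DataFrame,
                        participant: int) -> tuple[RespTrace, PhaseSeries, pd.DataFrame]:
    """Simulate the respiratory trace for one participant.

    The phase advances piecewise linearly at rate pi/T_inhale during
    inhalation and pi/T_exhale during exhalation, with per-cycle durations
    drawn around the participant mean.  At every fixation onset the phase is
    partially reset toward the target phase (circular mixture with weight
    lambda).  End-expiratory pauses hold the signal at the trough.  The
    recorded signal is -cos(phase) plus white measurement noise, sampled at
    ``spec.fs_raw``.

    Returns the raw trace, the ground-truth phase series (100 Hz, NaN during
    pauses) and a table of ground-truth cycles (cycles disturbed by a reset
    are not listed; their timing has no clean inhale/peak/exhale structure).
    """
    sub = _subject_params(spec, participant)
    rng = _rng(spec, participant, _S_TRACE)
    lam = spec.entrainment_strength
    target = spec.entrainment_target_phase % TWO_PI
    t_end = float(trials["t_response_s"].iloc[-1]) + spec.pad_end
    events = list(trials["t_fixation_s"].to_numpy())

    def draw_cycle() -> tuple[float, float]:
        dur = float(np.clip(rng.normal(sub["cycle_mean"], sub["cycle_within_sd"]),
                            1.2, 9.0))
        t_in = dur * spec.inhale_fraction
        return t_in, dur - t_in

    # forward simulation producing piecewise-linear phase segments
    seg_t, seg_phi, seg_rate, seg_pause = [], [], [], []
    landmarks = []            # (time, kind) kind in {onset, peak, end, reset}
    t = 0.0
    phi = float(rng.uniform(0.0, TWO_PI))
    t_in, t_ex = draw_cycle()
    ev = 0
    if phi < 1e-9:
        landmarks.append((t, "onset"))

    def rate_of(p: float) -> float:
        return np.pi / t_in if p < np.pi else np.pi / t_ex

    while t < t_end:
        r = rate_of(phi)
        # time to next half-cycle boundary
        bound = np.pi if phi < np.pi else TWO_PI
        t_bound = t + (bound - phi) / r
        t_event = events[ev] if ev < len(events) else np.inf
        if t_event < min(t_bound, t_end):
            seg_t.append(t); seg_phi.append(phi); seg_rate.append(r)
            seg_pause.append(False)
            phi = (phi + r * (t_event - t)) % TWO_PI
            t = t_event
            new_phi = _circular_mix(phi, target, lam)
            if abs(new_phi - phi) > 1e-9:
                landmarks.append((t, "reset"))
            phi = new_phi
            ev += 1
            continue
        seg_t.append(t); seg_phi.append(phi); seg_rate.append(r)
        seg_pause.append(False)
        t = t_bound
        if bound == np.pi:
            phi = np.pi
            landmarks.append((t, "peak"))
        else:
            phi = 0.0
            landmarks.append((t, "end"))
            if rng.uniform() < spec.pause_prob:
                pause = float(rng.uniform(*spec.pause_range))
                seg_t.append(t); seg_phi.append(0.0); seg_rate.append(0.0)
                seg_pause.append(True)
                t += pause
            landmarks.append((t, "onset"))
            t_in, t_ex = draw_cycle()

    seg_t = np.asarray(seg_t)
    seg_phi = np.asarray(seg_phi)
    seg_rate = np.asarray(seg_rate)
    seg_pause = np.asarray(seg_pause, dtype=bool)

    def phase_on_grid(fs: float) -> tuple[np.ndarray, np.ndarray]:
        tt = np.arange(0.0, t_end, 1.0 / fs)
        k = np.searchsorted(seg_t, tt, side="right") - 1
        k = np.clip(k, 0, seg_t.size - 1)
        ph = (seg_phi[k] + seg_rate[k] * (tt - seg_t[k])) % TWO_PI
        return ph, seg_pause[k]

    ph_raw, pause_raw = phase_on_grid(spec.fs_raw)
    values = -np.cos(ph_raw)
    values[pause_raw] = -1.0
    values += spec.noise_sd * rng.standard_normal(values.size)
    trace = RespTrace(values, spec.fs_raw, stage="raw", participant_id=participant)

    ph_true, pause_true = phase_on_grid(100.0)
    ph_true[pause_true] = np.nan
    true_phase = PhaseSeries(ph_true, 100.0)

    # assemble clean ground-truth cycles: onset -> peak -> end, no reset inside
    cyc_rows = []
    onset = peak = None
    for tt, kind in landmarks:
        if kind == "onset":
            onset, peak = tt, None
        elif kind == "peak":
            peak = tt if onset is not None else None
        elif kind == "end":
            if onset is not None and peak is not None:
                cyc_rows.append((participant, onset, peak, tt))
            onset = peak = None
        elif kind == "reset":
            onset = peak = None
    true_cycles = pd.DataFrame(
        cyc_rows, columns=["participant_id", "t_inhale_on_s", "t_peak_s",
                           "t_exhale_end_s"])
    return trace, true_phase, true_cycles


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_behaviour(spec: SessionSpec, true_phase: PhaseSeries,
                       trials: pd.DataFrame, participant: int) -> pd.DataFrame:
    """Add phase-coupled reaction times and accuracy to a trial table.

    sqrt(RT) receives ``beta_s*sin(phi) + beta_c*cos(phi)`` on top of the
    provisional draw made by :func:`generate_trial_sequence`, where phi is
    the ground-truth phase at (reference event + lag).  With a
    response-referenced lag the coupling time depends on the RT itself, so
    phi is evaluated at (stimulus + provisional RT + lag) and refined by one
    fixed-point iteration; for realistic coupling amplitudes the second pass
    moves phi by far less than one phase bin.  Accuracy is Bernoulli with a
    logistic link using the same phase.  Trials whose coupling phase is
    undefined keep the uncoupled behaviour; if that happens for more than
    half the trials the trace is unusable and a ValueError is raised.
    """
    out = trials.copy()
    rng = _rng(spec, participant, _S_BEHAV)
    n = len(out)
    bs, bc = spec.coupling_amplitude_rt
    as_, ac_ = spec.coupling_amplitude_acc
    lvl_c = out["stim_level"].to_numpy() - (spec.n_stim_levels + 1) / 2.0
    sqrt0 = out["sqrt_rt0"].to_numpy()
    stim = out["t_stimulus_s"].to_numpy()

    def rt_term(ph: np.ndarray) -> np.ndarray:
        term = bs * np.sin(ph) + bc * np.cos(ph)
        return np.where(np.isfinite(term), term, 0.0)

    if spec.coupling_reference == "stimulus":
        phi = true_phase.phase_at(stim + spec.coupling_lag)
        sqrt_rt = np.maximum(sqrt0 + rt_term(phi), 0.1)
    else:
        rt_prov = sqrt0 ** 2
        phi = true_phase.phase_at(stim + rt_prov + spec.coupling_lag)
        rt1 = np.maximum(sqrt0 + rt_term(phi), 0.1) ** 2
        phi = true_phase.phase_at(stim + rt1 + spec.coupling_lag)
        sqrt_rt = np.maximum(sqrt0 + rt_term(phi), 0.1)

    undef = ~np.isfinite(phi)
    if undef.mean() > 0.5:
        raise ValueError(
            f"coupling phase undefined for {undef.mean():.0%} of trials; "
            "trace too short or too many unclassified samples")

    rt = sqrt_rt ** 2
    out["rt_s"] = rt
    out["t_response_s"] = stim + rt

    eta = spec.acc_intercept + spec.acc_level_beta * lvl_c
    phase_eta = as_ * np.sin(phi) + ac_ * np.cos(phi)
    eta = eta + np.where(np.isfinite(phase_eta), phase_eta, 0.0)
    out["correct"] = (rng.uniform(size=n) < _sigmoid(eta)).astype(int)
    out["wrong_button"] = rng.uniform(size=n) < spec.wrong_button_prob
    out["phi_true"] = phi
    return out


def generate_session(spec: SessionSpec) -> SyntheticSession:
    """Generate the full cohort: traces, trials, behaviour and ground truth."""
    traces: dict[int, RespTrace] = {}
    phases: dict[int, PhaseSeries] = {}
    frames = []
    truth_sub = {}
    for pid in range(spec.n_participants):
        seq = generate_trial_sequence(spec, pid)
        trace, true_phase, true_cycles = generate_resp_trace(spec, seq, pid)
        trials = generate_behaviour(spec, true_phase, seq, pid)
        traces[pid] = trace
        phases[pid] = true_phase
        frames.append(trials)
        sub = _subject_params(spec, pid)
        sub["true_cycles"] = true_cycles
        truth_sub[pid] = sub
    trials = pd.concat(frames, ignore_index=True)
    truth = {
        "entrainment_strength": spec.entrainment_strength,
        "entrainment_target_phase": spec.entrainment_target_phase,
        "coupling_amplitude_rt": list(spec.coupling_amplitude_rt),
        "coupling_amplitude_acc": list(spec.coupling_amplitude_acc),
        "coupling_lag": spec.coupling_lag,
        "coupling_reference": spec.coupling_reference,
        "participants": truth_sub,
    }
    return SyntheticSession(spec=spec, traces=traces, true_phase=phases,
                            trials=trials, truth=truth)


TRIAL_COLUMNS = ["participant_id", "trial_nr", "t_fixation_s", "t_stimulus_s",
                 "t_response_s", "stim_level", "correct", "rt_s"]


def write_session(session: SyntheticSession, outdir: str | Path) -> None:
    """Write traces (CSV per participant), the trial table (TSV) and the
    ground truth (JSON) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, trace in session.traces.items():
        df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
        df.to_csv(outdir / f"resp_p{pid:03d}.csv", index=False, float_format="%.6f")
        meta = {"sampling_rate_hz": trace.fs, "participant_id": pid}
        (outdir / f"resp_p{pid:03d}.json").write_text(json.dumps(meta))
    session.trials[TRIAL_COLUMNS].to_csv(outdir / "trials.tsv", sep="\t",
                                         index=False, float_format="%.6f")
    truth = {k: v for k, v in session.truth.items() if k != "participants"}
    truth["participants"] = {
        str(pid): {k: v for k, v in sub.items() if k != "true_cycles"}
        for pid, sub in session.truth["participants"].items()
    }
    truth["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(session.spec).items()}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_session(indir: str | Path) -> tuple[dict[int, RespTrace], pd.DataFrame]:
    """Read traces and trials previously written by :func:`write_session`."""
    indir = Path(indir)
    traces = {}
    for meta_path in sorted(indir.glob("resp_p*.json")):
        meta = json.loads(meta_path.read_text())
        pid = int(meta["participant_id"])
        df = pd.read_csv(meta_path.with_suffix(".csv"))
        traces[pid] = RespTrace(df["value"].to_numpy(),
                                float(meta["sampling_rate_hz"]),
                                t0=float(df["time_s"].iloc[0]),
                                stage="raw", participant_id=pid)
    trials = pd.read_csv(indir / "trials.tsv", sep="\t")
    return traces, trials
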