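"""Shared synthetic fixtures.

Everything is generated programmatically; expensive cohorts are session
scoped so several test modules can share them.
"""
from __future__ import annotations

import numpy as np
import pytest

import respco as rc


def make_cosine_trace(cycles, fs=100.0, amp=1.4, pad_s=2.0):
    """Piecewise raised-cosine trace from (inhale_s, exhale_s[, amp]) tuples.

    Returns (RespTrace at ``fs`` in z-like units, list of ground-truth
    (onset, peak, end) times).  The trace starts after ``pad_s`` seconds of
    silence-free continuation (a half-amplitude lead-in keeps the Hilbert
    edge away from the first cycle).
    """
    t_step = 1.0 / fs
    seg = [np.full(int(pad_s * fs), -amp)]
    truth = []
    t = pad_s
    for cyc in cycles:
        t_in, t_ex = cyc[0], cyc[1]
        a = cyc[2] if len(cyc) > 2 else amp
        n_in = int(round(t_in * fs))
        n_ex = int(round(t_ex * fs))
        phi_in = np.pi * np.arange(n_in) / n_in
        phi_ex = np.pi + np.pi * np.arange(n_ex) / n_ex
        seg.append(-a * np.cos(np.concatenate([phi_in, phi_ex])))
        truth.append((t, t + t_in, t + t_in + t_ex))
        t += t_in + t_ex
    seg.append(np.full(int(pad_s * fs), -amp))
    samples = np.concatenate(seg)
    return rc.RespTrace(samples, fs, stage="zscored"), truth


@pytest.fixture(scope="session")
def clean_session():
    """One participant, no entrainment, no noise, no pauses: the timing
    oracle configuration."""
    spec = rc.SessionSpec(n_participants=1, n_trials=40, seed=2,
                          entrainment_strength=0.0, noise_sd=0.0,
                          pause_prob=0.0)
    return rc.generate_session(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort (entrainment + coupling) used by several
    integration tests."""
    spec = rc.SessionSpec(n_participants=6, n_trials=120, seed=7)
    return rc.generate_session(spec)


@pytest.fixture(scope="session")
def small_cohort_processed(small_cohort):
    phase_by, cycles_by = {}, {}
    for pid, raw in small_cohort.traces.items():
        _, cycles, phase = rc.process_trace(raw)
        phase_by[pid] = phase
        cycles_by[pid] = cycles
    return small_cohort, phase_by, cycles_by


@pytest.fixture(scope="session")
def null_cohort():
    """No entrainment, no coupling: the null-calibration configuration."""
    spec = rc.SessionSpec(n_participants=6, n_trials=100, seed=31,
                          entrainment_strength=0.0,
                          coupling_amplitude_rt=(0.0, 0.0),
                          coupling_amplitude_acc=(0.0, 0.0))
    return rc.generate_session(spec)


@pytest.fixture(scope="session")
def null_cohort_processed(null_cohort):
    phase_by = {pid: rc.process_trace(tr)[2]
                for pid, tr in null_cohort.traces.items()}
    return null_cohort, phase_by
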