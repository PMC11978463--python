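"""Respiratory trace preprocessing: filtering, cycle detection and phase assignment.

A raw single-channel respiration signal is band-limited (third-order
Butterworth, 0.03 Hz high-pass and 6 Hz low-pass, both applied
forward-backward so the filtering is zero-phase), resampled to 100 Hz and
z-scored.  Individual respiratory cycles are then detected from the phase of
the analytic (Hilbert) signal, split into an inhalation (positive-slope run
ending at the peak) and an exhalation (negative-slope run following the
peak), with brief slope interruptions (< 500 ms) bridged.  Atypical cycles
are rejected by their mean-squared distance from the participant's centroid
cycle shape.  Finally every sample is assigned a respiratory phase that runs
linearly from 0 to pi over the inhalation and from pi to 2*pi over the
exhalation; samples outside classified cycles (pauses, rejected cycles,
gaps) carry an undefined phase, encoded as NaN.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "RespTrace",
    "RespCycle",
    "PhaseSeries",
    "preprocess_trace",
    "detect_cycles",
    "segment_cycle",
    "segment_cycles",
    "exclude_atypical_cycles",
    "compute_phase_series",
    "process_trace",
]

#: filters of the standard pipeline
HIGHPASS_HZ = 0.03
LOWPASS_HZ = 6.0
FILTER_ORDER = 3
TARGET_FS = 100.0
#: peaks below this z-value are discarded
PEAK_Z_THRESHOLD = 0.5
#: half-width of the window used to delineate one cycle around its peak
CYCLE_WINDOW_S = 3.5
#: slope interruptions shorter than this are bridged
BRIDGE_S = 0.5
#: |slope| below this (z-units per second) counts as flat; typical mid-inhale
#: slopes are 1.5-3 z/s, while residual drift of the band-passed signal in a
#: breathing pause stays an order of magnitude below this bound
FLAT_SLOPE = 0.05
#: the slope estimate is averaged over this window; a boxcar preserves
#: locally linear slopes, so threshold crossings are not biased
SLOPE_SMOOTH_S = 0.11
#: half-width of the local-maximum refinement around an analytic-phase peak
PEAK_REFINE_S = 0.4


@dataclass
class RespTrace:
    """A continuous single-channel respiratory signal."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    stage: str = "raw"
    participant_id: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class RespCycle:
    """One detected respiratory cycle (times in seconds)."""

    inhale_onset: float
    peak: float
    exhale_end: float
    valid: bool = True
    truncated: bool = False
    unclassified_intervals: list = field(default_factory=list)
    distance_to_centroid: float = float("nan")

    @property
    def inhale_duration(self) -> float:
        return self.peak - self.inhale_onset

    @property
    def exhale_duration(self) -> float:
        return self.exhale_end - self.peak

    @property
    def duration(self) -> float:
        return self.exhale_end - self.inhale_onset


@dataclass
class PhaseSeries:
    """Per-sample respiratory phase in [0, 2*pi); NaN marks undefined samples.

    Within an inhalation the phase increases linearly in time from 0 to pi,
    within an exhalation from pi to 2*pi, so the three anchors (0, pi, 2*pi)
    have the same interpretation regardless of cycle shape.
    """

    phase: np.ndarray
    fs: float
    t0: float = 0.0
    cycle_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)

    @property
    def duration(self) -> float:
        return self.phase.size / self.fs

    def phase_at(self, times) -> np.ndarray:
        """Phase at arbitrary times by nearest-sample lookup.

        Times outside the series (or NaN) return NaN.  At 100 Hz the
        nearest-sample error is at most 5 ms, about half a degree for a
        typical 3.6 s cycle.
        """
        t = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.full(t.shape, np.nan)
        ok = np.isfinite(t)
        idx = np.round((t[ok] - self.t0) * self.fs).astype(int)
        inside = (idx >= 0) & (idx < self.phase.size)
        vals = np.full(idx.shape, np.nan)
        vals[inside] = self.phase[idx[inside]]
        out[ok] = vals
        return out if np.ndim(times) else float(out[0])

    def defined_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.phase)))


def preprocess_trace(raw: RespTrace, target_fs: float = TARGET_FS) -> RespTrace:
    """Band-limit, resample to ``target_fs`` and z-score a raw trace.

    Both Butterworth filters are applied with :func:`scipy.signal.sosfiltfilt`
    (forward-backward), i.e. zero-phase: cycle timing is what the downstream
    analysis measures, so the filters must not introduce group delay.

    Raises
    ------
    ValueError
        If the sampling rate cannot support the 6 Hz low-pass (fs < 50 Hz)
        or the trace is shorter than 30 s.
    """
    if raw.fs < 50.0:
        raise ValueError(f"sampling rate {raw.fs} Hz too low; need >= 50 Hz")
    if raw.duration < 30.0:
        raise ValueError(f"trace of {raw.duration:.1f} s too short; need >= 30 s")

    x = raw.samples.astype(float)
    sos_hp = sps.butter(FILTER_ORDER, HIGHPASS_HZ, "highpass", fs=raw.fs, output="sos")
    sos_lp = sps.butter(FILTER_ORDER, LOWPASS_HZ, "lowpass", fs=raw.fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, x)
    x = sps.sosfiltfilt(sos_lp, x)

    if raw.fs != target_fs:
        frac = Fraction(target_fs / raw.fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)

    sd = float(np.std(x))
    if sd < 1e-12:
        warnings.warn("degenerate (constant) trace: z-scoring skipped", RuntimeWarning)
        z = x - np.mean(x)
    else:
        z = (x - np.mean(x)) / sd
    return RespTrace(z, target_fs, t0=raw.t0, stage="zscored",
                     participant_id=raw.participant_id)


def detect_cycles(trace: RespTrace) -> list[tuple[float, bool]]:
    """Candidate peak times from the analytic-signal phase.

    The phase of the Hilbert analytic signal crosses 0 at local maxima of a
    band-limited signal; each upward zero crossing is refined to the local
    maximum of the trace within ``PEAK_REFINE_S`` (the analytic phase of an
    asymmetric cycle crosses zero a few tens of milliseconds away from the
    actual maximum).  Peaks where the z-scored trace does not exceed
    ``PEAK_Z_THRESHOLD`` are discarded.  Peaks whose 7 s delineation window
    extends past the trace boundary are kept but flagged truncated.

    Returns a list of ``(peak_time_s, truncated)`` tuples; may be empty.
    """
    x = trace.samples
    if x.size < 4 or np.all(x == 0):
        return []
    ph = np.angle(sps.hilbert(x))
    d = np.diff(ph)
    cross = np.nonzero((ph[:-1] < 0) & (ph[1:] >= 0) & (d < np.pi))[0]
    half = int(round(PEAK_REFINE_S * trace.fs))
    out = []
    seen = set()
    for i in cross:
        frac = -ph[i] / (ph[i + 1] - ph[i])
        idx = i + int(round(frac))
        lo, hi = max(0, idx - half), min(x.size, idx + half + 1)
        idx = lo + int(np.argmax(x[lo:hi]))
        if idx in seen:
            continue
        seen.add(idx)
        if x[idx] <= PEAK_Z_THRESHOLD:
            continue
        t = trace.t0 + idx / trace.fs
        truncated = (t - CYCLE_WINDOW_S < trace.t0) or (
            t + CYCLE_WINDOW_S > trace.t0 + trace.duration
        )
        out.append((float(t), bool(truncated)))
    return out


def _slope_sign(trace: RespTrace) -> np.ndarray:
    """Sample-wise slope class: +1 rising, -1 falling, 0 flat.

    Rising/falling follows the sign of the raw central-difference slope (so
    segment boundaries are sample-accurate), while "flat" requires the
    slope magnitude averaged over ``SLOPE_SMOOTH_S`` to stay below
    ``FLAT_SLOPE``: a breathing pause is sustained near-zero slope, whereas
    a peak or trough is a sharp sign change whose windowed mean magnitude
    never drops that low.
    """
    slope = np.gradient(trace.samples) * trace.fs
    sgn = np.where(slope > 0, 1, -1).astype(np.int8)
    w = max(1, int(round(SLOPE_SMOOTH_S * trace.fs)) | 1)  # odd window
    smooth_mag = np.convolve(np.abs(slope), np.ones(w) / w, mode="same")
    sgn[smooth_mag < FLAT_SLOPE] = 0
    return sgn


def _smooth_slope(trace: RespTrace, window_s: float = 0.15) -> np.ndarray:
    """Slope averaged over ``window_s`` for boundary refinement.

    Near a peak or trough the slope is locally linear through zero, so the
    symmetric average leaves the zero crossing in place while averaging out
    the small ripple the 6 Hz low-pass leaves at curvature corners.
    """
    slope = np.gradient(trace.samples) * trace.fs
    w = max(1, int(round(window_s * trace.fs)) | 1)
    return np.convolve(slope, np.ones(w) / w, mode="same")


def _refine_extremum(smslope: np.ndarray, idx: int, kind: str, fs: float,
                     halfwin_s: float = 0.15) -> int:
    """Snap ``idx`` to the nearest smoothed-slope zero crossing.

    ``kind`` is 'trough' (- to + crossing: inhale onset / exhale end) or
    'peak' (+ to -).  Returns ``idx`` unchanged when no crossing lies within
    the window.
    """
    h = int(round(halfwin_s * fs))
    lo, hi = max(0, idx - h), min(smslope.size - 1, idx + h)
    seg = smslope[lo:hi + 1]
    if kind == "trough":
        cross = np.nonzero((seg[:-1] < 0) & (seg[1:] >= 0))[0]
    else:
        cross = np.nonzero((seg[:-1] > 0) & (seg[1:] <= 0))[0]
    if cross.size == 0:
        return idx
    cand = lo + cross
    j = int(cand[np.argmin(np.abs(cand - idx))])
    return j if abs(smslope[j]) <= abs(smslope[j + 1]) else j + 1


def _pause_adjacent(sgn: np.ndarray, idx: int, step: int, fs: float,
                    look_s: float = 0.25) -> bool:
    """Is the region just beyond ``idx`` (direction ``step``) mostly flat?"""
    n = int(round(look_s * fs))
    seg = sgn[idx + 1:idx + 1 + n] if step > 0 else sgn[max(0, idx - n):idx]
    return seg.size > 0 and float(np.mean(seg == 0)) > 0.5


def _walk(sgn: np.ndarray, start: int, step: int, want: int,
          bridge_n: int, lo: int, hi: int) -> int | None:
    """Index of the farthest ``want``-slope sample reachable from ``start``.

    Moves in direction ``step`` (+1/-1) bridging runs of non-``want`` slope
    shorter than ``bridge_n`` samples; stops at a longer interruption or at
    the index bounds [lo, hi].
    """
    last = None
    gap = 0
    i = start + step
    while lo <= i <= hi:
        if sgn[i] == want:
            last = i
            gap = 0
        else:
            gap += 1
            if gap >= bridge_n:
                break
        i += step
    return last


def segment_cycle(trace: RespTrace, peak_s: float, truncated: bool = False,
                  sgn: np.ndarray | None = None,
                  smslope: np.ndarray | None = None) -> RespCycle:
    """Delineate the inhalation/exhalation around one detected peak.

    The inhalation is the maximal continuous positive-slope run ending at
    the peak and the exhalation the maximal negative-slope run starting at
    it, each allowed to bridge interruptions shorter than 500 ms, searched
    within a 7 s window centred on the peak.  Slope is taken by central
    differences on the processed 100 Hz trace; |slope| < 1e-3 z/s counts as
    flat.  Flat pauses of 500 ms or more therefore terminate the exhalation
    and stay unclassified (undefined phase downstream).
    """
    if sgn is None:
        sgn = _slope_sign(trace)
    if smslope is None:
        smslope = _smooth_slope(trace)
    fs = trace.fs
    peak_idx = int(round((peak_s - trace.t0) * fs))
    peak_idx = min(max(peak_idx, 0), sgn.size - 1)
    bridge_n = int(round(BRIDGE_S * fs))
    half = int(round(CYCLE_WINDOW_S * fs))
    lo = max(0, peak_idx - half)
    hi = min(sgn.size - 1, peak_idx + half)

    on_idx = _walk(sgn, peak_idx, -1, +1, bridge_n, lo, hi)
    end_idx = _walk(sgn, peak_idx, +1, -1, bridge_n, lo, hi)

    if on_idx is None or end_idx is None:
        return RespCycle(peak_s - 1.0, peak_s, peak_s + 1.0, valid=False,
                         truncated=truncated)
    # refine clean extrema to the smoothed-slope zero crossing; boundaries
    # that border a flat pause keep the end of their slope run instead
    peak_idx = _refine_extremum(smslope, peak_idx, "peak", fs, halfwin_s=0.1)
    if not _pause_adjacent(sgn, on_idx, -1, fs):
        on_idx = _refine_extremum(smslope, on_idx, "trough", fs)
    if not _pause_adjacent(sgn, end_idx, +1, fs):
        end_idx = _refine_extremum(smslope, end_idx, "trough", fs)
    cyc = RespCycle(
        inhale_onset=trace.t0 + on_idx / fs,
        peak=trace.t0 + peak_idx / fs,
        exhale_end=trace.t0 + end_idx / fs,
        truncated=truncated,
    )
    min_run = 2.0 / fs
    if cyc.inhale_duration < min_run or cyc.exhale_duration < min_run:
        cyc.valid = False
    return cyc


def segment_cycles(trace: RespTrace, peaks: list[tuple[float, bool]]) -> list[RespCycle]:
    """Segment every detected peak, sharing one slope computation."""
    sgn = _slope_sign(trace)
    smslope = _smooth_slope(trace)
    return [segment_cycle(trace, t, truncated=tr, sgn=sgn, smslope=smslope)
            for t, tr in peaks]


def exclude_atypical_cycles(cycles: list[RespCycle], trace: RespTrace,
                            n_points: int = 100, n_sd: float = 3.0,
                            min_cycles: int = 5) -> list[RespCycle]:
    """Flag cycles whose shape is atypical for this participant.

    Every valid cycle's time course is linearly resampled to ``n_points``
    samples; the centroid is the pointwise mean across cycles and each
    cycle's distance is its mean squared deviation from the centroid.
    Cycles farther than ``mean + n_sd * SD`` of the distance distribution
    are marked invalid.  Skipped (with a warning) when fewer than
    ``min_cycles`` valid cycles are available.
    """
    valid = [c for c in cycles if c.valid]
    if len(valid) < min_cycles:
        warnings.warn(
            f"only {len(valid)} valid cycles; atypical-cycle exclusion skipped",
            RuntimeWarning,
        )
        return cycles
    tt = trace.times
    shapes = np.empty((len(valid), n_points))
    for i, c in enumerate(valid):
        grid = np.linspace(c.inhale_onset, c.exhale_end, n_points)
        shapes[i] = np.interp(grid, tt, trace.samples)
    centroid = shapes.mean(axis=0)
    dist = np.mean((shapes - centroid) ** 2, axis=1)
    thresh = dist.mean() + n_sd * dist.std(ddof=1)
    for c, d in zip(valid, dist):
        c.distance_to_centroid = float(d)
        if d > thresh:
            c.valid = False
    return cycles


def compute_phase_series(cycles: list[RespCycle], trace: RespTrace) -> PhaseSeries:
    """Linear-in-time phase per sample: 0..pi over inhalation, pi..2*pi over
    exhalation; NaN between cycles, inside unclassified intervals and inside
    invalid cycles."""
    n = trace.samples.size
    phase = np.full(n, np.nan)
    cyc_idx = np.full(n, -1, dtype=int)
    fs = trace.fs
    valid = sorted((c for c in cycles if c.valid), key=lambda c: c.inhale_onset)
    for k, c in enumerate(valid):
        end_eff = c.exhale_end
        if k + 1 < len(valid):
            end_eff = min(end_eff, valid[k + 1].inhale_onset)
        i0 = max(0, int(np.ceil((c.inhale_onset - trace.t0) * fs)))
        ip = int(np.ceil((c.peak - trace.t0) * fs))
        i1 = min(n, int(np.ceil((end_eff - trace.t0) * fs)))
        if ip > i0:
            t = trace.t0 + np.arange(i0, min(ip, n)) / fs
            phase[i0:min(ip, n)] = np.pi * (t - c.inhale_onset) / c.inhale_duration
            cyc_idx[i0:min(ip, n)] = k
        if i1 > ip >= 0:
            t = trace.t0 + np.arange(max(ip, 0), i1) / fs
            phase[max(ip, 0):i1] = np.pi + np.pi * (t - c.peak) / c.exhale_duration
            cyc_idx[max(ip, 0):i1] = k
        for (u0, u1) in c.unclassified_intervals:
            j0 = max(0, int(np.ceil((u0 - trace.t0) * fs)))
            j1 = min(n, int(np.ceil((u1 - trace.t0) * fs)))
            phase[j0:j1] = np.nan
            cyc_idx[j0:j1] = -1
    np.clip(phase, 0.0, 2 * np.pi - 1e-12, out=phase)
    return PhaseSeries(phase, fs, t0=trace.t0, cycle_index=cyc_idx)


def process_trace(raw: RespTrace):
    """Full preprocessing chain for one participant.

    Returns ``(trace, cycles, phase_series)`` where ``trace`` is the
    filtered/resampled/z-scored signal.
    """
    trace = preprocess_trace(raw)
    peaks = detect_cycles(trace)
    cycles = segment_cycles(trace, peaks)
    cycles = exclude_atypical_cycles(cycles, trace)
    phase = compute_phase_series(cycles, trace)
    return trace, cycles, phase
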