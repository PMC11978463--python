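"""Reporting: phase bins, breather split, between-participant analysis,
rate-PLV correlation, pipeline driver."""
import numpy as np
import pandas as pd
import pytest

import respco as rc
from respco import events as ev, locking as lk
from respco import reporting as rp


def _binned_frame(phi0=np.pi, G=8, n=240, amp=0.05, seed=0):
    """sqrt(RT) = 1 + amp*cos(phase - phi0) + noise."""
    rng = np.random.default_rng(seed)
    rows, phases = [], []
    for g in range(G):
        ph = rng.uniform(0, 2 * np.pi, n)
        srt = 1.0 + amp * np.cos(ph - phi0) + 0.03 * rng.standard_normal(n)
        rows.append(pd.DataFrame({
            "participant_id": g, "trial_nr": np.arange(1, n + 1),
            "stim_level": 3, "rt_s": srt ** 2,
            "correct": (rng.uniform(size=n) < 0.85).astype(int)}))
        phases.append(ph)
    return pd.concat(rows, ignore_index=True), np.concatenate(phases)


class TestPhaseBins:
    def test_cosine_modulation_traces_through_bins(self):
        """With sqrt(RT) ~ cos(phase - pi), the slowest bin contains pi and
        the fastest contains 0 (the generated minimum at phi0 + pi)."""
        df, ph = _binned_frame(phi0=np.pi)
        out = rp.phase_bin_summary(df, ph)
        slowest = out.loc[out["sqrt_rt_mean"].idxmax(), "bin_center_rad"]
        fastest = out.loc[out["sqrt_rt_mean"].idxmin(), "bin_center_rad"]
        assert abs(np.angle(np.exp(1j * (slowest - np.pi)))) < np.pi / 3 + 0.01
        assert abs(np.angle(np.exp(1j * fastest))) < np.pi / 3 + 0.01

    def test_normalised_values_average_to_zero(self):
        df, ph = _binned_frame(amp=0.0, seed=1)
        out = rp.phase_bin_summary(df, ph)
        assert abs(out["sqrt_rt_mean"].mean()) < 1e-12
        assert abs(out["frac_correct_mean"].mean()) < 1e-12

    def test_flat_behaviour_within_sem_of_zero(self):
        df, ph = _binned_frame(amp=0.0, G=12, seed=2)
        out = rp.phase_bin_summary(df, ph)
        z = out["sqrt_rt_mean"].abs() / out["sqrt_rt_sem"]
        assert (z < 3.5).all()

    def test_invariant_to_trial_order(self):
        df, ph = _binned_frame(seed=3)
        perm = np.random.default_rng(0).permutation(len(df))
        out1 = rp.phase_bin_summary(df, ph)
        out2 = rp.phase_bin_summary(df.iloc[perm].reset_index(drop=True),
                                    ph[perm])
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_cells_missing_not_zero(self):
        df, ph = _binned_frame(G=2, n=30, seed=4)
        ph[:] = 0.1                      # everything in bin 0
        out = rp.phase_bin_summary(df, ph)
        assert np.isnan(out.loc[3, "sqrt_rt_mean"])


def _split_cohort(seed=0, fast_amp=0.05, slow_amp=0.05):
    """Cohort with heterogeneous cycle durations and per-group coupling."""
    rng = np.random.default_rng(seed)
    G, n = 10, 200
    rows, phases, durs = [], [], {}
    for g in range(G):
        dur = 3.0 + 0.15 * g            # 3.0 .. 4.35 s
        durs[g] = [rc.RespCycle(0.0, dur * 0.45, dur)] * 10
        amp = fast_amp if g < G // 2 else slow_amp
        ph = rng.uniform(0, 2 * np.pi, n)
        srt = 1.0 + amp * np.sin(ph) + 0.05 * rng.standard_normal(n)
        rows.append(pd.DataFrame({
            "participant_id": g, "trial_nr": np.arange(1, n + 1),
            "stim_level": rng.integers(1, 6, n), "rt_s": srt ** 2,
            "correct": 1, "wrong_button": False}))
        phases.append(ph)
    trials = pd.concat(rows, ignore_index=True)
    ph = np.concatenate(phases)
    pm = ev.PhaseSampleMatrix("response", np.array([-2.1]), ph[:, None],
                              trials.index)
    return trials, durs, pm


class TestBreatherSplit:
    def test_homogeneous_coupling_both_groups_significant(self):
        trials, durs, pm = _split_cohort(fast_amp=0.06, slow_amp=0.06)
        res = rp.breather_split_analysis(trials, durs, pm)
        assert res.summed_daic_fast[0] > 9.2
        assert res.summed_daic_slow[0] > 9.2
        assert len(res.fast) == len(res.slow) == 5

    def test_fast_only_coupling_orders_groups(self):
        trials, durs, pm = _split_cohort(fast_amp=0.08, slow_amp=0.0)
        res = rp.breather_split_analysis(trials, durs, pm)
        assert res.summed_daic_fast[0] > res.summed_daic_slow[0]

    def test_odd_cohort_median_goes_slow(self):
        trials, durs, pm = _split_cohort()
        drop = trials["participant_id"] != 9
        durs9 = {k: v for k, v in durs.items() if k != 9}
        pm9 = ev.PhaseSampleMatrix("response", pm.lags,
                                   pm.phase[drop.to_numpy()],
                                   trials.index[drop])
        res = rp.breather_split_analysis(trials[drop].reset_index(drop=True),
                                         durs9,
                                         ev.PhaseSampleMatrix(
                                             "response", pm.lags,
                                             pm.phase[drop.to_numpy()],
                                             pd.RangeIndex(drop.sum())))
        # 9 participants: 4 fast, 5 slow (median participant is slow)
        assert len(res.fast) == 4 and len(res.slow) == 5

    def test_degenerate_split_flagged(self):
        trials, durs, pm = _split_cohort()
        same = {k: [rc.RespCycle(0.0, 1.6, 3.5)] * 5 for k in durs}
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = rp.breather_split_analysis(trials, same, pm)
        assert res.degenerate


class TestBetweenParticipant:
    def _cohort(self, coupled=True, seed=0, G=40):
        rng = np.random.default_rng(seed)
        rows, mp = [], []
        for g in range(G):
            mean_ph = rng.uniform(0, 2 * np.pi)
            good = np.cos(mean_ph) > 0      # entrained near phase 0
            rt = 0.8 + (0.0 if (good and coupled) else (0.25 if coupled else 0.0))
            rts = rt + 0.05 * rng.standard_normal(150)
            rows.append(pd.DataFrame({
                "participant_id": g, "rt_s": rts ** 2,
                "correct": (rng.uniform(size=150) < 0.85).astype(int)}))
            mp.append({"participant_id": g, "mean_phase": mean_ph})
        return pd.concat(rows, ignore_index=True), pd.DataFrame(mp)

    def test_phase_dependent_rt_detected(self):
        trials, mp = self._cohort(coupled=True)
        res = rp.between_participant_phase_analysis(trials, mp)
        assert res["median_rt"]["p"] < 0.01
        assert res["median_rt"]["t"] < 0    # inhale-onset group is faster

    def test_null_cohort_not_significant(self):
        ps = []
        for seed in range(8):
            trials, mp = self._cohort(coupled=False, seed=seed)
            res = rp.between_participant_phase_analysis(trials, mp)
            ps.append(res["median_rt"]["p"])
        assert np.mean(np.asarray(ps) < 0.05) <= 0.25

    def test_slow_participants_excluded(self):
        trials, mp = self._cohort()
        slow = trials["participant_id"] == 0
        trials.loc[slow, "rt_s"] = 5.3
        res = rp.between_participant_phase_analysis(trials, mp)
        assert 0 not in set(res["per_participant"]["participant_id"])


class TestRatePLV:
    def test_perfect_monotone_decreasing(self):
        dur = pd.Series([3.0, 3.2, 3.5, 3.9, 4.4])
        plv = pd.Series([0.9, 0.7, 0.5, 0.3, 0.1])
        res = rp.rate_plv_correlation(dur, plv, n_boot=50)
        assert res["r"] == pytest.approx(-1.0)

    def test_independent_pairs_small_r(self):
        rng = np.random.default_rng(2)
        rs = []
        for _ in range(20):
            dur = pd.Series(rng.normal(3.6, 0.4, 30))
            plv = pd.Series(rng.uniform(0.1, 0.5, 30))
            rs.append(rp.rate_plv_correlation(dur, plv, n_boot=10)["r"])
        assert abs(np.mean(rs)) < 0.12

    def test_entrained_cohort_anticorrelated(self, small_cohort_processed):
        """Fixed entrainment with heterogeneous cycle durations: slower
        breathers lock less tightly to the ~3 s trial rhythm (negative
        Spearman correlation, matching the qualitative field finding)."""
        sess, phase_by, cycles_by = small_cohort_processed
        dur = rp.mean_cycle_duration(cycles_by)
        mp = lk.participant_mean_phase(sess.trials, phase_by, "stimulus", 0.0)
        res = rp.rate_plv_correlation(
            dur, mp.set_index("participant_id")["plv"], n_boot=50)
        assert res["r"] < 0

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            rp.rate_plv_correlation(pd.Series([3.0, 3.5]),
                                    pd.Series([0.3, 0.2]))


class TestPipeline:
    def test_smoke_and_determinism(self, tmp_path):
        cfg = {"seed": 3, "n_participants": 5, "n_trials": 60,
               "n_surrogates": 100, "n_shuffles": 100, "max_lag": -2.4}
        r1 = rc.run_pipeline(cfg, tmp_path / "a")
        r2 = rc.run_pipeline(cfg, tmp_path / "b")
        for name in ("lag_scan.tsv", "plv_curves.tsv", "phase_bins.tsv",
                     "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
        assert np.isfinite(r1["shuffle"]["p"])
        assert r1["lag_scan_response"].lags.size == 9
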