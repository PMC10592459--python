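"""Epoch QC, bout extraction and inter-bout intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitchnav.config import AnalysisConfig
from pitchnav.segment import (
    Epoch,
    compute_speed,
    extract_bouts,
    extract_ibis,
    qc_epochs,
    supra_threshold_runs,
)


def make_epoch(speed, frame_rate=100.0, pitch=None, epoch_id=0):
    n = len(speed)
    t = np.arange(n) / frame_rate
    return Epoch(
        epoch_id=epoch_id,
        t=t,
        x=np.zeros(n),
        z=np.zeros(n),
        pitch=np.full(n, 10.0) if pitch is None else np.asarray(pitch, float),
        frame_rate=frame_rate,
        speed=np.asarray(speed, float),
    )


class TestComputeSpeed:
    def test_stationary_animal_has_zero_speed(self):
        speed = compute_speed(np.full(50, 3.0), np.full(50, -2.0), dt=0.01)
        assert np.all(speed == 0)

    def test_uniform_motion_at_166_hz(self):
        x = np.arange(20) * 1.0  # 1 mm per frame
        speed = compute_speed(x, np.zeros(20), dt=1 / 166)
        assert np.allclose(speed, 166.0)

    def test_single_frame_epoch_raises(self):
        with pytest.raises(ValueError):
            compute_speed(np.array([1.0]), np.array([1.0]), dt=0.01)

    def test_speed_argmax_matches_displacement_bump(self, rng):
        t = np.arange(200) * 0.01
        v = 20 * np.exp(-((t - 1.0) ** 2) / (2 * 0.06**2))
        x = np.cumsum(v) * 0.01
        speed = compute_speed(x, np.zeros_like(x), dt=0.01)
        assert abs(int(np.argmax(speed)) - 100) <= 1


class TestQcEpochs:
    def test_short_fast_epoch_rejected(self, config):
        ep = make_epoch(np.full(240, 20.0), frame_rate=100)  # 2.39 s
        kept, counts = qc_epochs([ep], config)
        assert kept == [] and counts["too_short"] == 1

    def test_long_slow_epoch_rejected(self, config):
        ep = make_epoch(np.full(1000, 3.0), frame_rate=100)  # 10 s, 3 mm/s
        kept, counts = qc_epochs([ep], config)
        assert kept == [] and counts["too_slow"] == 1

    def test_long_fast_epoch_retained(self, config):
        speed = np.full(300, 1.0)
        speed[150] = 20.0
        kept, _ = qc_epochs([make_epoch(speed, frame_rate=100)], config)
        assert len(kept) == 1


class TestExtractBouts:
    def test_single_bump_with_margins_yields_one_bout(self, config):
        speed = np.zeros(600)
        speed[150:201] = 10.0
        speed[175] = 12.0
        bouts = extract_bouts(make_epoch(speed), config)
        assert len(bouts) == 1
        assert bouts[0].peak_index == 175
        assert bouts[0].peak_speed == 12.0
        # at 100 Hz: 50 pre + 1 + 30 post frames
        assert len(bouts[0].speed) == 81 and bouts[0].i_peak == 50

    def test_bump_too_close_to_epoch_start_is_dropped(self, config):
        speed = np.zeros(600)
        speed[30:45] = 10.0  # peak 400 ms in < 500 ms margin
        assert extract_bouts(make_epoch(speed), config) == []

    def test_two_bumps_give_two_bouts_in_time_order(self, config):
        speed = np.zeros(800)
        speed[150:200] = 8.0
        speed[400:450] = 9.0
        bouts = extract_bouts(make_epoch(speed), config)
        assert [b.peak_index for b in bouts] == [150, 400]

    def test_peak_tie_broken_to_earliest_frame(self, config):
        speed = np.zeros(400)
        speed[150:160] = 7.0  # flat maximum
        bouts = extract_bouts(make_epoch(speed), config)
        assert bouts[0].peak_index == 150

    def test_peak_is_run_maximum_and_supra_threshold(self, small_analysis, config):
        # the peak is the maximum of its own supra-threshold run; the full
        # 800 ms window may legitimately contain a faster neighboring bout
        for rep in small_analysis.repeats:
            bc = rep.bouts
            assert np.all(bc.peak_speed > config.speed_threshold_mm_s)
            for b in bc:
                lo = b.i_peak - (b.peak_index - b.run[0])
                hi = b.i_peak + (b.run[1] - b.peak_index)
                assert b.peak_speed >= b.speed[lo : hi + 1].max() - 1e-12


class TestExtractIbis:
    def make_two_bout_epoch(self, gap_frames, pitch=None):
        speed = np.zeros(900)
        speed[150:201] = 10.0
        start2 = 200 + gap_frames
        speed[start2 : start2 + 51] = 11.0
        ep = make_epoch(speed, pitch=pitch)
        return ep, extract_bouts(ep, AnalysisConfig())

    def test_one_second_gap_gives_800ms_ibi(self, config):
        # last supra frame at t=2.00 s, next first supra at t=3.00 s
        ep, bouts = self.make_two_bout_epoch(gap_frames=100)
        ibis = extract_ibis(ep, bouts, config)
        assert len(ibis) == 1
        assert ibis["duration"].iloc[0] == pytest.approx(0.800)
        assert ibis["bout_frequency"].iloc[0] == pytest.approx(1.25)

    def test_150ms_gap_discarded_by_buffer(self, config):
        ep, bouts = self.make_two_bout_epoch(gap_frames=15)
        assert len(extract_ibis(ep, bouts, config)) == 0

    def test_constant_pitch_gives_that_ibi_pitch(self, config):
        ep, bouts = self.make_two_bout_epoch(gap_frames=100)
        ibis = extract_ibis(ep, bouts, config)
        assert ibis["ibi_pitch"].iloc[0] == pytest.approx(10.0)

    def test_fewer_ibis_than_bouts_minus_one(self, small_analysis):
        for rep in small_analysis.repeats:
            per_epoch = rep.features.groupby("epoch_id").size()
            ibi_per_epoch = rep.ibis.groupby("epoch_id").size()
            for eid, n_ibi in ibi_per_epoch.items():
                assert n_ibi <= per_epoch[eid] - 1


class TestOracleEquivalence:
    @staticmethod
    def brute_force_runs(speed, thr):
        runs, start = [], None
        for i, s in enumerate(speed):
            if s > thr and start is None:
                start = i
            elif s <= thr and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(speed) - 1))
        return runs

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=50))
    def test_runs_match_brute_force_scan(self, speed):
        speed = np.asarray(speed)
        assert supra_threshold_runs(speed, 5.0) == self.brute_force_runs(speed, 5.0)

    def test_bout_candidates_match_brute_force_on_random_epochs(self, config, rng):
        for _ in range(100):
            speed = rng.uniform(0, 10, size=rng.integers(2, 51))
            runs = self.brute_force_runs(speed, config.speed_threshold_mm_s)
            expected_peaks = [s + int(np.argmax(speed[s : e + 1])) for s, e in runs]
            got = [
                s + int(np.argmax(speed[s : e + 1]))
                for s, e in supra_threshold_runs(speed, config.speed_threshold_mm_s)
            ]
            assert got == expected_peaks


class TestDetectionOnGeneratedBouts:
    def test_recall_and_precision_against_ground_truth(self, small_dataset, small_analysis):
        """>= 99% of generated bouts (peak >= 10 mm/s) found, few spurious."""
        tol = 2 / 166.0  # two frames
        for rep, (trace, truth) in zip(small_analysis.repeats, small_dataset.repeats):
            det = np.sort(rep.bouts.t_peak)
            gen = truth["t_peak"].to_numpy()
            fast = truth[truth["peak_speed"] >= 10.0]["t_peak"].to_numpy()
            matched = np.abs(fast[:, None] - det[None, :]).min(axis=1) <= tol
            assert matched.mean() >= 0.99
            spurious = np.abs(det[:, None] - gen[None, :]).min(axis=1) > tol
            assert 1.0 - spurious.mean() >= 0.99
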