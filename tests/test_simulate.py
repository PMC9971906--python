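"""Simulator: motor paths, rendering, blinking, fixture battery."""

import json

import numpy as np
import pandas as pd
import pytest
import tifffile

from curtainkit import (AcquisitionConfig, DnaTether, MotorParams,
                        simulate_motor_path, render_stack, make_fixture_suite)
from curtainkit.simulate import _integrated_gaussian_stamp


def event_queue_oracle(params, duration, seed):
    """Independent event-queue reimplementation of the pause schedule.

    Draws the same exponential waiting times from the same generator
    stream the simulator uses, but builds the event list by explicit
    queue processing rather than the simulator's loop.
    """
    rng = np.random.default_rng(seed)
    if params.fixed_pauses is not None:
        return [(t0, t0 + d) for t0, d in params.fixed_pauses]
    if params.pause_rate <= 0:
        return []
    queue = []
    t = 0.0
    while t < duration:
        wait = rng.exponential(1.0 / params.pause_rate)
        start = t + wait
        if start >= duration:
            break
        dur = rng.exponential(params.pause_duration_mean)
        queue.append((start, start + dur))
        t = start + dur
    return queue


class TestAcquisitionConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            AcquisitionConfig(frame_interval=0.0)
        with pytest.raises(ValueError):
            AcquisitionConfig(exposure=3.0, frame_interval=2.0)
        with pytest.raises(ValueError):
            AcquisitionConfig(n_frames=0)
        with pytest.raises(ValueError):
            AcquisitionConfig(n_frames=100, flow_stop=(50, 200))

    def test_one_hour_is_1800_frames(self):
        acq = AcquisitionConfig.from_duration(3600.0, frame_interval=2.0)
        assert acq.n_frames == 1800


class TestSimulateMotorPath:
    def test_stationary_identity(self, acq_short, tether):
        params = MotorParams(initial_position_bp=5000.0)
        tr = simulate_motor_path(params, acq_short, tether, seed=0)
        assert np.all(tr.position_bp == 5000.0)
        assert tr.dissociation_time is None
        assert tr.pauses == []

    def test_exact_displacement(self, tether):
        # 10 bp/s for 100 s -> exactly 1000 bp
        acq = AcquisitionConfig(n_frames=51, frame_interval=2.0)
        params = MotorParams(initial_position_bp=1000.0, velocity_bp_s=10.0)
        tr = simulate_motor_path(params, acq, tether, seed=0)
        assert tr.position_bp[-1] - tr.position_bp[0] == pytest.approx(1000.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MotorParams(pause_rate=-1.0)

    def test_pause_schedule_matches_event_queue_oracle(self, tether):
        acq = AcquisitionConfig(n_frames=600)
        params = MotorParams(initial_position_bp=1000.0, velocity_bp_s=15.0,
                             pause_rate=0.002, pause_duration_mean=60.0)
        for seed in range(10):
            tr = simulate_motor_path(params, acq, tether, seed=seed)
            expected = event_queue_oracle(params, acq.duration, seed)
            expected = [(a, b) for a, b in expected if a < acq.duration]
            assert len(tr.pauses) == len(expected)
            for got, exp in zip(tr.pauses, expected):
                assert got[0] == pytest.approx(exp[0])
                assert got[1] == pytest.approx(min(exp[1], acq.duration))

    def test_single_fixed_pause_is_60s(self, acq_short, tether):
        params = MotorParams(initial_position_bp=1000.0, velocity_bp_s=10.0,
                             fixed_pauses=((100.0, 60.0),))
        tr = simulate_motor_path(params, acq_short, tether, seed=3)
        assert len(tr.pauses) == 1
        t0, t1 = tr.pauses[0]
        assert t1 - t0 == pytest.approx(60.0)
        # position flat during the pause
        times = acq_short.times
        inside = (times >= t0) & (times < t1)
        assert np.ptp(tr.position_bp[inside]) == pytest.approx(0.0)

    def test_path_clipped_to_tether(self, tether):
        acq = AcquisitionConfig(n_frames=400)
        params = MotorParams(initial_position_bp=47000.0, velocity_bp_s=50.0)
        tr = simulate_motor_path(params, acq, tether, seed=0)
        assert np.nanmax(tr.position_bp) <= tether.total_bp

    def test_dissociation_truncates(self, tether):
        acq = AcquisitionConfig(n_frames=500)
        params = MotorParams(initial_position_bp=1000.0, velocity_bp_s=10.0,
                             dissociation_rate=0.01)
        tr = simulate_motor_path(params, acq, tether, seed=4)
        assert tr.dissociation_time is not None
        assert not tr.bound[-1]
        assert np.isnan(tr.position_bp[~tr.bound]).all()

    def test_blinking_duty_cycle(self, tether):
        # long-run emitting fraction -> on/(on+off) within 3 SE
        acq = AcquisitionConfig(n_frames=12000)
        on, off = 0.3, 0.1
        params = MotorParams(blink_on_rate=on, blink_off_rate=off)
        tr = simulate_motor_path(params, acq, tether, seed=5)
        duty = tr.emitting.mean()
        expect = on / (on + off)
        se = np.sqrt(expect * (1 - expect) / acq.n_frames)
        # telegraph samples are autocorrelated; allow 3 SE with an
        # inflation factor for the effective sample size
        rho = np.exp(-(on + off) * acq.frame_interval)
        n_eff = acq.n_frames * (1 - rho) / (1 + rho)
        se_eff = np.sqrt(expect * (1 - expect) / n_eff)
        assert abs(duty - expect) < 3 * se_eff

    def test_pause_count_rate(self, tether):
        # empirical pause arrivals per motile second -> pause_rate (3 SE)
        acq = AcquisitionConfig(n_frames=900)
        rate = 0.003
        params = MotorParams(initial_position_bp=1000.0, velocity_bp_s=2.0,
                             pause_rate=rate, pause_duration_mean=10.0)
        counts, motile = 0, 0.0
        for seed in range(120):
            tr = simulate_motor_path(params, acq, tether, seed=seed)
            counts += len(tr.pauses)
            motile += acq.duration - sum(b - a for a, b in tr.pauses)
        est = counts / motile
        se = np.sqrt(counts) / motile
        assert abs(est - rate) < 3 * se

    def test_determinism(self, acq_short, tether):
        params = MotorParams(velocity_bp_s=12.0, pause_rate=0.01,
                             velocity_noise_sd=20.0, blink_off_rate=0.1,
                             blink_on_rate=0.4)
        a = simulate_motor_path(params, acq_short, tether, seed=7)
        b = simulate_motor_path(params, acq_short, tether, seed=7)
        assert np.array_equal(a.position_bp, b.position_bp, equal_nan=True)
        assert np.array_equal(a.emitting, b.emitting)


class TestRenderStack:
    def test_pure_noise_background(self):
        acq = AcquisitionConfig(n_frames=20, image_shape=(32, 32),
                                em_gain_noise=(100.0, 2.0))
        stacks, truth = render_stack([], [], acq, seed=0)
        mean = stacks[0].mean()
        n = stacks[0].size
        se = np.sqrt(100.0 + 4.0) / np.sqrt(n)
        assert abs(mean - 100.0) < 3 * se
        assert truth.empty

    def test_photon_conservation(self, tether):
        # noiseless single emitter: summed signal above background equals
        # the integrated amplitude to within grid truncation (0.5%)
        acq = AcquisitionConfig(n_frames=5, image_shape=(64, 128),
                                em_gain_noise=(100.0, 0.0))
        params = MotorParams(initial_position_bp=20000.0, amplitude_photons=2000.0)
        tr = simulate_motor_path(params, acq, tether, seed=0)
        stacks, _ = render_stack([tr], [tether], acq, seed=0, noise=False)
        for frame in stacks[0]:
            total = float(frame.sum()) - 100.0 * frame.size
            assert total == pytest.approx(2000.0, rel=0.005)

    def test_photon_conservation_oracle(self):
        # independent numerical summation of the analytic Gaussian
        sigma, amp = 1.1, 2000.0
        yy, xx = np.mgrid[0:31, 0:31]
        fine = 9
        sub = np.linspace(-0.5 + 0.5 / fine, 0.5 - 0.5 / fine, fine)
        total = 0.0
        for dy in sub:
            for dx in sub:
                g = np.exp(-((yy + dy - 15.2) ** 2 + (xx + dx - 14.7) ** 2)
                           / (2 * sigma ** 2))
                total += g.sum() / fine ** 2
        total *= amp / (2 * np.pi * sigma ** 2)
        stamp = _integrated_gaussian_stamp(15.2, 14.7, amp, sigma,
                                           np.arange(31), np.arange(31))
        assert stamp.sum() == pytest.approx(total, rel=1e-4)

    def test_1800_frames_in_one_hour(self, tether):
        acq = AcquisitionConfig.from_duration(3600.0, frame_interval=2.0,
                                              image_shape=(16, 16))
        stacks, _ = render_stack([], [tether], acq, seed=0, noise=False)
        assert stacks[0].shape[0] == 1800

    def test_out_of_frame_warns_and_clips(self):
        acq = AcquisitionConfig(n_frames=3, image_shape=(16, 16))
        tether = DnaTether(anchor_px=(8.0, 8.0), extension_px=100.0)
        params = MotorParams(initial_position_bp=40000.0)  # maps far outside
        tr = simulate_motor_path(params, acq, tether, seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            render_stack([tr], [tether], acq, seed=0, noise=False)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            MotorParams(amplitude_photons=-5.0)

    def test_flow_stop_recoil(self):
        acq = AcquisitionConfig(n_frames=30, image_shape=(32, 128),
                                flow_stop=(10, 20))
        tether = DnaTether(anchor_px=(16.0, 10.0))
        bound = MotorParams(initial_position_bp=20000.0)
        stuck = MotorParams(initial_position_bp=20000.0, tethered=False)
        trb = simulate_motor_path(bound, acq, tether, seed=0, molecule_id=0)
        trs = simulate_motor_path(stuck, acq, tether, seed=0, molecule_id=1)
        _, truth = render_stack([trb, trs], [tether, tether], acq, seed=0)
        b = truth[truth.molecule_id == 0].set_index("frame")
        s = truth[truth.molecule_id == 1].set_index("frame")
        # bound molecule drawn 80% of the way toward the anchor col
        col_flow = b.loc[5, "true_col_px"]
        col_stop = b.loc[15, "true_col_px"]
        d_flow = col_flow - 10.0
        assert col_stop - 10.0 == pytest.approx(0.2 * d_flow, rel=1e-6)
        assert s.loc[15, "true_col_px"] == pytest.approx(s.loc[5, "true_col_px"])

    def test_render_determinism(self, acq_short, tether, mover_track):
        a, _ = render_stack([mover_track], [tether], acq_short, seed=9)
        b, _ = render_stack([mover_track], [tether], acq_short, seed=9)
        assert np.array_equal(a[0], b[0])


@pytest.fixture(scope="module")
def suite(tmp_path_factory):
    return make_fixture_suite(tmp_path_factory.mktemp("suite"), seed=0)


class TestFixtureSuite:
    def test_battery_contents(self, suite):
        assert len(suite["names"]) >= 7
        truth = pd.read_csv(suite["paths"]["ground_truth"])
        for name in suite["names"]:
            assert (truth["fixture"] == name).any()

    def test_files_written(self, suite):
        stack = tifffile.imread(suite["paths"]["stack_ch0"])
        assert stack.ndim == 3
        cfg = json.loads(open(suite["paths"]["config"]).read())
        assert "acquisition" in cfg and "fixtures" in cfg

    def test_determinism_byte_identical(self, tmp_path):
        make_fixture_suite(tmp_path / "a", seed=42)
        make_fixture_suite(tmp_path / "b", seed=42)
        csv_a = (tmp_path / "a" / "ground_truth.csv").read_bytes()
        csv_b = (tmp_path / "b" / "ground_truth.csv").read_bytes()
        assert csv_a == csv_b
        tif_a = (tmp_path / "a" / "stack_ch0.tif").read_bytes()
        tif_b = (tmp_path / "b" / "stack_ch0.tif").read_bytes()
        assert tif_a == tif_b

    def test_pausing_mover_has_one_long_pause(self, suite):
        idx = suite["names"].index("pausing_mover")
        track = suite["tracks"][idx]
        oracle = event_queue_oracle(track.params, suite["acq"].duration, 0)
        assert [tuple(p) for p in track.pauses] == [
            (a, min(b, suite["acq"].duration)) for a, b in oracle]
        long_pauses = [p for p in track.pauses if p[1] - p[0] >= 30.0]
        assert len(long_pauses) == 1
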