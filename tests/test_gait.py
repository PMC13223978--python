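"""Walking detection, gait-cycle segmentation, normalization and metrics."""
import numpy as np
import pytest

from scigait import (GaitDetectionConfig, GaitMetrics, GaitScenario,
                     GaitSessionModel, NormalizedGaitCycle, ParameterError,
                     RawCycle, SignalChannel, WalkingInterval, cycle_metrics,
                     detect_walking, eligibility, gait_delta,
                     generate_gait_session, normalize_cycle,
                     representative_cycle, segment_cycles)
from scigait.gait import circular_diff_pct, circular_mean_pct


def channel(x, rate=1000.0, units="deg/s^2", axis="medio_lateral"):
    return SignalChannel(np.asarray(x, float), rate=rate, units=units, axis=axis)


def sin_channel(freq, seconds=20.0, rate=1000.0, amp=1.0):
    t = np.arange(int(seconds * rate)) / rate
    return channel(amp * np.sin(2 * np.pi * freq * t), rate=rate)


class TestDetectWalking:
    def test_pure_3hz_all_blocks_walking(self):
        ivs = detect_walking(sin_channel(3.0))
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (0.0, 20.0)
        assert ivs[0].dominant_frequency == pytest.approx(3.0, abs=0.2)

    def test_pure_1hz_not_walking(self):
        assert detect_walking(sin_channel(1.0)) == []

    def test_band_membership_is_closed(self):
        # frequencies chosen on exact FFT bins (0.2 Hz resolution at 5-s
        # blocks); the 4.0 Hz upper edge itself must count as walking
        assert len(detect_walking(sin_channel(2.6))) == 1
        assert len(detect_walking(sin_channel(4.0))) == 1
        assert detect_walking(sin_channel(2.4)) == []
        assert detect_walking(sin_channel(4.2)) == []

    def test_short_channel_returns_empty(self):
        assert detect_walking(sin_channel(3.0, seconds=2.0)) == []

    def test_dominant_frequency_within_fft_resolution(self):
        for f in (2.6, 3.3, 3.9):
            ivs = detect_walking(sin_channel(f, seconds=10.0))
            assert ivs and abs(ivs[0].dominant_frequency - f) <= 1.0 / 5.0

    def test_generator_bouts_recovered_blockwise(self):
        from scigait import prepare_gait_channels
        hits = total = 0
        for seed in range(3):
            sc = GaitScenario(seed=seed)
            rec, _ = generate_gait_session(sc)
            det, _ = prepare_gait_channels(rec)
            ivs = detect_walking(det)
            truth = sc.true_block_labels()
            pred = np.zeros_like(truth)
            for iv in ivs:
                pred[int(iv.start // 5):int(iv.end // 5)] = True
            hits += int((pred == truth).sum())
            total += truth.size
        assert hits / total >= 0.95


class TestEligibility:
    @pytest.mark.parametrize("score,n,expected", [
        (1, 0, False),    # complete paraplegia, nothing to analyse
        (8, 12, True),    # near-normal walking with plenty of cycles
        (4, 2, False),    # behaviourally eligible but too few cycles
        (3, 10, False),   # score must strictly exceed 3
        (3.5, 3, True),
    ])
    def test_gate(self, score, n, expected):
        assert eligibility(score, n) is expected


class TestSegmentCycles:
    def test_periodic_signal_peak_to_peak(self):
        t = np.arange(10_000) / 1000.0
        hip = channel(10 * np.sin(2 * np.pi * 1.0 * t), units="deg", axis="flexion")
        cfg = GaitDetectionConfig(cycles_per_session=20)
        cycles = segment_cycles(hip, [WalkingInterval(0.0, 10.0, 3.0)], cfg)
        assert len(cycles) == 9
        assert all(c.duration == pytest.approx(1.0, abs=0.005) for c in cycles)

    def test_flat_signal_has_no_cycles(self):
        hip = channel(np.zeros(10_000), units="deg", axis="flexion")
        assert segment_cycles(hip, [WalkingInterval(0.0, 10.0, 3.0)]) == []

    def test_first_n_cycles_retained_chronologically(self):
        t = np.arange(30_000) / 1000.0
        hip = channel(10 * np.sin(2 * np.pi * 1.0 * t), units="deg", axis="flexion")
        cycles = segment_cycles(hip, [WalkingInterval(0.0, 30.0, 3.0)])
        assert len(cycles) == 10
        starts = [c.start_time for c in cycles]
        assert starts == sorted(starts) and starts[0] < 1.0

    def test_out_of_bounds_durations_discarded(self):
        t = np.arange(10_000) / 1000.0
        hip = channel(10 * np.sin(2 * np.pi * 0.25 * t), units="deg", axis="flexion")
        # 4-s cycles exceed the 2-s upper duration bound
        assert segment_cycles(hip, [WalkingInterval(0.0, 10.0, 3.0)]) == []

    def test_generator_onsets_recovered_within_20ms(self):
        from scigait import prepare_gait_channels
        sc = GaitScenario(seed=9)
        rec, truth = generate_gait_session(sc)
        det, hips = prepare_gait_channels(rec)
        ivs = detect_walking(det)
        cycles = segment_cycles(hips["left"], ivs)
        true_starts = truth.cycles[truth.cycles.side == "left"].start_s.to_numpy()
        for c in cycles:
            assert np.min(np.abs(true_starts - c.start_time)) < 0.020


class TestNormalizeCycle:
    def test_linear_ramp(self):
        raw = RawCycle(np.linspace(0, 10, 501), rate=1000.0, start_time=0.0)
        nc = normalize_cycle(raw)
        np.testing.assert_allclose(nc.angles, 0.1 * np.arange(101), atol=1e-12)

    def test_exact_grid_coincidence_201_samples(self):
        x = np.random.default_rng(0).normal(size=201)
        nc = normalize_cycle(RawCycle(x, rate=1000.0, start_time=0.0))
        np.testing.assert_allclose(nc.angles, x[::2], atol=1e-12)

    def test_sinusoid_amplitude_within_half_percent(self):
        t = np.linspace(0, 1, 800)
        raw = RawCycle(20 * np.sin(2 * np.pi * t), rate=800.0, start_time=0.0)
        nc = normalize_cycle(raw)
        assert abs(nc.angles.max() - 20.0) / 20.0 < 0.005

    def test_too_short_cycle_rejected(self):
        with pytest.raises(ParameterError):
            normalize_cycle(RawCycle(np.zeros(3), rate=1000.0, start_time=0.0))

    def test_endpoints_equal_raw_endpoints(self):
        x = np.cos(np.linspace(0, 7, 137)) * 12
        nc = normalize_cycle(RawCycle(x, rate=1000.0, start_time=0.0))
        assert nc.angles[0] == pytest.approx(x[0])
        assert nc.angles[100] == pytest.approx(x[-1])


class TestCycleMetrics:
    def test_sinusoid_extrema_and_timing(self):
        pct = np.arange(101)
        nc = NormalizedGaitCycle(18 * np.sin(2 * np.pi * pct / 100.0))
        m = cycle_metrics(nc)
        assert m.max_angle == pytest.approx(18.0, abs=0.05)
        assert m.min_angle == pytest.approx(-18.0, abs=0.05)
        assert m.rom == pytest.approx(36.0, abs=0.1)
        assert m.pct_at_max == 25 and m.pct_at_min == 75

    def test_constant_cycle_tie_rule(self):
        m = cycle_metrics(NormalizedGaitCycle(np.full(101, 5.0)))
        assert (m.max_angle, m.min_angle, m.rom) == (5.0, 5.0, 0.0)
        assert m.pct_at_max == 0 and m.pct_at_min == 0

    def test_rom_non_negative_on_random_cycles(self, rng):
        for _ in range(50):
            m = cycle_metrics(NormalizedGaitCycle(rng.normal(size=101)))
            assert m.rom >= 0


class TestRepresentativeCycle:
    def test_identical_cycles_mean_equals_cycle_sem_zero(self):
        nc = NormalizedGaitCycle(np.sin(np.linspace(0, 2 * np.pi, 101)) * 15)
        rep = representative_cycle([nc] * 10)
        np.testing.assert_allclose(rep.mean, nc.angles)
        np.testing.assert_allclose(rep.sem, 0.0, atol=1e-12)
        assert rep.n_cycles == 10

    def test_two_constant_cycles_average(self):
        a = NormalizedGaitCycle(np.zeros(101))
        b = NormalizedGaitCycle(np.full(101, 10.0))
        rep = representative_cycle([a, b])
        np.testing.assert_allclose(rep.mean, 5.0)

    def test_metrics_averaged_not_reextracted(self):
        # two asynchronous sawtooth peaks: the mean curve's max is damped,
        # the averaged per-cycle max is not
        x1 = np.zeros(101); x1[30] = 20.0
        x2 = np.zeros(101); x2[60] = 20.0
        rep = representative_cycle([NormalizedGaitCycle(x1), NormalizedGaitCycle(x2)])
        assert rep.metrics.max_angle == pytest.approx(20.0)
        assert rep.mean.max() == pytest.approx(10.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            representative_cycle([])

    def test_timing_average_is_circular_at_wrap(self):
        cycles = [NormalizedGaitCycle(np.r_[20.0, np.linspace(-1, 0, 100)]),
                  NormalizedGaitCycle(np.r_[np.linspace(0, -1, 100), 20.0])]
        rep = representative_cycle(cycles)
        # per-cycle maxima at 0 % and 100 %: the mean must sit at the wrap,
        # not mid-cycle
        d = circular_diff_pct(rep.metrics.pct_at_max, 0.0)
        assert abs(d) <= 1.0


class TestGaitDelta:
    BASE = GaitMetrics(max_angle=25.0, min_angle=-15.0, rom=40.0,
                       pct_at_max=40.0, pct_at_min=85.0)

    def test_identity_all_zero(self):
        d = gait_delta(self.BASE, self.BASE)
        assert (d.d_max_pct, d.d_min_pct, d.d_rom_pct,
                d.d_pct_at_max, d.d_pct_at_min) == (0, 0, 0, 0, 0)

    def test_rom_reduction(self):
        post = GaitMetrics(25.0, -15.0, 32.0, 40.0, 85.0)
        assert gait_delta(post, self.BASE).d_rom_pct == pytest.approx(-20.0)

    def test_earlier_flexion_peak_negative_points(self):
        post = GaitMetrics(25.0, -15.0, 40.0, 30.0, 85.0)
        assert gait_delta(post, self.BASE).d_pct_at_max == pytest.approx(-10.0)

    def test_extension_relative_change_uses_magnitude(self):
        # a shallower extension (-15 -> -9.585) is a -36.1 % change
        post = GaitMetrics(25.0, -9.585, 34.585, 40.0, 85.0)
        assert gait_delta(post, self.BASE).d_min_pct == pytest.approx(-36.1)

    def test_zero_baseline_flagged_nan(self):
        base = GaitMetrics(0.0, -15.0, 15.0, 40.0, 85.0)
        assert np.isnan(gait_delta(self.BASE, base).d_max_pct)

    def test_timing_delta_wraps_shortest_arc(self):
        post = GaitMetrics(25.0, -15.0, 40.0, 99.0, 85.0)
        base = GaitMetrics(25.0, -15.0, 40.0, 1.0, 85.0)
        assert gait_delta(post, base).d_pct_at_max == pytest.approx(-2.0)


class TestCircularHelpers:
    def test_mean_of_wrap_cluster_stays_at_wrap(self):
        m = circular_mean_pct([0.0, 100.0, 0.0, 99.0])
        assert min(m, 100.0 - m) <= 1.0

    def test_mean_away_from_wrap_is_arithmetic(self):
        assert circular_mean_pct([44, 45, 46]) == pytest.approx(45.0, abs=1e-9)


class TestEndToEndRecovery:
    def test_prescribed_waveform_recovered(self):
        # in-memory end-to-end; the from-file variant lives in the
        # acceptance suite
        sc = GaitScenario(seed=21, pct_at_max=35.0, pct_at_min=80.0,
                          peak_flexion_deg=22.0, peak_extension_deg=-12.0)
        rec, truth = generate_gait_session(sc)
        res = GaitSessionModel(rec).fit()
        for side in ("left", "right"):
            m = res.metrics(side)
            t = truth.cycles[truth.cycles.side == side].iloc[0]
            assert abs(m.max_angle - t.max_angle) <= 0.5
            assert abs(m.min_angle - t.min_angle) <= 0.5
            assert abs(m.rom - t.rom) <= 1.0
            assert abs(circular_diff_pct(m.pct_at_max, t.pct_at_max)) <= 1.0
            assert abs(circular_diff_pct(m.pct_at_min, t.pct_at_min)) <= 1.0
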