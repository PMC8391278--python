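import numpy as np
import pytest

from coilquant import (
    Burst,
    EventParams,
    IntensityTrace,
    PeakParams,
    extract_events,
    find_peaks,
    intervals,
    reprocess,
    simulate_trace,
    summarize,
)
from coilquant.peaks import PeakSet


def _trace(values, fps=30.0):
    return IntensityTrace(values=np.asarray(values, float), fps=fps)


class TestExtractEvents:
    def test_constant_trace_has_no_events(self):
        assert extract_events(_trace(np.full(200, 2.0)), EventParams()) == []

    def test_rectangular_pulse_segmented_once(self):
        v = np.zeros(300)
        v[100:131] = 10.0
        events = extract_events(_trace(v), EventParams())
        assert len(events) == 1
        e = events[0]
        assert e.start_frame == 100
        assert abs(e.end_frame - 131) <= 1
        assert e.duration_s == pytest.approx((e.end_frame - 99) / 30.0)
        assert e.peak_intensity == 10.0

    def test_slow_rise_needs_lower_start_threshold(self):
        # second burst climbs only 2 points per frame: invisible at
        # threshold 3, recovered at 1.5
        v = np.zeros(400)
        v[100:110] = 10.0  # sharp burst
        v[200:205] = [2, 4, 6, 8, 10]  # slow riser
        v[205:210] = 10.0
        high = extract_events(_trace(v), EventParams(start_threshold=3.0))
        low = extract_events(_trace(v), EventParams(start_threshold=1.5))
        assert len(high) == 1
        assert len(low) == 2

    def test_event_open_at_last_frame_closes_there(self):
        v = np.zeros(100)
        v[95:] = 10.0
        events = extract_events(_trace(v), EventParams())
        assert len(events) == 1
        assert events[0].end_frame == 99

    def test_literal_end_threshold_honoured(self):
        v = np.zeros(200)
        v[50:80] = 10.0
        v[80:120] = 4.0  # tail above a literal end level of 3
        events = extract_events(
            _trace(v), EventParams(start_threshold=3.0, end_threshold=3.0)
        )
        assert len(events) == 1
        assert events[0].end_frame == 120

    def test_median_is_over_whole_recording(self):
        # baseline plateau at 2 dominates the recording, so the sentinel end
        # level is 2 and the event closes on return to the plateau
        v = np.full(200, 2.0)
        v[50:80] = 10.0
        events = extract_events(_trace(v), EventParams())
        assert len(events) == 1
        assert events[0].start_frame == 50
        assert events[0].end_frame == 80

    def test_min_duration_filter_drops_short_events(self):
        v = np.zeros(300)
        v[50:53] = 10.0
        v[150:200] = 10.0
        p = EventParams(min_duration_s=10 / 30.0)
        events = extract_events(_trace(v), p)
        assert len(events) == 1
        assert events[0].start_frame == 150

    def test_events_disjoint_ordered_in_bounds(self, rng):
        v = np.clip(rng.normal(0, 3, 1000), 0, None)
        events = extract_events(_trace(v), EventParams())
        for e in events:
            assert 0 <= e.start_frame <= e.end_frame < 1000
        for a, b in zip(events, events[1:]):
            assert b.start_frame > a.end_frame

    def test_count_monotone_in_start_threshold_noise_free(self):
        tr, _ = simulate_trace(
            1800,
            [Burst(100, 20, 4.0), Burst(400, 20, 8.0), Burst(800, 20, 2.0),
             Burst(1200, 30, 10.0), Burst(1600, 20, 6.0)],
            noise_sigma=0.0, shape="rect",
        )
        counts = [
            len(extract_events(tr, EventParams(start_threshold=s)))
            for s in (0.5, 1.5, 3.0, 5.0, 9.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestGroundTruthRecovery:
    def test_rect_bursts_recovered_under_low_noise(self):
        bursts = [Burst(200, 25, 10.0), Burst(700, 20, 10.0),
                  Burst(1200, 30, 10.0), Burst(2000, 22, 10.0),
                  Burst(2900, 25, 10.0)]
        tr, truth = simulate_trace(3600, bursts, noise_sigma=0.5, seed=5,
                                   shape="rect")
        # end level 1.5 = 3 sigma of the noise floor, well below the pulses
        events = extract_events(
            tr, EventParams(start_threshold=3.0, end_threshold=1.5)
        )
        assert len(events) == len(bursts)  # recall and precision both 1
        for e, b in zip(events, truth):
            assert abs(e.start_frame - b.start_frame) <= 2
            assert abs((e.end_frame - e.start_frame + 1) - b.duration_frames) <= 2
        gaps = intervals(events, tr.fps)
        for g, (b0, b1) in zip(gaps, zip(truth, truth[1:])):
            assert abs(g - (b1.start_frame - b0.end_frame) / tr.fps) <= 4 / tr.fps


class TestIntervals:
    def test_two_events_gap_in_seconds(self):
        v = np.zeros(500)
        v[90:101] = 10.0
        v[400:420] = 10.0
        events = extract_events(_trace(v, fps=30.0), EventParams())
        assert len(events) == 2
        gaps = intervals(events, 30.0)
        assert len(gaps) == 1
        assert gaps[0] == pytest.approx((400 - events[0].end_frame) / 30.0)

    @pytest.mark.parametrize("n_events", [0, 1])
    def test_zero_or_one_event_gives_empty_list(self, n_events):
        v = np.zeros(200)
        if n_events == 1:
            v[50:70] = 10.0
        events = extract_events(_trace(v), EventParams())
        assert len(events) == n_events
        assert intervals(events, 30.0) == []


class TestReprocess:
    def test_identical_params_idempotent(self, rng):
        v = np.clip(rng.normal(0, 3, 500), 0, None)
        tr = _trace(v)
        assert reprocess(tr, EventParams()) == extract_events(tr, EventParams())

    def test_lower_threshold_recovers_missed_burst(self):
        v = np.zeros(400)
        v[100:110] = 10.0
        v[200:205] = [2, 4, 6, 8, 10]
        v[205:210] = 10.0
        tr = _trace(v)
        first = extract_events(tr, EventParams(start_threshold=3.0))
        redone = reprocess(tr, EventParams(start_threshold=1.5))
        assert len(redone) == len(first) + 1

    def test_threshold_above_all_rises_gives_no_events(self):
        v = np.zeros(300)
        v[100:120] = 10.0
        assert reprocess(_trace(v), EventParams(start_threshold=99.0)) == []


class TestSummarize:
    def test_six_maxima_in_one_minute_is_frequency_six(self):
        tr = _trace(np.zeros(1800), fps=30.0)  # exactly one minute
        ps = PeakSet(maxima=[(i * 300, 5.0) for i in range(6)], minima=[],
                     params=PeakParams())
        s = summarize("roi_0", ps, [], tr)
        assert s.tc_frequency == pytest.approx(6.0)

    def test_no_activity_gives_zero_frequency_and_empty_fields(self):
        tr = _trace(np.zeros(900), fps=30.0)
        ps = PeakSet(maxima=[], minima=[], params=PeakParams())
        s = summarize("roi_0", ps, [], tr)
        assert s.tc_frequency == 0.0
        assert s.mean_intensity is None
        assert s.mean_duration_s is None
        assert s.mean_interval_s is None

    def test_mean_intensity_is_mean_of_maxima(self):
        tr = _trace(np.zeros(1800), fps=30.0)
        ps = PeakSet(maxima=[(100, 8.0), (500, 12.0)], minima=[],
                     params=PeakParams())
        s = summarize("roi_0", ps, [], tr)
        assert s.mean_intensity == pytest.approx(10.0)


class TestPipelineFrequencyMatchesSchedule:
    def test_peaks_per_minute_equal_scheduled_coils(self, small_dish,
                                                    dish_hough_config):
        from coilquant import EnhanceConfig, detect_rois, trace_all

        stack, truth = small_dish
        rois = detect_rois(stack, dish_hough_config)
        traces = trace_all(stack, rois, EnhanceConfig())
        for tr, bursts in zip(traces, truth["schedule"]):
            ps = find_peaks(tr, PeakParams())
            events = extract_events(tr, EventParams())
            s = summarize("x", ps, events, tr)
            assert len(ps.maxima) == len(bursts)
            assert s.tc_frequency == pytest.approx(
                len(bursts) / tr.duration_min
            )
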