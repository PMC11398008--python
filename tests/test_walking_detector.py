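import numpy as np
import pytest

from ankle_adl.errors import LengthError
from ankle_adl.signal_filters import derive_signals
from ankle_adl.synthetic_generator import (ActivityScript, ScriptEntry,
                                           simulate_recording)
from ankle_adl.types import ActivityLabel, ImuRecording, Segment, SegmentSet
from ankle_adl.walking_detector import (ActivityThreshold,
                                        candidate_walking_segments,
                                        compute_activity_threshold,
                                        detect_walking, merge_and_prune,
                                        remove_stationary_steps)

FS = 50.0


def make_static(values):
    n = len(values)
    acc = np.zeros((n, 3))
    acc[:, 2] = values
    return ImuRecording(sample_rate=FS, time=np.arange(n) / FS, acc=acc,
                        gyro=np.zeros((n, 3)))


class TestActivityThreshold:
    def test_mean_plus_thirty_sd_on_gaussian_static(self, cfg):
        """Threshold equals mean + 30*sd of the high-passed trace, checked
        against an independent two-pass moment computation."""
        rng = np.random.default_rng(5)
        rec = make_static(1.0 + rng.normal(0, 0.002, int(30 * FS)))
        thresh = compute_activity_threshold(rec, cfg)
        from ankle_adl.signal_filters import FilterSpec, zero_lag_filter
        hp = zero_lag_filter(rec.acc_role("vertical"),
                             FilterSpec("highpass", cfg.static_hp_cutoff), FS)
        mean = sum(hp) / hp.size
        var = sum((v - mean) ** 2 for v in hp) / (hp.size - 1)
        assert thresh.value == pytest.approx(mean + 30 * var ** 0.5, abs=1e-9)

    def test_constant_static_gives_near_zero(self, cfg):
        rec = make_static(np.full(int(10 * FS), 0.98))
        thresh = compute_activity_threshold(rec, cfg)
        assert abs(thresh.value) < 1e-6

    def test_too_short_recording(self, cfg):
        with pytest.raises(LengthError):
            compute_activity_threshold(make_static(np.zeros(100)), cfg)


def brute_force_candidates(a_bplow, value, cfg, fs):
    """Literal per-sample reading of the exceedance rule: runs of
    |signal| > threshold, gaps < candidate_gap_close bridged, runs
    shorter than min_walk_duration dropped."""
    above = np.abs(a_bplow) > value
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) / fs < cfg.candidate_gap_close:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(i0, i1) for i0, i1 in merged
            if (i1 - i0) / fs >= cfg.min_walk_duration]


class TestCandidateSegments:
    def run(self, sig, cfg, value=0.5):
        return candidate_walking_segments(
            sig, ActivityThreshold(value), cfg, FS)

    def test_short_run_discarded(self, cfg):
        sig = np.zeros(500)
        sig[100:115] = 1.0  # 0.3 s
        assert len(self.run(sig, cfg)) == 0

    def test_one_second_run_kept(self, cfg):
        sig = np.zeros(500)
        sig[100:150] = 1.0
        (seg,) = self.run(sig, cfg)
        assert seg.duration == pytest.approx(1.0, abs=1 / FS)

    def test_negative_excursions_count(self, cfg):
        sig = np.zeros(500)
        sig[100:150] = -1.0  # rectified comparison
        assert len(self.run(sig, cfg)) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_scan(self, cfg, seed):
        rng = np.random.default_rng(seed)
        sig = rng.normal(0, 1, 600)
        out = self.run(sig, cfg)
        oracle = brute_force_candidates(sig, 0.5, cfg, FS)
        got = [(round(s.start * FS), round(s.end * FS)) for s in out]
        assert got == [tuple(r) for r in oracle]


def brute_force_stationary(seg, a_bpwalk, cfg, fs):
    """Literal range rule: find local maxima, drop those below
    range/4, re-span over what remains."""
    i0, i1 = round(seg.start * fs), round(seg.end * fs)
    w = a_bpwalk[i0:i1]
    rng_acc = w.max() - w.min()
    dist = round(cfg.peak_min_distance * fs)
    from scipy.signal import find_peaks
    pk, _ = find_peaks(w, distance=dist)
    kept = [p for p in pk if w[p] >= rng_acc * cfg.stationary_peak_fraction]
    return [(i0 + p) / fs for p in kept]


class TestStationaryStepRemoval:
    def impact_signal(self, heights, spacing=0.6, n=1000):
        sig = np.zeros(n)
        times = []
        for k, h in enumerate(heights):
            i = int((1.0 + k * spacing) * FS)
            sig[i] = h
            times.append(i / FS)
        return sig, times

    def seg_over(self, n=1000):
        return SegmentSet(ActivityLabel.WALKING,
                          (Segment(0.0, n / FS, ActivityLabel.WALKING),))

    def test_small_middle_peak_removed(self, cfg):
        # range 1.6 (max 0.8 on the segment edge, min -0.8 in a trough)
        # -> cutoff 0.4; the 0.3 peak goes, outer peaks span the segment
        sig, times = self.impact_signal([0.7, 0.3, 0.75])
        sig[int(0.5 * FS)] = 0.8    # boundary sample, not a local max
        sig[int(2.6 * FS)] = -0.8   # trough
        seg_in = SegmentSet(ActivityLabel.WALKING,
                            (Segment(0.5, 3.0, ActivityLabel.WALKING),))
        out = remove_stationary_steps(seg_in, sig, cfg, FS)
        (seg,) = out
        assert seg.peaks == (times[0], times[2])
        assert seg.start == pytest.approx(times[0])

    def test_equal_peaks_all_kept(self, cfg):
        sig, times = self.impact_signal([0.5, 0.5, 0.5, 0.5])
        out = remove_stationary_steps(self.seg_over(), sig, cfg, FS)
        assert out.segments[0].peaks == pytest.approx(tuple(times))

    def test_segment_without_surviving_peaks_dropped(self, cfg):
        sig = np.zeros(500)
        sig[100] = -1.0  # only a trough; no local max above cutoff
        out = remove_stationary_steps(self.seg_over(500), sig, cfg, FS)
        assert len(out) == 0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_literal_rule_oracle(self, cfg, seed):
        rng = np.random.default_rng(1000 + seed)
        sig = rng.normal(0, 0.2, 800)
        big = rng.choice(800, 6, replace=False)
        sig[big] += rng.uniform(0.5, 2.0, 6)
        seg = Segment(0.0, 800 / FS, ActivityLabel.WALKING)
        out = remove_stationary_steps(
            SegmentSet(ActivityLabel.WALKING, (seg,)), sig, cfg, FS)
        oracle = brute_force_stationary(seg, sig, cfg, FS)
        got = list(out.segments[0].peaks) if len(out) else []
        assert got == pytest.approx(oracle)


class TestMergeAndPrune:
    def seg(self, a, b, npeaks=3):
        peaks = tuple(np.linspace(a + 0.1, b - 0.1, npeaks))
        return Segment(a, b, ActivityLabel.WALKING, peaks=peaks)

    def test_sub_second_gap_merges(self, cfg):
        out = merge_and_prune(SegmentSet(ActivityLabel.WALKING,
                                         (self.seg(0.0, 2.0),
                                          self.seg(2.5, 4.0))), cfg)
        assert [(s.start, s.end) for s in out] == [(0.0, 4.0)]
        assert len(out.segments[0].peaks) == 6

    def test_exact_one_second_gap_stays_split(self, cfg):
        out = merge_and_prune(SegmentSet(ActivityLabel.WALKING,
                                         (self.seg(0.0, 2.0),
                                          self.seg(3.0, 4.0))), cfg)
        assert len(out) == 2

    def test_single_peak_segment_removed(self, cfg):
        out = merge_and_prune(SegmentSet(ActivityLabel.WALKING,
                                         (self.seg(0.0, 2.0, npeaks=1),)), cfg)
        assert len(out) == 0

    @pytest.mark.parametrize("seed", range(100))
    def test_idempotent(self, cfg, seed):
        rng = np.random.default_rng(2000 + seed)
        cuts = np.sort(rng.uniform(0, 60, 12))
        segs = tuple(self.seg(a, b, npeaks=int(rng.integers(1, 5)))
                     for a, b in zip(cuts[::2], cuts[1::2]) if b - a > 0.3)
        once = merge_and_prune(SegmentSet(ActivityLabel.WALKING, segs), cfg)
        twice = merge_and_prune(once, cfg)
        assert [(s.start, s.end, s.peaks) for s in once] == \
            [(s.start, s.end, s.peaks) for s in twice]


class TestDetectWalking:
    def test_all_zero_recording_yields_nothing(self, cfg, static_rec):
        n = 1500
        rec = ImuRecording(sample_rate=FS, time=np.arange(n) / FS,
                           acc=np.zeros((n, 3)), gyro=np.zeros((n, 3)))
        assert len(detect_walking(rec, static_rec, cfg)) == 0

    def test_tug_yields_two_bouts(self, cfg, tug, static_rec):
        out = detect_walking(tug.recording, static_rec, cfg)
        assert len(out) == 2
        for det, truth in zip(out, tug.truth[ActivityLabel.WALKING]):
            assert det.start == pytest.approx(truth.start, abs=0.5)
            assert det.end == pytest.approx(truth.end, abs=0.5)

    def test_shuffling_alone_is_not_walking(self, cfg, static_rec):
        script = ActivityScript(entries=(
            ScriptEntry("Rest", 5.0),
            ScriptEntry("StationaryShuffle", 10.0),
            ScriptEntry("Rest", 5.0)))
        lr = simulate_recording(script)
        assert len(detect_walking(lr.recording, static_rec, cfg)) == 0

    def test_raising_threshold_never_adds_walking_time(self, cfg, tug,
                                                       static_rec):
        sig = derive_signals(tug.recording, cfg)
        base = compute_activity_threshold(static_rec, cfg)
        total = []
        for scale in (1.0, 2.0, 4.0, 8.0):
            segs = candidate_walking_segments(
                sig.a_bplow, ActivityThreshold(base.value * scale), cfg, FS)
            total.append(segs.total_duration)
        assert all(a >= b for a, b in zip(total, total[1:]))
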