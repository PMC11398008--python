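"""Walking detection from vertical (along-shank) acceleration.

The pipeline turns foot-impact transients into Walking segments in five
steps:

1. an *activity threshold* is calibrated from a static recording as
   ``mean + 30 * sd`` of the high-passed vertical acceleration;
2. candidate intervals are samples where the rectified narrow-band
   acceleration exceeds that threshold for at least 0.4 s (sub-threshold
   dips shorter than 1 s are bridged first);
3. per candidate, impact peaks of the wide-band acceleration below a
   quarter of the segment's wide-band range are discarded (stationary
   shuffling), and the segment is re-spanned over the retained peaks;
4. segments closer than 1 s are concatenated and segments left with a
   single impact peak are dropped;
5. boundaries are refined by snapping the first/last narrow-band peak of
   each segment to the nearest (sharper) wide-band impact peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import DetectionConfig
from .errors import LengthError
from .signal_filters import FilterSpec, FilteredSignals, derive_signals, zero_lag_filter
from .types import ActivityLabel, ImuRecording, Segment, SegmentSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivityThreshold:
    """The walking activity threshold, in g."""

    value: float


def threshold_statistic(values: np.ndarray, sd_multiplier: float) -> float:
    """``mean + sd_multiplier * sd`` with the sample (n-1) deviation."""
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)) + sd_multiplier * sd


def compute_activity_threshold(static_rec: ImuRecording,
                               cfg: DetectionConfig) -> ActivityThreshold:
    """Calibrate ``mean + sd_multiplier * sd`` from a static recording.

    The vertical-role acceleration is high-passed at
    ``cfg.static_hp_cutoff`` to strip gravity; the standard deviation is
    the sample (n-1) estimate.  The recording must be at least
    ``cfg.static_min_duration`` seconds so the filter transient is
    negligible relative to the estimate.
    """
    if static_rec.duration < cfg.static_min_duration:
        raise LengthError(
            f"static recording of {static_rec.duration:.2f} s is shorter than "
            f"the required {cfg.static_min_duration} s")
    hp = zero_lag_filter(static_rec.acc_role("vertical"),
                         FilterSpec("highpass", cfg.static_hp_cutoff),
                         static_rec.sample_rate)
    return ActivityThreshold(value=threshold_statistic(hp, cfg.sd_multiplier))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``mask`` is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def candidate_walking_segments(a_bplow: np.ndarray, thresh: ActivityThreshold,
                               cfg: DetectionConfig,
                               sample_rate: float) -> SegmentSet:
    """Threshold-exceedance intervals of the rectified narrow-band signal.

    Gaps shorter than ``cfg.candidate_gap_close`` between exceedance runs
    are bridged; bridged intervals shorter than ``cfg.min_walk_duration``
    are discarded.
    """
    mask = np.abs(np.asarray(a_bplow, dtype=float)) > thresh.value
    runs = _runs_above(mask)
    gap_samples = cfg.candidate_gap_close * sample_rate
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < gap_samples:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    min_samples = cfg.min_walk_duration * sample_rate
    segs = [Segment(i0 / sample_rate, i1 / sample_rate, ActivityLabel.WALKING)
            for i0, i1 in merged if i1 - i0 >= min_samples]
    return SegmentSet(ActivityLabel.WALKING, tuple(segs))


def _segment_bounds(seg: Segment, n: int, sample_rate: float) -> tuple[int, int]:
    i0 = max(0, int(round(seg.start * sample_rate)))
    i1 = min(n, int(round(seg.end * sample_rate)))
    return i0, i1


def remove_stationary_steps(segments: SegmentSet, a_bpwalk: np.ndarray,
                            cfg: DetectionConfig,
                            sample_rate: float) -> SegmentSet:
    """Drop small impact peaks and re-span segments over retained peaks.

    Within each segment the wide-band range ``max - min`` is computed;
    local maxima with height below ``range * cfg.stationary_peak_fraction``
    are deleted from the segment's peak list.  A segment keeping no peak is
    dropped; otherwise it is rebuilt to span its retained peaks (one extra
    sample at the end keeps the interval non-degenerate).
    """
    a_bpwalk = np.asarray(a_bpwalk, dtype=float)
    dt = 1.0 / sample_rate
    dist = max(1, int(round(cfg.peak_min_distance * sample_rate)))
    out: list[Segment] = []
    for seg in segments:
        i0, i1 = _segment_bounds(seg, a_bpwalk.size, sample_rate)
        window = a_bpwalk[i0:i1]
        if window.size < 3:
            continue
        rng = float(window.max() - window.min())
        pk, _ = find_peaks(window, distance=dist)
        keep = pk[window[pk] >= rng * cfg.stationary_peak_fraction]
        if keep.size == 0:
            continue
        times = tuple((i0 + keep) * dt)
        out.append(Segment(times[0], times[-1] + dt, ActivityLabel.WALKING,
                           peaks=times))
    return SegmentSet(ActivityLabel.WALKING, tuple(out))


def merge_and_prune(segments: SegmentSet, cfg: DetectionConfig) -> SegmentSet:
    """Concatenate segments closer than the merge gap, then drop segments
    with fewer than ``cfg.min_peaks_per_segment`` retained impact peaks."""
    merged: list[Segment] = []
    for seg in segments:
        if merged and seg.start - merged[-1].end < cfg.walk_merge_gap:
            prev = merged[-1]
            peaks = tuple(sorted((prev.peaks or ()) + (seg.peaks or ())))
            merged[-1] = Segment(prev.start, max(prev.end, seg.end),
                                 ActivityLabel.WALKING, peaks=peaks or None)
        else:
            merged.append(seg)
    kept = tuple(s for s in merged
                 if s.peaks is None or len(s.peaks) >= cfg.min_peaks_per_segment)
    return SegmentSet(ActivityLabel.WALKING, kept)


def refine_boundaries(segments: SegmentSet, a_bplow: np.ndarray,
                      a_bpwalk: np.ndarray, cfg: DetectionConfig,
                      sample_rate: float) -> SegmentSet:
    """Snap segment boundaries to wide-band impact peaks.

    The first and last narrow-band peaks of each segment are located and
    each is mapped to the nearest retained wide-band impact peak (the
    wide-band peaks are sharper in time).  Because stationary-step removal
    re-spans segments over their wide-band peaks, the narrow-band peak
    belonging to the first impact of the *initial* candidate interval may
    sit just outside the current span; the search window is therefore the
    segment extended by ``cfg.refine_max_shift`` on both sides.  When no
    impact peak lies within ``cfg.refine_max_shift`` s of a boundary peak,
    that boundary is kept.
    """
    a_bplow = np.asarray(a_bplow, dtype=float)
    dt = 1.0 / sample_rate
    dist = max(1, int(round(cfg.peak_min_distance * sample_rate)))
    low_pk, _ = find_peaks(a_bplow, distance=dist)
    low_times = low_pk * dt
    out: list[Segment] = []
    for seg in segments:
        inside = low_times[(low_times >= seg.start - cfg.refine_max_shift)
                           & (low_times < seg.end + cfg.refine_max_shift)]
        wide = np.asarray(seg.peaks) if seg.peaks else np.array([])
        start, end = seg.start, seg.end
        if inside.size and wide.size:
            first, last = inside[0], inside[-1]
            d0 = np.abs(wide - first)
            d1 = np.abs(wide - last)
            if d0.min() <= cfg.refine_max_shift:
                start = float(wide[d0.argmin()])
            else:
                log.info("no wide-band peak within %.2f s of segment start at "
                         "%.2f s; boundary kept", cfg.refine_max_shift, first)
            if d1.min() <= cfg.refine_max_shift:
                end = float(wide[d1.argmin()]) + dt
            else:
                log.info("no wide-band peak within %.2f s of segment end at "
                         "%.2f s; boundary kept", cfg.refine_max_shift, last)
        if end <= start:
            start, end = seg.start, seg.end
        out.append(Segment(start, end, ActivityLabel.WALKING, peaks=seg.peaks))
    return SegmentSet(ActivityLabel.WALKING, tuple(out))


def detect_walking(rec: ImuRecording, static_rec: ImuRecording,
                   cfg: DetectionConfig | None = None,
                   signals: FilteredSignals | None = None) -> SegmentSet:
    """Full walking pipeline: threshold, candidates, stationary-step
    removal, merge/prune, boundary refinement."""
    cfg = cfg or DetectionConfig()
    sig = signals if signals is not None else derive_signals(rec, cfg)
    thresh = compute_activity_threshold(static_rec, cfg)
    segs = candidate_walking_segments(sig.a_bplow, thresh, cfg, rec.sample_rate)
    segs = remove_stationary_steps(segs, sig.a_bpwalk, cfg, rec.sample_rate)
    segs = merge_and_prune(segs, cfg)
    return refine_boundaries(segs, sig.a_bplow, sig.a_bpwalk, cfg,
                             rec.sample_rate)
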