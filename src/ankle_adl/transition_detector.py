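"""Sit-to-stand / stand-to-sit detection via an RMS-quartile test.

Angular velocity of the shank around the medio-lateral axis rises when the
leg pitches during sitting down or standing up, and is quiet while seated.
For every non-walking gap that is long enough to contain a sitting bout,
the RMS of the 4 Hz low-passed medio-lateral angular velocity is computed
over the first 25%, the middle 50% and the last 25% of the gap.  A
Sitting-down event is declared when the leading-edge RMS exceeds the
middle RMS by a 33% margin; a Standing-up event symmetrically for the
trailing edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DetectionConfig
from .errors import WindowingError
from .signal_filters import FilteredSignals, derive_signals
from .types import ActivityLabel, ImuRecording, Segment, SegmentSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RmsProfile:
    """Edge/middle RMS values (rad/s) of one non-walking segment."""

    rms_f: float
    rms_m: float
    rms_l: float
    segment: Segment


def nonwalking_segments(walking: SegmentSet, duration: float,
                        cfg: DetectionConfig) -> SegmentSet:
    """Complement of the walking segments within ``[0, duration)``."""
    segs = []
    cursor = 0.0
    for w in walking:
        if w.start > cursor:
            segs.append(Segment(cursor, min(w.start, duration),
                                ActivityLabel.NON_WALKING))
        cursor = max(cursor, w.end)
    if cursor < duration:
        segs.append(Segment(cursor, duration, ActivityLabel.NON_WALKING))
    return SegmentSet(ActivityLabel.NON_WALKING, tuple(segs))


def is_testable(segment: Segment, cfg: DetectionConfig) -> bool:
    """Whether a non-walking segment is long enough for the RMS test:
    it must fit a minimum sitting bout plus two useful edge windows."""
    return segment.duration >= (cfg.min_sit_duration
                                + 2 * cfg.transition_edge_min)


def _window_indices(n: int, frac: float) -> tuple[int, int]:
    e = int(round(n * frac))
    return e, n - e


def rms_profile(g_mvt: np.ndarray, segment: Segment, cfg: DetectionConfig,
                sample_rate: float) -> RmsProfile:
    """RMS over the first/middle/last windows of ``segment``.

    Windows split the segment's samples at the 25% and 75% points
    (``cfg.transition_edge_fraction``); each must be non-empty.
    """
    g_mvt = np.asarray(g_mvt, dtype=float)
    i0 = max(0, int(round(segment.start * sample_rate)))
    i1 = min(g_mvt.size, int(round(segment.end * sample_rate)))
    n = i1 - i0
    if n < 4:
        raise WindowingError(
            f"segment [{segment.start}, {segment.end}) has {n} samples; "
            "at least 4 are needed for the RMS windows")
    e, m = _window_indices(n, cfg.transition_edge_fraction)
    if e < 1 or m <= e:
        raise WindowingError("degenerate RMS windows")
    w = g_mvt[i0:i1]
    rms = lambda v: float(np.sqrt(np.mean(v ** 2)))  # noqa: E731
    return RmsProfile(rms_f=rms(w[:e]), rms_m=rms(w[e:m]), rms_l=rms(w[m:]),
                      segment=segment)


def _edge_exceeds(rms_edge: float, rms_m: float, cfg: DetectionConfig) -> bool:
    if rms_edge <= cfg.transition_min_edge_rms:
        return False
    if cfg.rms_margin_reference == "middle":
        return rms_edge > (1.0 + cfg.transition_rms_factor) * rms_m
    # alternative reading: the margin referenced to the edge RMS itself
    return rms_edge - cfg.transition_rms_factor * rms_edge > rms_m


def _refine_burst(g_mvt: np.ndarray, win_lo: int, win_hi: int,
                  seg_lo: int, seg_hi: int, rel_height: float,
                  sample_rate: float) -> tuple[float, float]:
    """Bounds of the dominant burst inside a qualifying edge window.

    The maximum of ``|g_mvt|`` inside the window is located and the burst
    extends while the rectified trace stays above ``rel_height`` of that
    peak, clipped to the parent non-walking segment.
    """
    rect = np.abs(g_mvt)
    pk = win_lo + int(np.argmax(rect[win_lo:win_hi]))
    level = rel_height * rect[pk]
    lo = pk
    while lo > seg_lo and rect[lo - 1] >= level:
        lo -= 1
    hi = pk + 1
    while hi < seg_hi and rect[hi] >= level:
        hi += 1
    return lo / sample_rate, hi / sample_rate


def detect_transitions(rec: ImuRecording, walking: SegmentSet,
                       cfg: DetectionConfig | None = None,
                       signals: FilteredSignals | None = None,
                       ) -> tuple[SegmentSet, SegmentSet]:
    """Detect Sitting-down and Standing-up in the non-walking gaps.

    Returns ``(sitting_down, standing_up)`` segment sets.  Gaps failing the
    duration gate are skipped.  Emitted bounds follow
    ``cfg.transition_bounds``: the dominant-burst extent inside the
    qualifying edge window (``"refined"``, default) or the raw edge-window
    bounds (``"window"``).
    """
    cfg = cfg or DetectionConfig()
    sig = signals if signals is not None else derive_signals(rec, cfg)
    g_mvt = sig.g_mvt
    fs = rec.sample_rate
    duration = rec.n_samples / fs
    sits: list[Segment] = []
    stands: list[Segment] = []
    for seg in nonwalking_segments(walking, duration, cfg):
        if not is_testable(seg, cfg):
            log.info("non-walking segment [%.2f, %.2f) too short for the "
                     "transition test; skipped", seg.start, seg.end)
            continue
        prof = rms_profile(g_mvt, seg, cfg, fs)
        i0 = max(0, int(round(seg.start * fs)))
        i1 = min(g_mvt.size, int(round(seg.end * fs)))
        e, m = _window_indices(i1 - i0, cfg.transition_edge_fraction)
        if _edge_exceeds(prof.rms_f, prof.rms_m, cfg):
            if cfg.transition_bounds == "refined":
                lo, hi = _refine_burst(g_mvt, i0, i0 + e, i0, i1,
                                       cfg.transition_peak_rel_height, fs)
            else:
                lo, hi = i0 / fs, (i0 + e) / fs
            sits.append(Segment(lo, hi, ActivityLabel.SITTING_DOWN,
                                score=prof.rms_f))
        if _edge_exceeds(prof.rms_l, prof.rms_m, cfg):
            if cfg.transition_bounds == "refined":
                lo, hi = _refine_burst(g_mvt, i0 + m, i1, i0, i1,
                                       cfg.transition_peak_rel_height, fs)
            else:
                lo, hi = (i0 + m) / fs, i1 / fs
            stands.append(Segment(lo, hi, ActivityLabel.STANDING_UP,
                                  score=prof.rms_l))
    return (SegmentSet(ActivityLabel.SITTING_DOWN, tuple(sits)),
            SegmentSet(ActivityLabel.STANDING_UP, tuple(stands)))
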