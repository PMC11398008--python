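"""Turning detection from rectified low-passed vertical angular velocity.

A turn on the spot produces a single smooth burst on the vertical
gyroscope channel.  Candidate peaks of the rectified low-passed trace with
prominence >= 0.1 rad/s are collected; a candidate becomes a turning event
when its amplitude exceeds the mean amplitude of all candidates (global
mean over the trial) or its prominence reaches 0.8 rad/s outright.  Each
event spans the peak location plus/minus half the peak width, and
overlapping events are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .config import DetectionConfig
from .errors import ValidationError
from .signal_filters import FilteredSignals, derive_signals
from .types import ActivityLabel, ImuRecording, Segment, SegmentSet, merge_touching


@dataclass(frozen=True)
class TurnPeak:
    """A candidate turning peak on the rectified low-passed vertical gyro."""

    time: float
    amplitude: float
    prominence: float
    width: float

    def __post_init__(self) -> None:
        if not (self.amplitude >= self.prominence >= 0):
            raise ValidationError("need amplitude >= prominence >= 0")
        if self.width <= 0:
            raise ValidationError("peak width must be positive")


def find_turn_peaks(g_lp: np.ndarray, cfg: DetectionConfig,
                    sample_rate: float) -> list[TurnPeak]:
    """Two-stage peak selection on the rectified low-passed vertical gyro.

    Stage 1 finds all local maxima with prominence >=
    ``cfg.turn_prominence_min``; stage 2 keeps those whose amplitude
    strictly exceeds the mean amplitude of the stage-1 set, or whose
    prominence reaches ``cfg.turn_prominence_strong``.
    """
    g_lp = np.asarray(g_lp, dtype=float)
    idx, props = find_peaks(g_lp, prominence=cfg.turn_prominence_min)
    if idx.size == 0:
        return []
    widths, _, _, _ = peak_widths(g_lp, idx,
                                  rel_height=cfg.turn_width_rel_height)
    amps = g_lp[idx]
    proms = props["prominences"]
    mean_amp = float(amps.mean())
    out = []
    for i in range(idx.size):
        if amps[i] > mean_amp or proms[i] >= cfg.turn_prominence_strong:
            out.append(TurnPeak(time=idx[i] / sample_rate,
                                amplitude=float(amps[i]),
                                prominence=float(proms[i]),
                                width=float(widths[i]) / sample_rate))
    return out


def peaks_to_segments(peaks: list[TurnPeak], duration: float) -> SegmentSet:
    """Span each kept peak by half its width on each side, clip to the
    recording and concatenate overlapping segments."""
    segs = []
    for p in peaks:
        seg = Segment(p.time - p.width / 2, p.time + p.width / 2,
                      ActivityLabel.TURNING, score=p.amplitude)
        clipped = seg.clipped(0.0, duration)
        if clipped is not None:
            segs.append(clipped)
    return merge_touching(segs, ActivityLabel.TURNING, max_gap=0.0)


def detect_turning(rec: ImuRecording, cfg: DetectionConfig | None = None,
                   signals: FilteredSignals | None = None) -> SegmentSet:
    """Full turning pipeline on a recording."""
    cfg = cfg or DetectionConfig()
    sig = signals if signals is not None else derive_signals(rec, cfg)
    peaks = find_turn_peaks(sig.g_lp, cfg, rec.sample_rate)
    return peaks_to_segments(peaks, rec.duration)
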