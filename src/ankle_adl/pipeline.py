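"""End-to-end detection: all four activities from one recording."""

from __future__ import annotations

import logging

import numpy as np

from .config import DetectionConfig
from .signal_filters import derive_signals
from .transition_detector import detect_transitions
from .turning_detector import detect_turning
from .types import ActivityLabel, ImuRecording, SegmentSet
from .walking_detector import detect_walking

log = logging.getLogger(__name__)


def quietest_window(rec: ImuRecording, window_s: float = 5.0) -> ImuRecording:
    """The lowest-variance window of a recording, usable as a static
    calibration fallback when no dedicated static recording exists."""
    n = rec.n_samples
    w = min(n, int(round(window_s * rec.sample_rate)))
    a = rec.acc_role("vertical")
    csum = np.concatenate(([0.0], np.cumsum(a)))
    csum2 = np.concatenate(([0.0], np.cumsum(a ** 2)))
    starts = np.arange(0, n - w + 1)
    var = (csum2[starts + w] - csum2[starts]) / w \
        - ((csum[starts + w] - csum[starts]) / w) ** 2
    i0 = int(var.argmin())
    return ImuRecording(sample_rate=rec.sample_rate,
                        time=rec.time[:w] - rec.time[0],
                        acc=rec.acc[i0:i0 + w].copy(),
                        gyro=rec.gyro[i0:i0 + w].copy(),
                        axis_map=dict(rec.axis_map),
                        meta={**dict(rec.meta), "window": "quietest"})


def detect_activities(rec: ImuRecording, static_rec: ImuRecording | None,
                      cfg: DetectionConfig | None = None,
                      ) -> dict[ActivityLabel, SegmentSet]:
    """Run the walking, turning and transition detectors on a recording.

    When ``static_rec`` is None, the activity threshold is calibrated from
    the quietest 5 s window of the trial itself (logged).
    """
    cfg = cfg or DetectionConfig()
    if static_rec is None:
        log.warning("no static recording given; calibrating the activity "
                    "threshold from the quietest window of the trial")
        static_rec = quietest_window(rec, cfg.static_min_duration)
    signals = derive_signals(rec, cfg)
    walking = detect_walking(rec, static_rec, cfg, signals=signals)
    turning = detect_turning(rec, cfg, signals=signals)
    sitting, standing = detect_transitions(rec, walking, cfg, signals=signals)
    return {ActivityLabel.WALKING: walking,
            ActivityLabel.TURNING: turning,
            ActivityLabel.SITTING_DOWN: sitting,
            ActivityLabel.STANDING_UP: standing}
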