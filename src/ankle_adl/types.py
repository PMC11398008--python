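"""Core domain types.

An :class:`ImuRecording` is a uniformly sampled 6-channel inertial time
series (tri-axial accelerometer in g, tri-axial gyroscope in rad/s) from a
single ankle-worn sensor.  Channels are addressed through *roles* rather
than raw column indices, because the mounting orientation of a consumer
watch strapped to the ankle is not canonical:

``vertical``
    along the shank; foot-impact transients during gait live here (and, for
    the gyroscope, yaw while turning on the spot).
``medio_lateral``
    left-right axis; shank pitch during sit-to-stand / stand-to-sit
    transitions appears on this gyroscope channel.
``anterior_posterior``
    front-back axis; carried but not used by the default detectors.

Detector outputs and ground truth share one currency: the half-open,
labelled time interval :class:`Segment`, grouped per activity into a
:class:`SegmentSet`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import SamplingError, ValidationError

#: Axis roles an ``axis_map`` must cover, each mapped to a distinct channel.
AXIS_ROLES = ("vertical", "medio_lateral", "anterior_posterior")

#: Default role -> channel mapping (x, y, z columns = channels 0, 1, 2):
#: the z column is taken as the along-shank axis.
DEFAULT_AXIS_MAP: dict[str, int] = {
    "vertical": 2,
    "medio_lateral": 0,
    "anterior_posterior": 1,
}

#: Tolerance on the uniformity of the time grid, in seconds.
TIME_GRID_TOL = 1e-6


class ActivityLabel(str, enum.Enum):
    """The activities of daily living this package detects."""

    WALKING = "Walking"
    TURNING = "Turning"
    SITTING_DOWN = "SittingDown"
    STANDING_UP = "StandingUp"
    NON_WALKING = "NonWalking"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels that may appear in annotation files (NonWalking is internal).
ANNOTATION_LABELS = (
    ActivityLabel.WALKING,
    ActivityLabel.TURNING,
    ActivityLabel.SITTING_DOWN,
    ActivityLabel.STANDING_UP,
)


@dataclass(frozen=True)
class Segment:
    """A labelled half-open time interval ``[start, end)`` in seconds.

    ``score`` optionally carries a detector-specific magnitude (e.g. the
    peak amplitude that generated a turning segment).  ``peaks`` is
    book-keeping used by the walking pipeline: times of the retained
    foot-impact acceleration peaks inside the segment.
    """

    start: float
    end: float
    label: ActivityLabel
    score: float | None = None
    peaks: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValidationError(
                f"segment start ({self.start}) must be < end ({self.end})"
            )
        if self.start < 0:
            raise ValidationError(f"segment start ({self.start}) must be >= 0")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap(self, other: "Segment") -> float:
        """Length of the intersection with ``other`` (0 if disjoint)."""
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))

    def clipped(self, lo: float, hi: float) -> "Segment | None":
        """Intersect with ``[lo, hi)``; ``None`` if the result is empty."""
        a, b = max(self.start, lo), min(self.end, hi)
        if a >= b:
            return None
        return replace(self, start=a, end=b)


@dataclass(frozen=True)
class SegmentSet:
    """Segments of one activity, sorted by start and mutually disjoint."""

    label: ActivityLabel
    segments: tuple[Segment, ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: (s.start, s.end)))
        for s in segs:
            if s.label is not self.label:
                raise ValidationError(
                    f"segment labelled {s.label} in a {self.label} set"
                )
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments [{a.start}, {a.end}) and "
                    f"[{b.start}, {b.end}) in {self.label} set"
                )
        object.__setattr__(self, "segments", segs)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def to_mask(self, n_samples: int, sample_rate: float) -> np.ndarray:
        """Boolean per-sample occupancy on a grid of ``n_samples`` at
        ``sample_rate`` Hz (sample i covers time i / sample_rate)."""
        mask = np.zeros(n_samples, dtype=bool)
        for s in self.segments:
            i0 = max(0, int(np.ceil(s.start * sample_rate - 1e-9)))
            i1 = min(n_samples, int(np.ceil(s.end * sample_rate - 1e-9)))
            mask[i0:i1] = True
        return mask


def merge_touching(segments: Iterable[Segment], label: ActivityLabel,
                   max_gap: float = 0.0) -> SegmentSet:
    """Union segments whose gap is < ``max_gap`` (overlap always merges).

    With ``max_gap=0`` only genuinely overlapping intervals merge; abutting
    half-open intervals stay separate.  Peak lists are concatenated and
    scores combined by max.
    """
    segs = sorted(segments, key=lambda s: (s.start, s.end))
    merged: list[Segment] = []
    for s in segs:
        if merged and s.start - merged[-1].end < max_gap:
            prev = merged[-1]
            peaks = None
            if prev.peaks is not None or s.peaks is not None:
                peaks = tuple(sorted((prev.peaks or ()) + (s.peaks or ())))
            score = None
            if prev.score is not None or s.score is not None:
                score = max(prev.score or -np.inf, s.score or -np.inf)
            merged[-1] = Segment(prev.start, max(prev.end, s.end), label,
                                 score=score, peaks=peaks)
        else:
            merged.append(s)
    return SegmentSet(label, tuple(merged))


@dataclass(frozen=True)
class ImuRecording:
    """A uniformly sampled ankle IMU recording.

    Parameters
    ----------
    sample_rate:
        Sampling frequency in Hz (the detectors were designed for 50 Hz;
        other rates are accepted but never resampled implicitly).
    time:
        Seconds from recording start, a uniform grid ``i / sample_rate``.
    acc:
        ``(n, 3)`` accelerometer channels in g.
    gyro:
        ``(n, 3)`` gyroscope channels in rad/s.
    axis_map:
        Role -> channel mapping; see module docstring.
    meta:
        Free-form provenance strings.
    """

    sample_rate: float
    time: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    axis_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_AXIS_MAP))
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        acc = np.asarray(self.acc, dtype=float)
        gyro = np.asarray(self.gyro, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if time.ndim != 1 or time.size < 2:
            raise ValidationError("recording needs at least 2 samples")
        if acc.shape != (time.size, 3) or gyro.shape != (time.size, 3):
            raise ValidationError(
                "acc and gyro must both have shape (n_samples, 3) matching time"
            )
        dt = 1.0 / self.sample_rate
        expected = time[0] + dt * np.arange(time.size)
        err = float(np.max(np.abs(time - expected)))
        if err > TIME_GRID_TOL:
            raise SamplingError(
                f"time grid deviates from uniform {self.sample_rate} Hz "
                f"sampling by up to {err:.3g} s (tolerance {TIME_GRID_TOL} s)"
            )
        roles = set(self.axis_map)
        if roles != set(AXIS_ROLES):
            raise ValidationError(
                f"axis_map must define exactly the roles {AXIS_ROLES}"
            )
        channels = [self.axis_map[r] for r in AXIS_ROLES]
        if len(set(channels)) != 3 or not all(c in (0, 1, 2) for c in channels):
            raise ValidationError(
                "axis_map must assign each role to a distinct channel in {0,1,2}"
            )
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "acc", acc)
        object.__setattr__(self, "gyro", gyro)

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Time span from first to last sample, in seconds."""
        return float(self.time[-1] - self.time[0])

    def acc_role(self, role: str) -> np.ndarray:
        return self.acc[:, self.axis_map[role]]

    def gyro_role(self, role: str) -> np.ndarray:
        return self.gyro[:, self.axis_map[role]]

    def reversed(self) -> "ImuRecording":
        """The same recording played backwards (for symmetry checks)."""
        return ImuRecording(
            sample_rate=self.sample_rate,
            time=self.time - self.time[0],
            acc=self.acc[::-1].copy(),
            gyro=self.gyro[::-1].copy(),
            axis_map=dict(self.axis_map),
            meta=dict(self.meta),
        )
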