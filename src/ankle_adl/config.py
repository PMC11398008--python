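"""Detector configuration.

:class:`DetectionConfig` gathers every cutoff, threshold multiplier,
duration and prominence constant used by the three detectors, with the
published defaults.  All accelerations are in g, angular velocities in
rad/s, times in seconds, frequencies in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class DetectionConfig:
    """Constants of the rule-based detection pipeline.

    Walking
    -------
    static_hp_cutoff:
        High-pass corner (Hz) applied to the static calibration recording
        before the activity threshold ``mean + sd_multiplier * sd`` is taken.
    walk_band_low:
        Narrow band-pass (Hz) isolating the per-step pattern of foot impacts
        (the signal compared against the activity threshold).
    walk_band_wide:
        Wide band-pass (Hz) keeping individual impact peaks sharp; used for
        the stationary-step range test and boundary refinement.
    sd_multiplier:
        The 30x standard-deviation multiplier of the activity threshold.
    min_walk_duration:
        Minimum time (s) the rectified narrow-band acceleration must exceed
        the threshold for a candidate walking interval.
    candidate_gap_close:
        Sub-threshold dips shorter than this (s) are bridged when forming
        candidate intervals (same constant as ``walk_merge_gap``; the
        rule set is kept minimal on purpose).
    walk_merge_gap:
        Walking segments closer than this (s) are concatenated.
    stationary_peak_fraction:
        Impact peaks below this fraction of the per-segment wide-band range
        are discarded as stationary shuffling.
    min_peaks_per_segment:
        Segments retaining fewer impact peaks than this are dropped.
    peak_min_distance:
        Minimum spacing (s) between detected impact peaks; 0.25 s
        corresponds to the fastest plausible step cadence (~4 Hz).
    refine_max_shift:
        A narrow-band boundary peak is snapped to the nearest wide-band
        impact peak only if one lies within this window (s), about half a
        gait cycle; otherwise the original boundary is kept.
    static_min_duration:
        Minimum static-recording length (s) for threshold calibration.

    Turning
    -------
    turn_lp_cutoff:
        Low-pass corner (Hz) for the rectified vertical angular velocity.
    turn_prominence_min / turn_prominence_strong:
        The 0.1 rad/s candidate-peak prominence and the 0.8 rad/s
        prominence that qualifies a peak regardless of amplitude.

    Sit-to-stand / stand-to-sit
    ---------------------------
    transition_lp_cutoff:
        Low-pass corner (Hz) for the medio-lateral angular velocity.
    transition_rms_factor:
        The 0.33 margin of the RMS test: an edge window qualifies when
        its RMS exceeds ``(1 + factor) * RMS_middle``.
    transition_edge_fraction:
        Fraction of a non-walking segment forming each edge window (0.25).
    transition_edge_min:
        Minimum useful edge-window length (s) for the testability gate.
    min_sit_duration:
        A non-walking segment must be at least ``min_sit_duration +
        2 * transition_edge_min`` long to be tested (the 2 s minimum-sit
        rule of manual segmentation).
    transition_bounds:
        ``"refined"`` places emitted transition bounds around the dominant
        angular-velocity burst inside the qualifying edge window (at
        ``transition_peak_rel_height`` of its peak); ``"window"`` emits the
        raw 25% edge-window bounds.
    transition_min_edge_rms:
        Absolute floor (rad/s) an edge-window RMS must clear before the
        ratio test applies; far below any sensor noise, it only rejects
        windows whose content is numerical dust on an all-zero channel.
    rms_margin_reference:
        ``"middle"`` (default) applies the 0.33 margin to the middle-window
        RMS; ``"edge"`` applies it to the edge RMS (the alternative reading
        of the printed threshold formula), i.e. requires
        ``(1 - factor) * RMS_edge > RMS_middle``.
    transition_three_axis:
        Use the norm of all three low-passed gyro channels instead of the
        medio-lateral channel alone.
    """

    # walking
    static_hp_cutoff: float = 0.5
    walk_band_low: tuple[float, float] = (0.5, 0.8)
    walk_band_wide: tuple[float, float] = (0.5, 3.0)
    sd_multiplier: float = 30.0
    min_walk_duration: float = 0.4
    candidate_gap_close: float = 1.0
    walk_merge_gap: float = 1.0
    stationary_peak_fraction: float = 0.25
    min_peaks_per_segment: int = 2
    peak_min_distance: float = 0.25
    refine_max_shift: float = 0.6
    static_min_duration: float = 5.0
    # turning
    turn_lp_cutoff: float = 0.5
    turn_prominence_min: float = 0.1
    turn_prominence_strong: float = 0.8
    turn_width_rel_height: float = 0.5
    # transitions
    transition_lp_cutoff: float = 4.0
    transition_rms_factor: float = 0.33
    transition_edge_fraction: float = 0.25
    transition_edge_min: float = 0.5
    min_sit_duration: float = 2.0
    transition_bounds: str = "refined"
    transition_peak_rel_height: float = 0.5
    transition_min_edge_rms: float = 1e-6
    rms_margin_reference: str = "middle"
    transition_three_axis: bool = False

    def __post_init__(self) -> None:
        for name in ("static_hp_cutoff", "min_walk_duration",
                     "candidate_gap_close", "walk_merge_gap",
                     "peak_min_distance", "turn_lp_cutoff",
                     "transition_lp_cutoff", "min_sit_duration",
                     "static_min_duration", "sd_multiplier"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("stationary_peak_fraction", "transition_edge_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")
        lo, hi = self.walk_band_low
        wlo, whi = self.walk_band_wide
        if not (0 < lo < hi and 0 < wlo < whi):
            raise ValidationError("band-pass corners must satisfy 0 < low < high")
        if not (wlo <= lo and hi <= whi):
            raise ValidationError("walk_band_low must lie inside walk_band_wide")
        if not 0 <= self.turn_prominence_min <= self.turn_prominence_strong:
            raise ValidationError(
                "turn prominences must satisfy 0 <= min <= strong")
        if 2 * self.transition_edge_fraction >= 1.0:
            raise ValidationError(
                "transition_edge_fraction must leave a non-empty middle window")
        if self.transition_bounds not in ("refined", "window"):
            raise ValidationError("transition_bounds must be 'refined' or 'window'")
        if self.rms_margin_reference not in ("middle", "edge"):
            raise ValidationError("rms_margin_reference must be 'middle' or 'edge'")

    def replace(self, **kwargs) -> "DetectionConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "DetectionConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(
                f"unknown config key(s): {', '.join(sorted(unknown))}")
        coerced = dict(data)
        for key in ("walk_band_low", "walk_band_wide"):
            if key in coerced:
                coerced[key] = tuple(float(v) for v in coerced[key])
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectionConfig":
        """Load a config from YAML; omitted keys keep their defaults."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
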