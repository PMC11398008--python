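"""Zero-lag Butterworth filter bank and the four derived detector signals.

All detectors operate on second-order Butterworth filters applied
forward-backward (``scipy.signal.filtfilt``), which cancels the phase
response and doubles the magnitude attenuation: a component at frequency
``f`` comes out scaled by ``|H(f)|**2`` where ``H`` is the single-pass
response.  Edge effects are controlled by odd (signal-reflection) padding.

The derived signals are:

``a_bplow``
    vertical (along-shank) acceleration band-passed to the narrow step
    band; gravity is removed by the 0.5 Hz lower corner and the trace
    follows the general per-step pattern of foot impacts.
``a_bpwalk``
    the same channel band-passed to a wider band that keeps individual
    impact peaks sharp.
``g_lp``
    vertical angular velocity low-passed and full-wave rectified; turning
    on the spot appears as a single smooth burst.
``g_mvt``
    medio-lateral angular velocity low-passed at 4 Hz; shank pitch during
    sit-down / stand-up appears as a burst at the edge of sitting bouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import DetectionConfig
from .errors import FilterSpecError, LengthError
from .types import ImuRecording


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter specification.

    ``cutoff_hz`` is a single corner for low/high-pass and an ``(low,
    high)`` pair for band-pass.  ``zero_lag=True`` applies the filter
    forward-backward (zero phase); ``False`` applies a single causal pass.
    """

    kind: str
    cutoff_hz: float | tuple[float, float]
    order: int = 2
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise FilterSpecError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise FilterSpecError("filter order must be >= 1")
        if self.kind == "bandpass":
            try:
                lo, hi = self.cutoff_hz  # type: ignore[misc]
            except TypeError:
                raise FilterSpecError("bandpass needs a (low, high) cutoff pair")
            if not 0 < lo < hi:
                raise FilterSpecError("bandpass corners must satisfy 0 < low < high")
        else:
            if not np.isscalar(self.cutoff_hz) or float(self.cutoff_hz) <= 0:  # type: ignore[arg-type]
                raise FilterSpecError(f"{self.kind} needs one positive cutoff")

    def validate_rate(self, sample_rate: float) -> None:
        cut = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        if np.any(cut >= sample_rate / 2):
            raise FilterSpecError(
                f"cutoff {self.cutoff_hz} Hz at or above Nyquist "
                f"({sample_rate / 2} Hz)")

    def coefficients(self, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
        self.validate_rate(sample_rate)
        return sps.butter(self.order, self.cutoff_hz, btype=self.kind,
                          fs=sample_rate)


@dataclass(frozen=True)
class FilteredSignals:
    """The four derived detector signals (see module docstring)."""

    a_bplow: np.ndarray
    a_bpwalk: np.ndarray
    g_lp: np.ndarray
    g_mvt: np.ndarray
    sample_rate: float


def zero_lag_filter(x: np.ndarray, spec: FilterSpec,
                    sample_rate: float) -> np.ndarray:
    """Apply ``spec`` to ``x``; zero-phase when ``spec.zero_lag``.

    Output length equals input length.  Raises :class:`LengthError` when
    the signal is shorter than the reflection padding requires and
    :class:`FilterSpecError` for cutoffs at or above Nyquist.
    """
    x = np.asarray(x, dtype=float)
    b, a = spec.coefficients(sample_rate)
    if not spec.zero_lag:
        return sps.lfilter(b, a, x)
    padlen = 3 * max(len(a), len(b))
    if x.size <= padlen:
        raise LengthError(
            f"signal of {x.size} samples too short for zero-lag filtering "
            f"(needs > {padlen})")
    return sps.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def butter_zero_lag_gain(f: np.ndarray | float, spec: FilterSpec,
                         sample_rate: float) -> np.ndarray:
    """Closed-form amplitude gain of the forward-backward filter at ``f`` Hz.

    Uses the exact digital Butterworth magnitude (bilinear-transform
    design), squared for the two passes.  Serves as an analytic reference
    for tests and documentation; the filtering itself never calls this.
    """
    f = np.asarray(f, dtype=float)
    warp = lambda g: np.tan(np.pi * g / sample_rate)  # noqa: E731
    w = warp(f)
    n = spec.order
    if spec.kind == "lowpass":
        wc = warp(float(spec.cutoff_hz))  # type: ignore[arg-type]
        h2 = 1.0 / (1.0 + (w / wc) ** (2 * n))
    elif spec.kind == "highpass":
        wc = warp(float(spec.cutoff_hz))  # type: ignore[arg-type]
        with np.errstate(divide="ignore"):
            h2 = 1.0 / (1.0 + (wc / w) ** (2 * n))
    else:
        lo, hi = spec.cutoff_hz  # type: ignore[misc]
        wl, wh = warp(lo), warp(hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (w ** 2 - wl * wh) / (w * (wh - wl))
        q = np.where(w == 0, np.inf, q)
        h2 = 1.0 / (1.0 + q ** (2 * n))
    return h2  # |H|^2: amplitude gain after the forward and backward pass


def derive_signals(rec: ImuRecording, cfg: DetectionConfig) -> FilteredSignals:
    """Compute the four derived signals from a recording's axis roles."""
    fs = rec.sample_rate
    a_v = rec.acc_role("vertical")
    a_bplow = zero_lag_filter(
        a_v, FilterSpec("bandpass", cfg.walk_band_low), fs)
    a_bpwalk = zero_lag_filter(
        a_v, FilterSpec("bandpass", cfg.walk_band_wide), fs)
    g_lp = np.abs(zero_lag_filter(
        rec.gyro_role("vertical"), FilterSpec("lowpass", cfg.turn_lp_cutoff), fs))
    lp4 = FilterSpec("lowpass", cfg.transition_lp_cutoff)
    if cfg.transition_three_axis:
        filtered = np.column_stack(
            [zero_lag_filter(rec.gyro[:, c], lp4, fs) for c in range(3)])
        g_mvt = np.linalg.norm(filtered, axis=1)
    else:
        g_mvt = zero_lag_filter(rec.gyro_role("medio_lateral"), lp4, fs)
    return FilteredSignals(a_bplow=a_bplow, a_bpwalk=a_bpwalk, g_lp=g_lp,
                           g_mvt=g_mvt, sample_rate=fs)
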