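"""Scripted synthesis of labelled single-ankle IMU recordings.

No public recordings exist for this problem, so detectors and evaluation
are exercised on synthetic signals whose morphology mimics what an ankle
sensor sees:

* **Walk** - one damped-sinusoid foot-impact burst per stride on the
  vertical (along-shank) acceleration.  The carrier sits at the stride
  rate, giving the train the strong step-frequency fundamental that the
  narrow walking band picks up, and the decay sharpens each burst into a
  single countable impact peak.
* **StationaryShuffle** - the same bursts at a fraction of the walking
  impact amplitude: in-place steps that must *not* count as walking.
* **Turn** - a single smooth unimodal burst on the
  vertical gyro, confined to the scripted span.
* **SitDown / StandUp** - the same burst shape on the medio-lateral gyro
  (shank pitch while the leg folds/unfolds).
* **Rest / Sit** - baseline only.

Gravity appears as a constant 1 g offset on the vertical acceleration
channel; white sensor noise and an optional 4-6 Hz tremor sinusoid are
added to every channel.  The script's label track, gated by the manual
segmentation rules (walks shorter than two strides and sits shorter than
2 s are unlabelled), is the ground truth.

Randomness is fully determined by the script's single seed, split into
independent streams (one per noise channel plus one for tremor phases)
via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ScriptError
from .types import (ActivityLabel, DEFAULT_AXIS_MAP, ImuRecording, Segment,
                    SegmentSet)

#: Activity primitives a script may contain.
PRIMITIVES = ("Rest", "Sit", "Walk", "Turn", "SitDown", "StandUp",
              "StationaryShuffle")

#: Morphology defaults, overridable per entry through ``params``.
WALK_DEFAULTS = {"stride_rate": 0.9, "impact_amp": 1.0, "impact_decay": 0.8,
                 "first_impact_offset": 0.2}
SHUFFLE_AMP_FRACTION = 0.2
TURN_DEFAULTS = {"peak": 1.5}
TRANSITION_DEFAULTS = {"peak": 1.0}
#: Exponent of the power-of-sine burst window sin(pi*tau)**p: strictly
#: unimodal with compact support; with p = 0.3 the half-height width is
#: ~0.94 of the burst duration, so a detected peak width tracks the
#: scripted activity duration.
BURST_SINE_POWER = 0.3
GRAVITY_G = 1.0
#: Minimum number of strides for a Walk to count as a walking bout
#: (the 1.5 m minimum-distance rule expressed without a spatial model).
MIN_STRIDES_FOR_LABEL = 2
#: Minimum sitting-bout duration (s) for the flanking transitions to be
#: part of the ground truth.
MIN_SIT_FOR_LABEL = 2.0

#: Sensor noise floor (g and rad/s) used for static calibration recordings.
STATIC_NOISE_SD = 0.002


@dataclass(frozen=True)
class ScriptEntry:
    """One scripted activity primitive."""

    primitive: str
    duration: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.primitive not in PRIMITIVES:
            raise ScriptError(f"unknown primitive {self.primitive!r}")
        if self.duration <= 0:
            raise ScriptError("entry duration must be positive")


@dataclass(frozen=True)
class ActivityScript:
    """An ordered list of activity primitives plus noise settings.

    ``noise_sd_acc`` (g) and ``noise_sd_gyro`` (rad/s) set the white-noise
    level on all channels; ``tremor_amplitude`` (> 0 enables) adds a
    sinusoid at ``tremor_freq`` Hz (4-6 Hz band) to every channel.
    """

    entries: tuple[ScriptEntry, ...]
    noise_sd_acc: float = 0.0
    noise_sd_gyro: float = 0.0
    tremor_amplitude: float = 0.0
    tremor_freq: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ScriptError("script has no entries")
        if self.tremor_amplitude and not 4.0 <= self.tremor_freq <= 6.0:
            raise ScriptError("tremor_freq must lie in [4, 6] Hz")
        _validate_ordering(self.entries)

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.entries))


def _validate_ordering(entries: tuple[ScriptEntry, ...]) -> None:
    """Posture book-keeping: SitDown only from standing, StandUp and Sit
    only while seated, locomotion only while standing."""
    seated = entries[0].primitive == "Sit"
    for e in entries:
        if e.primitive == "SitDown":
            if seated:
                raise ScriptError("SitDown while already seated")
            seated = True
        elif e.primitive == "StandUp":
            if not seated:
                raise ScriptError("StandUp while not seated")
            seated = False
        elif e.primitive == "Sit":
            if not seated:
                raise ScriptError("Sit entry must follow SitDown "
                                  "(or open the script)")
        elif e.primitive in ("Walk", "Turn", "StationaryShuffle", "Rest"):
            if seated:
                raise ScriptError(f"{e.primitive} while seated")


@dataclass(frozen=True)
class LabeledRecording:
    """A synthesized recording plus its per-activity ground truth."""

    recording: ImuRecording
    truth: dict[ActivityLabel, SegmentSet]


def _sine_burst(t: np.ndarray, start: float, duration: float,
                peak: float) -> np.ndarray:
    """A single smooth burst with compact support: exactly zero outside
    [start, start + duration), one maximum at the centre."""
    x = np.zeros_like(t)
    m = (t >= start) & (t < start + duration)
    tau = (t[m] - start) / duration
    x[m] = peak * np.sin(np.pi * tau) ** BURST_SINE_POWER
    return x


def _impact_train(t: np.ndarray, start: float, duration: float,
                  stride_rate: float, amp: float, decay: float,
                  offset: float) -> tuple[np.ndarray, list[float]]:
    """One damped-sinusoid burst per stride; the final burst's oscillation
    decays naturally past the entry end, as a real last footfall does."""
    x = np.zeros_like(t)
    support = 1.0 / stride_rate
    end = start + duration
    centers = []
    c = start + offset
    while c + offset <= end:
        m = (t >= c) & (t < c + support)
        tau = t[m] - c
        x[m] += amp * np.exp(-tau / decay) * np.sin(2 * np.pi * stride_rate * tau)
        centers.append(c)
        c += support
    return x, centers


def simulate_recording(script: ActivityScript,
                       sample_rate: float = 50.0) -> LabeledRecording:
    """Render a script into an :class:`ImuRecording` with ground truth.

    Deterministic given ``(script, sample_rate)``: all randomness stems
    from ``script.seed``.
    """
    n = int(round(script.total_duration * sample_rate))
    if n < 2:
        raise ScriptError("script too short for the sample rate")
    t = np.arange(n) / sample_rate
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    axis_map = dict(DEFAULT_AXIS_MAP)
    i_v, i_ml = axis_map["vertical"], axis_map["medio_lateral"]

    truth: dict[ActivityLabel, list[Segment]] = {
        lab: [] for lab in (ActivityLabel.WALKING, ActivityLabel.TURNING,
                            ActivityLabel.SITTING_DOWN, ActivityLabel.STANDING_UP)}
    entries = script.entries
    cursor = 0.0
    for k, e in enumerate(entries):
        if e.primitive in ("Walk", "StationaryShuffle"):
            p = {**WALK_DEFAULTS, **e.params}
            amp = p["impact_amp"]
            if e.primitive == "StationaryShuffle":
                amp *= p.get("amp_fraction", SHUFFLE_AMP_FRACTION)
            x, centers = _impact_train(t, cursor, e.duration, p["stride_rate"],
                                       amp, p["impact_decay"],
                                       p["first_impact_offset"])
            acc[:, i_v] += x
            if (e.primitive == "Walk"
                    and len(centers) >= MIN_STRIDES_FOR_LABEL):
                truth[ActivityLabel.WALKING].append(
                    Segment(cursor, cursor + e.duration, ActivityLabel.WALKING))
        elif e.primitive == "Turn":
            p = {**TURN_DEFAULTS, **e.params}
            gyro[:, i_v] += _sine_burst(t, cursor, e.duration, p["peak"])
            truth[ActivityLabel.TURNING].append(
                Segment(cursor, cursor + e.duration, ActivityLabel.TURNING))
        elif e.primitive in ("SitDown", "StandUp"):
            p = {**TRANSITION_DEFAULTS, **e.params}
            gyro[:, i_ml] += _sine_burst(t, cursor, e.duration, p["peak"])
            # the transition is ground truth only when the sitting bout it
            # borders lasts at least MIN_SIT_FOR_LABEL seconds
            neighbour = k + 1 if e.primitive == "SitDown" else k - 1
            sit_ok = (0 <= neighbour < len(entries)
                      and entries[neighbour].primitive == "Sit"
                      and entries[neighbour].duration >= MIN_SIT_FOR_LABEL)
            if sit_ok:
                lab = (ActivityLabel.SITTING_DOWN if e.primitive == "SitDown"
                       else ActivityLabel.STANDING_UP)
                truth[lab].append(Segment(cursor, cursor + e.duration, lab))
        cursor += e.duration

    acc[:, i_v] += GRAVITY_G

    streams = np.random.SeedSequence(script.seed).spawn(7)
    for c in range(3):
        if script.noise_sd_acc > 0:
            acc[:, c] += np.random.default_rng(streams[c]).normal(
                0.0, script.noise_sd_acc, n)
        if script.noise_sd_gyro > 0:
            gyro[:, c] += np.random.default_rng(streams[3 + c]).normal(
                0.0, script.noise_sd_gyro, n)
    if script.tremor_amplitude > 0:
        phases = np.random.default_rng(streams[6]).uniform(0, 2 * np.pi, 6)
        for c in range(3):
            acc[:, c] += script.tremor_amplitude * np.sin(
                2 * np.pi * script.tremor_freq * t + phases[c])
            gyro[:, c] += script.tremor_amplitude * np.sin(
                2 * np.pi * script.tremor_freq * t + phases[3 + c])

    rec = ImuRecording(sample_rate=sample_rate, time=t, acc=acc, gyro=gyro,
                       axis_map=axis_map,
                       meta={"source": "ankle_adl.synthetic_generator",
                             "seed": str(script.seed)})
    truth_sets = {lab: SegmentSet(lab, tuple(segs))
                  for lab, segs in truth.items()}
    return LabeledRecording(recording=rec, truth=truth_sets)


def make_static_script(duration: float = 30.0,
                       noise_sd: float = STATIC_NOISE_SD,
                       seed: int = 0) -> ActivityScript:
    """A sensor-at-rest script at the sensor noise floor, for calibrating
    the walking activity threshold."""
    return ActivityScript(entries=(ScriptEntry("Rest", duration),),
                          noise_sd_acc=noise_sd, noise_sd_gyro=noise_sd,
                          seed=seed)


def make_tug_script(seed: int = 0, noise_sd_acc: float = 0.0,
                    noise_sd_gyro: float = 0.0,
                    tremor_amplitude: float = 0.0) -> ActivityScript:
    """A Timed Up and Go trial: sit, stand up, walk out, turn around,
    walk back, turn and sit down, remain seated."""
    entries = (
        ScriptEntry("Sit", 5.0),
        ScriptEntry("StandUp", 1.5),
        ScriptEntry("Walk", 4.0),
        ScriptEntry("Turn", 5.0),
        ScriptEntry("Walk", 4.0),
        ScriptEntry("Turn", 5.0),
        ScriptEntry("SitDown", 1.5),
        ScriptEntry("Sit", 19.5),
    )
    return ActivityScript(entries=entries, noise_sd_acc=noise_sd_acc,
                          noise_sd_gyro=noise_sd_gyro,
                          tremor_amplitude=tremor_amplitude, seed=seed)


def make_free_living_script(total_duration: float = 180.0,
                            n_sit_bouts: int = 3, n_turns: int = 6,
                            seed: int = 0, noise_sd_acc: float = 0.0,
                            noise_sd_gyro: float = 0.0,
                            tremor_amplitude: float = 0.0) -> ActivityScript:
    """A free-living-style trial interleaving walking bouts with turns,
    sitting bouts, stationary shuffling and rest.

    Exactly ``n_sit_bouts`` SitDown+Sit+StandUp triples and ``n_turns``
    turns are placed in a seed-randomised order, each reached by a walking
    bout.  Leftover time is spread across the walking bouts and a final
    rest so the scripted duration equals ``total_duration`` exactly.
    """
    if total_duration < 60.0:
        raise ScriptError("free-living scripts must last at least 60 s")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5C817)))

    blocks: list[list[ScriptEntry]] = []
    for _ in range(n_sit_bouts):
        blocks.append([ScriptEntry("SitDown", 1.5),
                       ScriptEntry("Sit", float(rng.uniform(3.5, 5.0))),
                       ScriptEntry("StandUp", 1.5)])
    for _ in range(n_turns):
        blocks.append([ScriptEntry("Turn", float(rng.uniform(4.8, 5.6)))])
    for _ in range(int(rng.integers(1, 4))):
        shuffle = [ScriptEntry("StationaryShuffle", float(rng.uniform(5.0, 6.0)))]
        if rng.random() < 0.5:
            shuffle.append(ScriptEntry("Rest", float(rng.uniform(1.5, 3.0))))
        blocks.append(shuffle)
    order = rng.permutation(len(blocks))

    entries: list[ScriptEntry] = [ScriptEntry("Rest", 2.0)]
    walk_positions: list[int] = []
    for bi in order:
        walk_positions.append(len(entries))
        entries.append(ScriptEntry("Walk", float(rng.uniform(3.0, 6.0))))
        entries.extend(blocks[bi])
    walk_positions.append(len(entries))
    entries.append(ScriptEntry("Walk", float(rng.uniform(3.0, 6.0))))

    used = sum(e.duration for e in entries)
    remaining = total_duration - used
    if remaining < 1.0:
        raise ScriptError(
            f"{n_sit_bouts} sitting bouts and {n_turns} turns do not fit in "
            f"{total_duration} s")
    final_rest = float(remaining * rng.uniform(0.2, 0.4))
    per_walk = (remaining - final_rest) / len(walk_positions)
    for pos in walk_positions:
        e = entries[pos]
        entries[pos] = replace(e, duration=e.duration + per_walk)
    entries.append(ScriptEntry("Rest", final_rest))

    return ActivityScript(entries=tuple(entries), noise_sd_acc=noise_sd_acc,
                          noise_sd_gyro=noise_sd_gyro,
                          tremor_amplitude=tremor_amplitude, seed=seed)
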