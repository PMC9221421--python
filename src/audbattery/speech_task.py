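"""Three-talker speech-in-competition task with spatial release from masking.

The task emulates a closed-set coordinate-response paradigm: a target talker
(callsign CHARLIE) instructs "Ready CHARLIE go to (COLOR) (NUMBER) now"
while two masker talkers, using other callsigns and different color/number
combinations, compete.  Maskers are either colocated with the target
(CO, all at 0 deg azimuth) or separated at +/-45 deg (SEP).

Thresholds come from progressive tracking: the target-to-masker ratio (TMR)
descends from +10 dB to -10 dB in 2-dB steps, two trials per step (22
trials); the threshold, in dB, is 10 minus the number of correct responses,
an estimate of the 50%-correct TMR.  Spatial release from masking is
SRM = CO threshold - SEP threshold.

Intelligibility is simulated at the psychometric level (probability correct
vs TMR; see :mod:`audbattery.virtual_listener`); no recorded speech corpus
is consumed.  :func:`render_scene` provides a simplified spherical-head
spatializer (Woodworth ITD + broadband ILD) for audio demos and QC in place
of measured head-related transfer functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .stimuli import AudioStimulus, CalibrationMap

__all__ = [
    "TMR_SCHEDULE",
    "CALLSIGNS",
    "COLORS",
    "NUMBERS",
    "TARGET_CALLSIGN",
    "ProgressiveTrack",
    "SceneSpec",
    "SentenceToken",
    "build_progressive_track",
    "score_progressive_track",
    "compute_srm",
    "sample_sentences",
    "run_progressive_track",
    "measure_speech_threshold",
    "woodworth_itd_s",
    "broadband_ild_db",
    "render_scene",
]

log = logging.getLogger(__name__)


class UsageError(RuntimeError):
    pass


#: fixed progressive schedule: 10 -> -10 dB TMR, 2-dB steps, 2 trials each
TMR_SCHEDULE: tuple[int, ...] = tuple(
    tmr for tmr in range(10, -11, -2) for _ in range(2)
)

CALLSIGNS = ("arrow", "baron", "charlie", "eagle", "hopper", "laker", "ringo", "tiger")
TARGET_CALLSIGN = "charlie"
COLORS = ("blue", "green", "red", "white")
NUMBERS = tuple(range(1, 9))


@dataclass(frozen=True)
class SentenceToken:
    """One talker's callsign / color / number selection."""

    callsign: str
    color: str
    number: int

    def __post_init__(self) -> None:
        if self.callsign not in CALLSIGNS:
            raise UsageError(f"unknown callsign {self.callsign!r}")
        if self.color not in COLORS or self.number not in NUMBERS:
            raise UsageError("color/number outside the closed set")


@dataclass
class ProgressiveTrack:
    """The fixed 22-trial TMR schedule and its responses for one condition."""

    condition: Literal["CO", "SEP"]
    tmr_schedule: tuple[int, ...] = TMR_SCHEDULE
    responses: list[bool] | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("CO", "SEP"):
            raise UsageError(f"unknown condition {self.condition!r}")
        if tuple(self.tmr_schedule) != TMR_SCHEDULE:
            raise UsageError("schedule must be 10..-10 dB in 2-dB steps, two trials each")


def build_progressive_track(condition: str) -> ProgressiveTrack:
    """A fresh (unanswered) progressive track for ``condition``."""
    return ProgressiveTrack(condition=condition)


def score_progressive_track(track: ProgressiveTrack | Sequence[bool]) -> int:
    """Threshold in dB: starting TMR (10 dB) minus the number correct.

    Estimates the 50%-correct point; an integer in [-12, 10].
    """
    responses = track.responses if isinstance(track, ProgressiveTrack) else list(track)
    if responses is None or len(responses) != len(TMR_SCHEDULE):
        raise UsageError(f"expected exactly {len(TMR_SCHEDULE)} responses")
    return 10 - int(sum(bool(r) for r in responses))


def compute_srm(co_threshold: float, sep_threshold: float) -> float:
    """Spatial release from masking: CO threshold minus SEP threshold, dB."""
    if not (math.isfinite(co_threshold) and math.isfinite(sep_threshold)):
        raise UsageError("thresholds must be finite")
    return co_threshold - sep_threshold


def sample_sentences(
    seed: int | np.random.Generator | None = None,
) -> tuple[SentenceToken, tuple[SentenceToken, SentenceToken]]:
    """Draw a target sentence and two masker sentences.

    The target always uses CHARLIE; maskers use two distinct other callsigns
    and color/number combinations that differ from the target's (and from
    each other), uniformly over the admissible combinations.
    """
    rng = np.random.default_rng(seed)
    target = SentenceToken(
        TARGET_CALLSIGN,
        COLORS[rng.integers(len(COLORS))],
        NUMBERS[rng.integers(len(NUMBERS))],
    )
    other_calls = [c for c in CALLSIGNS if c != TARGET_CALLSIGN]
    calls = rng.choice(len(other_calls), size=2, replace=False)
    other_colors = [c for c in COLORS if c != target.color]
    colors = rng.choice(len(other_colors), size=2, replace=False)
    other_numbers = [n for n in NUMBERS if n != target.number]
    numbers = rng.choice(len(other_numbers), size=2, replace=False)
    maskers = tuple(
        SentenceToken(other_calls[calls[i]], other_colors[colors[i]], other_numbers[numbers[i]])
        for i in range(2)
    )
    return target, maskers


# ---------------------------------------------------------------------------
# simulated measurement


def run_progressive_track(
    respond: Callable[[float], bool],
    condition: str,
) -> ProgressiveTrack:
    """Answer the full 22-trial schedule through a response model."""
    track = build_progressive_track(condition)
    track.responses = [bool(respond(float(tmr))) for tmr in track.tmr_schedule]
    return track


def measure_speech_threshold(
    respond: Callable[[float], bool],
    condition: str,
    n_runs: int = 2,
) -> float:
    """Scored threshold averaged over ``n_runs`` repeated tracks, dB."""
    scores = [score_progressive_track(run_progressive_track(respond, condition))
              for _ in range(n_runs)]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# simplified spatial rendering (spherical-head ITD/ILD, no measured HRTFs)

SPEED_OF_SOUND_M_S = 343.0
HEAD_RADIUS_M = 0.0875
#: broadband ILD scale: total left-right level difference at 90 deg (dB)
ILD_AT_90_DEG_DB = 8.0


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and level of the three-talker scene."""

    condition: Literal["CO", "SEP"] = "CO"
    target_azimuth_deg: float = 0.0
    masker_azimuths_deg: tuple[float, float] = (0.0, 0.0)
    target_level_db_spl: float = 65.0

    def __post_init__(self) -> None:
        expected = (0.0, 0.0) if self.condition == "CO" else (45.0, -45.0)
        if tuple(self.masker_azimuths_deg) != expected:
            raise UsageError(
                f"{self.condition} condition requires masker azimuths {expected}"
            )

    @classmethod
    def colocated(cls) -> "SceneSpec":
        return cls(condition="CO")

    @classmethod
    def separated(cls) -> "SceneSpec":
        return cls(condition="SEP", masker_azimuths_deg=(45.0, -45.0))


def woodworth_itd_s(azimuth_deg: float, head_radius_m: float = HEAD_RADIUS_M,
                    speed_of_sound_m_s: float = SPEED_OF_SOUND_M_S) -> float:
    """Interaural time difference of a rigid spherical head (Woodworth).

    ITD = (a/c) * (sin(theta) + theta); positive when the source is on the
    right (+azimuth), i.e. the left ear lags.
    """
    theta = math.radians(azimuth_deg)
    sign = 1.0 if theta >= 0 else -1.0
    theta = abs(theta)
    return sign * head_radius_m / speed_of_sound_m_s * (math.sin(theta) + theta)


def broadband_ild_db(azimuth_deg: float) -> float:
    """Broadband interaural level difference lookup (near-ear minus far-ear)."""
    return ILD_AT_90_DEG_DB * math.sin(math.radians(azimuth_deg))


def _spatialize(mono: np.ndarray, azimuth_deg: float, fs: int) -> np.ndarray:
    """Return (2, n) with ITD and ILD applied; azimuth 0 gives equal channels."""
    itd = woodworth_itd_s(azimuth_deg)
    lag = round(abs(itd) * fs)
    ild = broadband_ild_db(azimuth_deg)
    g_near = 10.0 ** (+abs(ild) / 40.0)
    g_far = 10.0 ** (-abs(ild) / 40.0)
    delayed = np.concatenate([np.zeros(lag), mono[: mono.size - lag]])
    if azimuth_deg > 0:  # source right: left ear far
        left, right = g_far * delayed, g_near * mono
    elif azimuth_deg < 0:
        left, right = g_near * mono, g_far * delayed
    else:
        left = right = mono
    return np.vstack([left, right])


def render_scene(
    signals: Sequence[AudioStimulus],
    scene: SceneSpec,
    tmr_db: float,
    calib: CalibrationMap | None = None,
) -> AudioStimulus:
    """Mix target + two maskers into a binaural scene at the given TMR.

    The target is fixed at the scene's level (65 dB SPL by default); each
    masker is set so the target-to-single-masker ratio equals ``tmr_db``
    (both maskers at equal level, the convention of closed-set
    speech-on-speech studies).  A colocated scene has zero interaural
    differences for every source.  A mix that would clip is rescaled, with a
    warning.
    """
    if len(signals) != 3:
        raise UsageError("expected target + two maskers")
    n = signals[0].n_samples
    fs = signals[0].sample_rate
    if any(s.n_samples != n or s.sample_rate != fs for s in signals):
        raise UsageError("signals must share length and sample rate")
    calib = calib or CalibrationMap()

    target_rms = calib.rms_for_level(scene.target_level_db_spl)
    masker_rms = calib.rms_for_level(scene.target_level_db_spl - tmr_db)

    def normalized(stim: AudioStimulus, rms: float) -> np.ndarray:
        x = stim.channel(0)
        return x * (rms / max(np.sqrt(np.mean(x**2)), 1e-30))

    azimuths = (scene.target_azimuth_deg,) + tuple(scene.masker_azimuths_deg)
    levels = (target_rms, masker_rms, masker_rms)
    mix = np.zeros((2, n))
    for stim, az, rms in zip(signals, azimuths, levels):
        mix += _spatialize(normalized(stim, rms), az, fs)
    peak = np.max(np.abs(mix))
    if peak > 1.0:
        log.warning("scene mix clipped (peak %.3f); rescaling to full scale", peak)
        mix /= peak
    return AudioStimulus(mix, fs)
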