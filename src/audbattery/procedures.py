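"""Four-interval 2C-2AFC trial structure and 2-down-1-up adaptive tracking.

A trial presents four temporal intervals: the first and fourth are "cue"
intervals that always contain the standard stimulus; the second and third
are the forced-choice pair, one of which (chosen with probability 1/2)
contains the target.  The target magnitude is tracked adaptively on a
logarithmic scale — log2(Hz) for FM depth, log2(ms) for the gap, dB for the
modulated-noise depths — with a 2-down-1-up rule, which converges on the
70.7%-correct point of the psychometric function.

Staircase constants (start level, step sizes, reversal counts) live in
:class:`AdaptiveConfig` so alternative published parameterizations can be
slotted in; the defaults are standard choices: step halving over the first
reversals, stop after 10 reversals or 60 trials, threshold = mean of the
last 6 reversal levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .stimuli import (
    AudioStimulus,
    CalibrationMap,
    FMToneSpec,
    GapStimulusSpec,
    ModulatedNoiseSpec,
    standard_for,
    synth_fm_tone,
    synth_gap_pair,
    synth_modulated_noise,
)

__all__ = [
    "AdaptiveConfig",
    "StaircaseState",
    "TrialLayout",
    "ThresholdEstimate",
    "TrackResult",
    "new_staircase",
    "staircase_update",
    "estimate_threshold",
    "choose_target_position",
    "make_trial",
    "run_adaptive_task",
]


class UsageError(RuntimeError):
    """An operation was invoked outside its contract."""


@dataclass(frozen=True)
class AdaptiveConfig:
    """Constants of the adaptive track (all levels/steps in log units)."""

    start_level_log: float
    initial_step_log: float = 1.0
    min_step_log: float = 0.25
    rule_down: int = 2
    rule_up: int = 1
    step_halving_reversals: int = 4
    stop_reversals: int = 10
    max_trials: int = 60
    level_bounds_log: tuple[float, float] = (-10.0, 10.0)
    n_reversals_for_threshold: int = 6

    def __post_init__(self) -> None:
        lo, hi = self.level_bounds_log
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("level bounds must be finite with lo < hi")
        if self.stop_reversals < self.step_halving_reversals:
            raise ValueError("stop_reversals must be >= step_halving_reversals")
        if self.initial_step_log <= 0 or self.min_step_log <= 0:
            raise ValueError("step sizes must be positive")


@dataclass(frozen=True)
class StaircaseState:
    """Immutable bookkeeping of one adaptive track."""

    level_log: float
    step_log: float
    n_correct_at_level: int = 0
    reversals: tuple[float, ...] = ()
    history: tuple[tuple[float, bool], ...] = ()
    finished: bool = False
    direction: int = 0  # -1 descending, +1 ascending, 0 before first move


def new_staircase(config: AdaptiveConfig) -> StaircaseState:
    return StaircaseState(level_log=config.start_level_log, step_log=config.initial_step_log)


def _clamp(x: float, bounds: tuple[float, float]) -> float:
    return min(max(x, bounds[0]), bounds[1])


def staircase_update(
    state: StaircaseState, config: AdaptiveConfig, correct: bool
) -> StaircaseState:
    """Advance the 2-down-1-up track by one trial.

    The level moves down one step after ``rule_down`` consecutive correct
    responses and up one step after any incorrect response.  A reversal is
    recorded (at the pre-move level) whenever the movement direction flips;
    the step halves, not below ``min_step_log``, after each of the first
    ``step_halving_reversals`` reversals.
    """
    if state.finished:
        raise UsageError("staircase already finished")

    history = state.history + ((state.level_log, bool(correct)),)
    level = state.level_log
    step = state.step_log
    reversals = state.reversals
    direction = state.direction
    n_corr = state.n_correct_at_level

    move = 0
    if correct:
        n_corr += 1
        if n_corr >= config.rule_down:
            move = -1
            n_corr = 0
    else:
        n_corr = 0
        move = +1

    if move != 0:
        if direction != 0 and move != direction:
            reversals = reversals + (level,)
            if len(reversals) <= config.step_halving_reversals:
                step = max(step / 2.0, config.min_step_log)
        direction = move
        level = _clamp(level + move * step, config.level_bounds_log)

    finished = len(reversals) >= config.stop_reversals or len(history) >= config.max_trials
    return StaircaseState(
        level_log=level,
        step_log=step,
        n_correct_at_level=n_corr,
        reversals=reversals,
        history=history,
        finished=finished,
        direction=direction,
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    value: float
    n_reversals_used: int
    converged: bool  # False when fewer than the requested reversals existed


def estimate_threshold(state: StaircaseState, config: AdaptiveConfig) -> ThresholdEstimate:
    """Mean of the last k reversal levels (k = config.n_reversals_for_threshold).

    Falls back, flagged, to the mean of all reversals when fewer than k are
    available; with no reversals at all the final level is returned.
    """
    if not state.finished:
        raise UsageError("track not finished")
    k = config.n_reversals_for_threshold
    revs = state.reversals
    if len(revs) >= k:
        return ThresholdEstimate(float(np.mean(revs[-k:])), k, True)
    if revs:
        return ThresholdEstimate(float(np.mean(revs)), len(revs), False)
    return ThresholdEstimate(state.level_log, 0, False)


# ---------------------------------------------------------------------------
# trial assembly


@dataclass(frozen=True)
class TrialLayout:
    """One four-interval trial: roles, stimuli, and the seeded target slot."""

    interval_roles: tuple[str, str, str, str]  # (cue, choiceA, choiceB, cue)
    target_position: str  # "choiceA" | "choiceB"
    isi_s: float
    intervals: tuple[AudioStimulus, ...] = ()

    def __post_init__(self) -> None:
        if self.interval_roles[0] != "cue" or self.interval_roles[3] != "cue":
            raise UsageError("first and fourth intervals must be cue standards")
        if self.target_position not in ("choiceA", "choiceB"):
            raise UsageError("target_position must be choiceA or choiceB")


def choose_target_position(rng: np.random.Generator) -> str:
    """Fair coin over the two forced-choice slots."""
    return "choiceA" if rng.random() < 0.5 else "choiceB"


def _synthesize(spec, calib, rng, sample_rate):
    if isinstance(spec, FMToneSpec):
        # carrier roves independently per interval, uniform over [460, 550] Hz
        roved = replace(spec, carrier_hz=float(rng.uniform(460.0, 550.0)))
        return synth_fm_tone(roved, calib, seed=rng, sample_rate=sample_rate)
    if isinstance(spec, GapStimulusSpec):
        return synth_gap_pair(spec, calib, sample_rate=sample_rate)
    if isinstance(spec, ModulatedNoiseSpec):
        return synth_modulated_noise(spec, calib, seed=rng, sample_rate=sample_rate)
    raise UsageError(f"unsupported spec type {type(spec).__name__}")


def make_trial(
    standard_spec,
    target_spec,
    calib: CalibrationMap | None = None,
    seed: int | np.random.Generator | None = None,
    isi_s: float = 0.25,
    sample_rate: int = 44100,
) -> TrialLayout:
    """Assemble a seeded four-interval trial with synthesized audio.

    Intervals 1 and 4 are standards (cues); the target lands in interval 2
    or 3 with probability 1/2.  FM carriers rove per interval.
    """
    if type(standard_spec) is not type(target_spec):
        raise UsageError("standard and target specs must be the same kind")
    if getattr(standard_spec, "duration_s", None) != getattr(target_spec, "duration_s", None):
        raise UsageError("standard and target must share duration")
    if standard_spec.level_db_spl != target_spec.level_db_spl:
        raise UsageError("standard and target must share level")
    calib = calib or CalibrationMap()
    rng = np.random.default_rng(seed)
    position = choose_target_position(rng)
    roles = ("cue", "choiceA", "choiceB", "cue")
    specs = [
        standard_spec,
        target_spec if position == "choiceA" else standard_spec,
        target_spec if position == "choiceB" else standard_spec,
        standard_spec,
    ]
    intervals = tuple(_synthesize(s, calib, rng, sample_rate) for s in specs)
    return TrialLayout(roles, position, isi_s, intervals)


# ---------------------------------------------------------------------------
# simulated task runs


@dataclass
class TrackResult:
    """Threshold estimate plus the full trial-by-trial record."""

    threshold: float
    converged: bool
    n_trials: int
    n_reversals: int
    history: tuple[tuple[float, bool], ...]
    reversals: tuple[float, ...]
    reversal_trials: tuple[int, ...] = ()  # 1-based trial numbers

    def history_rows(self) -> list[dict]:
        rev = set(self.reversal_trials)
        return [
            {"trial": i + 1, "level": level, "correct": int(correct), "reversal": int(i + 1 in rev)}
            for i, (level, correct) in enumerate(self.history)
        ]


def run_adaptive_task(
    respond: Callable[[float], bool],
    config: AdaptiveConfig,
) -> TrackResult:
    """Run one adaptive track against a response model.

    ``respond(level)`` answers one trial at the given level (the listener's
    simulated 2C-2AFC decision, trial-by-trial feedback being implicit in the
    tracking rule).  Deterministic given the response model and its RNG.
    A track that hits ``max_trials`` with too few reversals is returned
    flagged (``converged=False``), not raised.
    """
    state = new_staircase(config)
    reversal_trials: list[int] = []
    while not state.finished:
        n_rev = len(state.reversals)
        state = staircase_update(state, config, respond(state.level_log))
        if len(state.reversals) > n_rev:
            reversal_trials.append(len(state.history))
    est = estimate_threshold(state, config)
    return TrackResult(
        threshold=est.value,
        converged=est.converged,
        n_trials=len(state.history),
        n_reversals=len(state.reversals),
        history=state.history,
        reversals=state.reversals,
        reversal_trials=tuple(reversal_trials),
    )
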