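"""Trial schedulers and adaptive procedures.

Turns an observer (a synthetic :class:`~tidlearn.observers.ObserverParams`
or any responder callable) into tidy trial logs:

* method of constant stimuli for the TID tasks (fixed signed ``delta_t``
  levels, shuffled within blocks, presentation order randomized per trial);
* the two-phase adaptive staircase used for tone frequency discrimination
  (halve the Weber fraction after every correct response until the first
  error, then a 3-down-1-up transformed up-down rule with step factor 1.414,
  converging near 79.4% correct);
* the same-different contrast discrimination blocks (80% same trials);
* full multi-session experiment orchestration with observer learning between
  sessions.

Trial logs use a fixed tidy schema (one row per trial):
``subject_id, session, block, trial_index, task, level, order, response,
correct`` plus ``phase`` for staircase trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .observers import (
    AUD,
    VIS,
    GroupDesign,
    ObserverParams,
    evolve_observer,
    p_comparison_longer,
    p_correct_fd,
    simulate_cd_response,
)

__all__ = [
    "TRIAL_COLUMNS",
    "TrialRecord",
    "ConstantStimuliDesign",
    "StaircaseConfig",
    "StaircaseTrack",
    "auditory_tid_design",
    "visual_tid_design",
    "trials_to_frame",
    "run_constant_stimuli",
    "run_staircase",
    "replay_staircase",
    "staircase_trials",
    "run_cd_block",
    "run_experiment",
]

TRIAL_COLUMNS = (
    "subject_id",
    "session",
    "block",
    "trial_index",
    "task",
    "level",
    "order",
    "response",
    "correct",
    "phase",
)

#: default auditory and visual delta-t level sets (ms)
AUD_LEVELS = (-20.1, -13.4, -6.7, 6.7, 13.4, 20.1)
VIS_LEVELS = (-33.5, -20.1, -6.7, 6.7, 20.1, 33.5)


@dataclass(frozen=True)
class TrialRecord:
    """One trial of any task, in presentation coordinates.

    ``order`` is ``"comparison_first"``/``"standard_first"`` for the 2IFC
    tasks and ``"same"``/``"different"`` for the contrast task; ``response``
    is the judged presentation (``"first"``/``"second"``) for 2IFC and
    ``"same"``/``"different"`` for the contrast task.
    """

    subject_id: str
    session: int
    block: int
    trial_index: int
    task: str
    level: float
    order: str
    response: str
    correct: bool
    phase: Optional[int] = None


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy DataFrame with the fixed trial-log schema."""
    return pd.DataFrame([r.__dict__ for r in records], columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# method of constant stimuli


@dataclass(frozen=True)
class ConstantStimuliDesign:
    """Fixed-level 2IFC design for one TID condition."""

    modality: str
    standard_interval: float = 100.0
    levels: tuple[float, ...] = AUD_LEVELS
    reps_per_level_per_block: int = 10
    n_blocks: int = 5
    level_scale: float = 1.0  # optional per-subject widening of the level set

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ValueError("empty level list")
        if self.reps_per_level_per_block <= 0:
            raise ValueError("reps_per_level_per_block must be > 0")
        if self.n_blocks <= 0:
            raise ValueError("n_blocks must be > 0")
        if self.level_scale <= 0:
            raise ValueError("level_scale must be > 0")

    @property
    def block_size(self) -> int:
        return len(self.levels) * self.reps_per_level_per_block

    @property
    def scaled_levels(self) -> tuple[float, ...]:
        return tuple(self.level_scale * lv for lv in self.levels)


def auditory_tid_design(**kwargs) -> ConstantStimuliDesign:
    kwargs.setdefault("levels", AUD_LEVELS)
    return ConstantStimuliDesign(modality=AUD, **kwargs)


def visual_tid_design(**kwargs) -> ConstantStimuliDesign:
    kwargs.setdefault("levels", VIS_LEVELS)
    return ConstantStimuliDesign(modality=VIS, **kwargs)


Responder = Callable[[str, float, str, np.random.Generator], str]


def run_constant_stimuli(
    design: ConstantStimuliDesign,
    responder: Union[ObserverParams, Responder],
    rng: np.random.Generator,
    *,
    subject_id: str = "s00",
    session: int = 1,
    task: Optional[str] = None,
    start_block: int = 1,
) -> list[TrialRecord]:
    """Run ``n_blocks`` constant-stimuli blocks.

    Each block presents every level exactly ``reps_per_level_per_block``
    times in shuffled order; the standard/comparison presentation order is a
    fair coin per trial.  ``responder`` is either an observer (simulated with
    the closed-form choice probability) or a callable
    ``(modality, delta_t, order, rng) -> "first" | "second"`` reporting which
    presentation held the longer interval.
    """
    if task is None:
        task = "tid_aud" if design.modality == AUD else "tid_vis"
    records: list[TrialRecord] = []
    base = np.repeat(np.asarray(design.scaled_levels, dtype=float),
                     design.reps_per_level_per_block)
    for b in range(design.n_blocks):
        levels = base[rng.permutation(base.size)]
        comp_first = rng.random(levels.size) < 0.5
        if isinstance(responder, ObserverParams):
            sigma = responder.effective_sigma(design.modality)
            phi = ndtr(levels / (sigma * math.sqrt(2.0)))
            p = (1.0 - responder.lapse) * phi + responder.lapse / 2.0
            report_comp = rng.random(levels.size) < p
        else:
            report_comp = np.empty(levels.size, dtype=bool)
            for i, dt in enumerate(levels):
                order = "comparison_first" if comp_first[i] else "standard_first"
                resp = responder(design.modality, float(dt), order, rng)
                if resp not in ("first", "second"):
                    raise ValueError("responder must return 'first' or 'second'")
                report_comp[i] = (resp == "first") == comp_first[i]
        for i, dt in enumerate(levels):
            order = "comparison_first" if comp_first[i] else "standard_first"
            response = "first" if report_comp[i] == comp_first[i] else "second"
            correct = bool(report_comp[i] == (dt > 0))
            records.append(
                TrialRecord(
                    subject_id=subject_id,
                    session=session,
                    block=start_block + b,
                    trial_index=i + 1,
                    task=task,
                    level=float(dt),
                    order=order,
                    response=response,
                    correct=correct,
                )
            )
    return records


# ---------------------------------------------------------------------------
# two-phase adaptive staircase


@dataclass(frozen=True)
class StaircaseConfig:
    """Two-phase staircase: halving until the first error, then 3-down-1-up."""

    start_level: float = 0.50
    phase1_factor: float = 2.0
    phase2_factor: float = 1.414
    n_down: int = 3
    n_trials: int = 60
    threshold_window: int = 40

    def __post_init__(self) -> None:
        if self.start_level <= 0:
            raise ValueError("start_level must be > 0")
        if self.phase1_factor <= 1 or self.phase2_factor <= 1:
            raise ValueError("step factors must be > 1")
        if self.n_down < 1:
            raise ValueError("n_down must be >= 1")
        if self.n_trials < self.threshold_window:
            raise ValueError("n_trials must be >= threshold_window")


@dataclass(frozen=True)
class StaircaseTrack:
    """Per-trial record of one staircase run."""

    config: StaircaseConfig
    levels: np.ndarray  # level presented on each trial
    correct: np.ndarray  # bool per trial
    phase: np.ndarray  # 1 or 2 per trial

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.correct) == len(self.phase)):
            raise ValueError("track arrays must have equal length")

    @property
    def reversals(self) -> list[int]:
        """Trial indices (0-based) at which the level-change direction flips."""
        signs = np.sign(np.diff(np.log(self.levels)))
        idx: list[int] = []
        last = 0.0
        for i, s in enumerate(signs):
            if s == 0:
                continue
            if last != 0 and s != last:
                idx.append(i + 1)
            last = s
        return idx


CorrectFn = Callable[[float, np.random.Generator], bool]


def _as_correct_fn(
    responder: Union[ObserverParams, CorrectFn]
) -> CorrectFn:
    if isinstance(responder, ObserverParams):
        def fn(level: float, rng: np.random.Generator) -> bool:
            return bool(rng.random() < p_correct_fd(responder, level))
        return fn
    return responder


def run_staircase(
    config: StaircaseConfig,
    responder: Union[ObserverParams, CorrectFn],
    rng: np.random.Generator,
) -> StaircaseTrack:
    """Run one staircase of exactly ``config.n_trials`` trials.

    Phase 1: the level is divided by ``phase1_factor`` after every correct
    response; the first error switches to phase 2 (and steps the level up).
    Phase 2: 3-down-1-up — after ``n_down`` consecutive correct responses the
    level is divided by ``phase2_factor`` and the counter resets; every error
    multiplies the level by ``phase2_factor`` and resets the counter.
    """
    correct_fn = _as_correct_fn(responder)
    level = config.start_level
    phase = 1
    streak = 0
    levels = np.empty(config.n_trials)
    correct = np.empty(config.n_trials, dtype=bool)
    phases = np.empty(config.n_trials, dtype=int)
    for t in range(config.n_trials):
        levels[t] = level
        phases[t] = phase
        c = bool(correct_fn(level, rng))
        correct[t] = c
        if phase == 1:
            if c:
                level /= config.phase1_factor
            else:
                phase = 2
                level *= config.phase2_factor
                streak = 0
        else:
            if c:
                streak += 1
                if streak == config.n_down:
                    level /= config.phase2_factor
                    streak = 0
            else:
                level *= config.phase2_factor
                streak = 0
    return StaircaseTrack(config=config, levels=levels, correct=correct,
                          phase=phases)


def replay_staircase(
    config: StaircaseConfig, correctness: Sequence[bool]
) -> StaircaseTrack:
    """Deterministically replay a logged correctness sequence through the
    staircase rules; the level sequence is a pure function of it."""
    seq = iter([bool(c) for c in correctness])

    def fn(level: float, rng: np.random.Generator) -> bool:
        try:
            return next(seq)
        except StopIteration as exc:  # pragma: no cover - guarded by config
            raise ValueError("correctness sequence shorter than n_trials") from exc

    cfg = StaircaseConfig(
        start_level=config.start_level,
        phase1_factor=config.phase1_factor,
        phase2_factor=config.phase2_factor,
        n_down=config.n_down,
        n_trials=len(correctness),
        threshold_window=min(config.threshold_window, len(correctness)),
    )
    return run_staircase(cfg, fn, np.random.default_rng(0))


def staircase_trials(
    track: StaircaseTrack,
    rng: np.random.Generator,
    *,
    subject_id: str = "s00",
    session: int = 1,
    block: int = 1,
) -> list[TrialRecord]:
    """Expand a staircase track into tidy 2IFC trial records (presentation
    order drawn per trial)."""
    records = []
    comp_first = rng.random(len(track.levels)) < 0.5
    for t, (lv, c, ph) in enumerate(
        zip(track.levels, track.correct, track.phase)
    ):
        order = "comparison_first" if comp_first[t] else "standard_first"
        chose_comp = bool(c)  # comparison is always the higher frequency
        response = "first" if chose_comp == comp_first[t] else "second"
        records.append(
            TrialRecord(
                subject_id=subject_id,
                session=session,
                block=block,
                trial_index=t + 1,
                task="fd",
                level=float(lv),
                order=order,
                response=response,
                correct=bool(c),
                phase=int(ph),
            )
        )
    return records


# ---------------------------------------------------------------------------
# same-different contrast discrimination


CdResponder = Callable[[bool, np.random.Generator], str]


def run_cd_block(
    n_trials: int,
    responder: Union[ObserverParams, CdResponder],
    rng: np.random.Generator,
    *,
    same_fraction: float = 0.8,
    contrast_range: tuple[float, float] = (0.15, 1.0),
    difference: float = 0.5,
    subject_id: str = "s00",
    session: int = 1,
    block: int = 1,
) -> list[TrialRecord]:
    """Run one same-different contrast block with stratified trial counts.

    ``round(n_trials * same_fraction)`` trials are "same" (both Gabors at a
    common contrast drawn uniformly from ``contrast_range``); the rest differ
    by ``difference`` (c2 = c1 * (1 + difference), c1 redrawn until c2 stays
    within range; which Gabor is the higher one is randomized).  The ``level``
    column records the signed contrast difference fraction (0 for same).
    """
    if not (0.0 < same_fraction <= 1.0):
        raise ValueError("same_fraction must lie in (0, 1]")
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    n_same = int(round(n_trials * same_fraction))
    labels = np.zeros(n_trials, dtype=bool)
    labels[:n_same] = True
    labels = labels[rng.permutation(n_trials)]
    lo, hi = contrast_range
    records = []
    for t, same in enumerate(labels):
        if same:
            level = 0.0
        else:
            while True:  # redraw until the incremented contrast stays in range
                c1 = rng.uniform(lo, hi)
                if c1 * (1.0 + difference) <= hi:
                    break
            level = difference if rng.random() < 0.5 else -difference
        if isinstance(responder, ObserverParams):
            resp = simulate_cd_response(responder, bool(same), rng)
        else:
            resp = responder(bool(same), rng)
        if resp not in ("same", "different"):
            raise ValueError("responder must return 'same' or 'different'")
        correct = (resp == "same") == bool(same)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                session=session,
                block=block,
                trial_index=t + 1,
                task="cd",
                level=float(level),
                order="same" if same else "different",
                response=resp,
                correct=bool(correct),
            )
        )
    return records


# ---------------------------------------------------------------------------
# experiment orchestration


def _measurement_design(task: str, level_scale: float = 1.0,
                        n_blocks: int = 5) -> ConstantStimuliDesign:
    if task == "tid_aud":
        return auditory_tid_design(n_blocks=n_blocks, level_scale=level_scale)
    if task == "tid_vis":
        return visual_tid_design(n_blocks=n_blocks, level_scale=level_scale)
    raise ValueError(f"constant stimuli only measure TID tasks, got {task!r}")


def _subject_level_scale(observer: ObserverParams, task: str) -> float:
    """Per-subject widening/narrowing of the TID level set.

    Emulates the experimenter adjusting the intervals between stimulus levels
    before the pre-test to ensure a sufficient range of correct rates: the
    level set is scaled by the subject's baseline threshold scale factor so
    every subject is sampled at comparable points of the psychometric range.
    """
    return observer.scale_aud if task == "tid_aud" else observer.scale_vis


def _run_task_block(
    task: str,
    observer: ObserverParams,
    rng: np.random.Generator,
    subject_id: str,
    session: int,
    block: int,
) -> list[TrialRecord]:
    """One 60-trial training block of any task."""
    if task in ("tid_aud", "tid_vis"):
        design = _measurement_design(
            task, level_scale=_subject_level_scale(observer, task), n_blocks=1
        )
        return run_constant_stimuli(
            design, observer, rng, subject_id=subject_id, session=session,
            task=task, start_block=block,
        )
    if task == "fd":
        track = run_staircase(StaircaseConfig(), observer, rng)
        return staircase_trials(
            track, rng, subject_id=subject_id, session=session, block=block
        )
    if task == "cd":
        return run_cd_block(
            60, observer, rng, subject_id=subject_id, session=session,
            block=block,
        )
    raise ValueError(f"unknown task {task!r}")


def run_experiment(
    design: GroupDesign,
    observers: Sequence[ObserverParams],
    rng: np.random.Generator,
    *,
    subject_prefix: str = "s",
) -> pd.DataFrame:
    """Simulate the full multi-session experiment for one condition.

    Sessions 1 and ``n_sessions`` are pre/post measurement sessions running
    ``blocks_pretest`` constant-stimuli blocks for every tested TID task
    (non-TID tested tasks run ``blocks_pretest`` task blocks instead).
    Intermediate sessions are training sessions: 16 blocks of
    the primary task, or 10 + 10 strictly alternating blocks for double
    training.  The observer state evolves between training sessions.
    """
    if len(observers) != design.n_subjects:
        raise ValueError(
            f"{design.condition_name!r} expects {design.n_subjects} observers, "
            f"got {len(observers)}"
        )
    all_records: list[TrialRecord] = []
    subject_rngs = rng.spawn(design.n_subjects)
    for s_idx, (obs, srng) in enumerate(zip(observers, subject_rngs)):
        sid = f"{subject_prefix}{s_idx:02d}"
        state = obs
        for session in range(1, design.n_sessions + 1):
            block = 1
            if session in (1, design.n_sessions):
                for task in design.tested_tasks:
                    if task in ("tid_aud", "tid_vis"):
                        d = _measurement_design(
                            task,
                            level_scale=_subject_level_scale(state, task),
                            n_blocks=design.blocks_pretest,
                        )
                        all_records.extend(
                            run_constant_stimuli(
                                d, state, srng, subject_id=sid,
                                session=session, task=task, start_block=block,
                            )
                        )
                        block += design.blocks_pretest
                    else:
                        for _ in range(design.blocks_pretest):
                            all_records.extend(
                                _run_task_block(task, state, srng, sid,
                                                session, block)
                            )
                            block += 1
            else:
                if design.is_double:
                    for _ in range(design.blocks_double_training):
                        for task in design.training_tasks:
                            all_records.extend(
                                _run_task_block(task, state, srng, sid,
                                                session, block)
                            )
                            block += 1
                else:
                    for _ in range(design.blocks_single_training):
                        all_records.extend(
                            _run_task_block(design.primary_task, state, srng,
                                            sid, session, block)
                        )
                        block += 1
                state = evolve_observer(state, design, session)
    return trials_to_frame(all_records)
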