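"""Synthetic observers for cross-modal temporal-interval discrimination (TID).

The latent model is standard equal-variance Gaussian signal detection for a
two-interval forced choice: each of the two presented intervals is perceived
with additive Gaussian noise, so the decision variable for "the comparison
interval is longer" is ``delta_t`` corrupted by noise of standard deviation
``sigma_m * sqrt(2)``, where ``sigma_m`` is the observer's effective
interval-coding noise in modality ``m``.  The effective noise combines a
supramodal (central) component shared across audition and vision with a
modality-specific component:

    sigma_m = scale_m * gain_m * sqrt(sigma_central**2 + sigma_m_specific**2)

``gain_m`` is the learning state (1.0 before training, shrinking
multiplicatively with practice), ``scale_m`` a static per-subject size factor
used to generate log-normal between-subject threshold variation.

Learning and transfer operate on the log-threshold scale: a training session
on the TID task of modality ``m`` multiplies ``gain_m`` by ``(1 - learn_rate)``,
and multiplies the untrained modality's gain by ``(1 - learn_rate)**gate``,
where the per-direction transfer gates express what fraction of the trained
log improvement reaches the untrained modality.  Under conventional single
training the audition-to-vision gate is partial and the vision-to-audition
gate is zero; under double training (TID training coupled with an orthogonal
task that exposes the untrained modality to the same interval) the relevant
gate is 1, producing complete transfer.  This is a calibration of the
published effect structure, not a mechanistic claim.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AUD",
    "VIS",
    "TASKS",
    "ObserverParams",
    "GroupDesign",
    "GroupEffect",
    "GROUP_EFFECTS",
    "DEFAULT_DESIGNS",
    "LEARN_RATE_AUD",
    "LEARN_RATE_VIS",
    "LEARN_RATE_FD",
    "CD_LEARN_STEP",
    "default_observer",
    "default_observers",
    "p_comparison_longer",
    "p_correct_fd",
    "simulate_tid_choice",
    "simulate_fd_choice",
    "simulate_cd_response",
    "evolve_observer",
    "sample_group_improvements",
]

AUD = "aud"
VIS = "vis"
#: task identifiers used throughout the trial logs
TASKS = ("tid_aud", "tid_vis", "fd", "cd")

_SQRT2 = math.sqrt(2.0)
#: half-interquartile width of a standard normal (z at p = 0.75)
_Z75 = 0.6744897501960817

# ---------------------------------------------------------------------------
# Default learning calibration.  Per-session rates are chosen so that the
# expected measured spans of the synthetic population equal the group-mean
# improvements the generator is designed to emulate:
#   * trained auditory TID: 0.30 log10 units over the 5 training sessions
#   * trained visual TID:   0.20 log10 units over the 5 training sessions
#   * tone frequency discrimination: 0.17 log10 units over the observable
#     4-step span between the first and last training session
#   * visual contrast discrimination: 0.84 d' over the same 4-step span
LEARN_RATE_AUD = 1.0 - 10.0 ** (-0.30 / 5.0)
LEARN_RATE_VIS = 1.0 - 10.0 ** (-0.20 / 5.0)
LEARN_RATE_FD = 1.0 - 10.0 ** (-0.17 / 4.0)
CD_LEARN_STEP = 0.84 / 4.0

#: fraction of trained log improvement transferred audition -> vision under
#: single training (0.12 of 0.30); vision -> audition transfers nothing.
TRANSFER_GATE_AV_SINGLE = 0.40
TRANSFER_GATE_VA_SINGLE = 0.0

#: log10 SD of between-subject threshold scale (log-normal population)
_SUBJECT_SCALE_SD = 0.15
#: relative SD of between-subject learning-rate variation
_LEARN_JITTER_REL = 0.30


@dataclass(frozen=True)
class ObserverParams:
    """Latent parameters of one synthetic observer.

    Noise parameters are in milliseconds of perceived interval; ``freq_jnd``
    is a Weber fraction on (log) tone frequency; ``contrast_sens`` is the
    mean of the internal difference signal (hence the recoverable d') in the
    contrast same-different task.
    """

    sigma_central: float = 12.0
    sigma_aud: float = 10.0
    sigma_vis: float = 29.0
    lapse: float = 0.02
    freq_jnd: float = 0.05
    contrast_sens: float = 1.2
    learn_rate: float = LEARN_RATE_AUD
    learn_rate_fd: float = LEARN_RATE_FD
    cd_learn_step: float = CD_LEARN_STEP
    transfer_gate_av: float = TRANSFER_GATE_AV_SINGLE
    transfer_gate_va: float = TRANSFER_GATE_VA_SINGLE
    # learning state: multiplicative gains on the effective modality noise
    gain_aud: float = 1.0
    gain_vis: float = 1.0
    # static per-subject modality scale factors (between-subject variation)
    scale_aud: float = 1.0
    scale_vis: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma_central > 0):
            raise ValueError("sigma_central must be > 0")
        if self.sigma_aud < 0 or self.sigma_vis < 0:
            raise ValueError("modality-specific noise must be >= 0")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must lie in [0, 0.1]")
        if not (self.freq_jnd > 0):
            raise ValueError("freq_jnd must be > 0")
        if self.contrast_sens < 0:
            raise ValueError("contrast_sens must be >= 0")
        if not (0.0 <= self.learn_rate < 1.0):
            raise ValueError("learn_rate must lie in [0, 1)")
        if not (0.0 <= self.learn_rate_fd < 1.0):
            raise ValueError("learn_rate_fd must lie in [0, 1)")
        for g in (self.transfer_gate_av, self.transfer_gate_va):
            if not (0.0 <= g <= 1.0):
                raise ValueError("transfer gates must lie in [0, 1]")
        for g in (self.gain_aud, self.gain_vis, self.scale_aud, self.scale_vis):
            if not (g > 0):
                raise ValueError("gains/scales must be > 0")

    def effective_sigma(self, modality: str) -> float:
        """Effective interval-coding noise SD (ms) for one modality."""
        if modality == AUD:
            base = math.hypot(self.sigma_central, self.sigma_aud)
            return self.scale_aud * self.gain_aud * base
        if modality == VIS:
            base = math.hypot(self.sigma_central, self.sigma_vis)
            return self.scale_vis * self.gain_vis * base
        raise ValueError(f"unknown modality {modality!r}")

    def tid_threshold(self, modality: str) -> float:
        """Expected lapse-free TID threshold (half interquartile range, ms).

        For a probit observer the half-IQR equals ``z(.75) * sigma * sqrt(2)
        ~= 0.954 * sigma``.
        """
        return _Z75 * _SQRT2 * self.effective_sigma(modality)


@dataclass(frozen=True)
class GroupDesign:
    """One named training condition of the study design."""

    condition_name: str
    n_subjects: int
    primary_task: str
    secondary_task: Optional[str]
    tested_tasks: tuple[str, ...]
    n_sessions: int = 7
    blocks_single_training: int = 16
    blocks_double_training: int = 10  # per task, alternating -> 20 blocks
    blocks_pretest: int = 5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.primary_task not in TASKS:
            raise ValueError(f"unknown primary task {self.primary_task!r}")
        if self.secondary_task is not None and self.secondary_task not in TASKS:
            raise ValueError(f"unknown secondary task {self.secondary_task!r}")
        if self.n_sessions < 2:
            raise ValueError("need at least pre and post sessions")

    @property
    def is_double(self) -> bool:
        return self.secondary_task is not None

    @property
    def training_sessions(self) -> range:
        """Session indices (1-based) on which training blocks are run."""
        return range(2, self.n_sessions)

    @property
    def training_tasks(self) -> tuple[str, ...]:
        if self.secondary_task is None:
            return (self.primary_task,)
        return (self.primary_task, self.secondary_task)


#: the six training conditions with their group sizes (total n = 49)
DEFAULT_DESIGNS: dict[str, GroupDesign] = {
    "auditory_single": GroupDesign(
        "auditory_single", 7, "tid_aud", None, ("tid_aud", "tid_vis")
    ),
    "visual_single": GroupDesign(
        "visual_single", 9, "tid_vis", None, ("tid_vis", "tid_aud")
    ),
    "visual_double_FD": GroupDesign(
        "visual_double_FD", 9, "tid_vis", "fd", ("tid_vis", "tid_aud")
    ),
    "FD_control": GroupDesign("FD_control", 8, "fd", None, ("tid_aud",)),
    "auditory_double_CD": GroupDesign(
        "auditory_double_CD", 8, "tid_aud", "cd", ("tid_aud", "tid_vis")
    ),
    "CD_control": GroupDesign("CD_control", 8, "cd", None, ("tid_vis",)),
}


@dataclass(frozen=True)
class GroupEffect:
    """Calibration target for one (condition, measure): mean +/- SE at n.

    Improvements are in log10 units for threshold measures and in d' for the
    contrast task.
    """

    mean: float
    se: float
    n: int

    @property
    def sd(self) -> float:
        return self.se * math.sqrt(self.n)


#: group-mean improvements the synthetic population is calibrated to emulate
GROUP_EFFECTS: dict[tuple[str, str], GroupEffect] = {
    ("auditory_single", "tid_aud"): GroupEffect(0.30, 0.08, 7),
    ("auditory_single", "tid_vis"): GroupEffect(0.12, 0.04, 7),
    ("visual_single", "tid_vis"): GroupEffect(0.20, 0.05, 9),
    ("visual_single", "tid_aud"): GroupEffect(0.05, 0.05, 9),
    ("visual_double_FD", "tid_vis"): GroupEffect(0.21, 0.03, 9),
    ("visual_double_FD", "tid_aud"): GroupEffect(0.24, 0.04, 9),
    ("visual_double_FD", "fd"): GroupEffect(0.17, 0.05, 9),
    ("FD_control", "fd"): GroupEffect(0.17, 0.05, 8),
    ("FD_control", "tid_aud"): GroupEffect(-0.03, 0.07, 8),
    ("auditory_double_CD", "tid_aud"): GroupEffect(0.29, 0.04, 8),
    ("auditory_double_CD", "tid_vis"): GroupEffect(0.26, 0.03, 8),
    ("auditory_double_CD", "cd"): GroupEffect(0.37, 0.20, 8),
    ("CD_control", "cd"): GroupEffect(0.84, 0.15, 8),
    ("CD_control", "tid_vis"): GroupEffect(0.04, 0.03, 8),
}


# ---------------------------------------------------------------------------
# choice models


def _validate_modality(modality: str) -> None:
    if modality not in (AUD, VIS):
        raise ValueError(f"unknown modality {modality!r}")


def p_comparison_longer(
    observer: ObserverParams, modality: str, delta_t: float
) -> float:
    """Closed-form P(report "comparison interval longer") at signed ``delta_t``.

    Equal-variance 2IFC model: ``(1 - lapse) * Phi(delta_t / (sigma*sqrt(2)))
    + lapse / 2``.
    """
    _validate_modality(modality)
    if not math.isfinite(delta_t):
        raise ValueError("delta_t must be finite")
    if abs(delta_t) >= 100.0:
        raise ValueError("|delta_t| must be < 100 ms (standard interval)")
    sigma = observer.effective_sigma(modality)
    phi = 0.5 * (1.0 + math.erf(delta_t / (sigma * _SQRT2) / _SQRT2))
    return (1.0 - observer.lapse) * phi + observer.lapse / 2.0


def simulate_tid_choice(
    observer: ObserverParams,
    modality: str,
    delta_t: float,
    rng: np.random.Generator,
) -> str:
    """Simulate one TID judgement; returns ``"comparison_longer"`` or
    ``"standard_longer"``."""
    p = p_comparison_longer(observer, modality, delta_t)
    return "comparison_longer" if rng.random() < p else "standard_longer"


def p_correct_fd(observer: ObserverParams, delta_f: float) -> float:
    """Closed-form P(correct) in the 2IFC tone frequency discrimination task.

    ``delta_f`` is the Weber fraction of the comparison above the standard;
    the internal noise SD on log frequency is ``freq_jnd``.
    """
    if not math.isfinite(delta_f) or delta_f < 0:
        raise ValueError("delta_f must be finite and >= 0")
    phi = 0.5 * (1.0 + math.erf(delta_f / (observer.freq_jnd * _SQRT2) / _SQRT2))
    return (1.0 - observer.lapse) * phi + observer.lapse / 2.0


def simulate_fd_choice(
    observer: ObserverParams, delta_f: float, rng: np.random.Generator
) -> str:
    """Simulate one frequency judgement; returns which pair was reported
    higher, ``"comparison"`` or ``"standard"`` (comparison is the higher one,
    so ``"comparison"`` is correct whenever ``delta_f > 0``)."""
    p = p_correct_fd(observer, delta_f)
    return "comparison" if rng.random() < p else "standard"


def simulate_cd_response(
    observer: ObserverParams, same_trial: bool, rng: np.random.Generator
) -> str:
    """Simulate one same-different contrast judgement.

    A unit-variance internal difference signal has mean 0 on same trials and
    ``contrast_sens`` on different trials; "different" is reported when the
    signal exceeds the unbiased criterion ``contrast_sens / 2``, so the
    recoverable d' equals ``contrast_sens``.
    """
    if rng.random() < observer.lapse:
        return "different" if rng.random() < 0.5 else "same"
    mean = 0.0 if same_trial else observer.contrast_sens
    x = rng.normal(mean, 1.0)
    return "different" if x > observer.contrast_sens / 2.0 else "same"


# ---------------------------------------------------------------------------
# learning dynamics


def evolve_observer(
    observer: ObserverParams, condition: GroupDesign, session_index: int
) -> ObserverParams:
    """Return the observer after one training session of ``condition``.

    ``session_index`` is the 1-based session just completed and must be one
    of the condition's training sessions.  Trained-task noise shrinks
    multiplicatively; TID training additionally propagates to the untrained
    modality through the direction-specific transfer gate (exponent on the
    per-session shrink factor, i.e. a fraction of the log improvement).
    """
    if session_index not in condition.training_sessions:
        raise ValueError(
            f"session {session_index} is not a training session of "
            f"{condition.condition_name!r}"
        )
    updates: dict[str, float] = {}
    for task in condition.training_tasks:
        keep = 1.0 - observer.learn_rate
        if task == "tid_aud":
            updates["gain_aud"] = updates.get("gain_aud", observer.gain_aud) * keep
            updates["gain_vis"] = (
                updates.get("gain_vis", observer.gain_vis)
                * keep**observer.transfer_gate_av
            )
        elif task == "tid_vis":
            updates["gain_vis"] = updates.get("gain_vis", observer.gain_vis) * keep
            updates["gain_aud"] = (
                updates.get("gain_aud", observer.gain_aud)
                * keep**observer.transfer_gate_va
            )
        elif task == "fd":
            updates["freq_jnd"] = observer.freq_jnd * (1.0 - observer.learn_rate_fd)
        elif task == "cd":
            updates["contrast_sens"] = (
                observer.contrast_sens + observer.cd_learn_step
            )
    return dataclasses.replace(observer, **updates)


def default_observer(
    condition: GroupDesign, rng: Optional[np.random.Generator] = None
) -> ObserverParams:
    """Default-calibrated observer for one condition.

    Without ``rng`` the population-mean observer is returned (useful for
    analytic expectations).  With ``rng``, between-subject heterogeneity is
    sampled: log-normal threshold scales, jittered learning rates.
    """
    if condition.primary_task == "tid_vis":
        learn_rate = LEARN_RATE_VIS
    else:
        learn_rate = LEARN_RATE_AUD
    gate_av, gate_va = TRANSFER_GATE_AV_SINGLE, TRANSFER_GATE_VA_SINGLE
    if condition.is_double:
        # the orthogonal secondary task exposes the untrained modality to the
        # trained interval: the corresponding gate opens completely
        if condition.primary_task == "tid_aud" and condition.secondary_task == "cd":
            gate_av = 1.0
        if condition.primary_task == "tid_vis" and condition.secondary_task == "fd":
            gate_va = 1.0
    kwargs: dict[str, float] = dict(
        learn_rate=learn_rate,
        transfer_gate_av=gate_av,
        transfer_gate_va=gate_va,
    )
    if rng is not None:
        kwargs["scale_aud"] = 10.0 ** rng.normal(0.0, _SUBJECT_SCALE_SD)
        kwargs["scale_vis"] = 10.0 ** rng.normal(0.0, _SUBJECT_SCALE_SD)
        kwargs["freq_jnd"] = 0.05 * 10.0 ** rng.normal(0.0, _SUBJECT_SCALE_SD)
        kwargs["contrast_sens"] = 1.2 * 10.0 ** rng.normal(0.0, 0.1)
        jit = 1.0 + _LEARN_JITTER_REL * rng.normal()
        kwargs["learn_rate"] = float(np.clip(learn_rate * jit, 0.0, 0.45))
        jit_fd = 1.0 + _LEARN_JITTER_REL * rng.normal()
        kwargs["learn_rate_fd"] = float(np.clip(LEARN_RATE_FD * jit_fd, 0.0, 0.45))
        jit_cd = 1.0 + _LEARN_JITTER_REL * rng.normal()
        kwargs["cd_learn_step"] = float(max(CD_LEARN_STEP * jit_cd, 0.0))
    return ObserverParams(**kwargs)


def default_observers(
    condition: GroupDesign, rng: np.random.Generator
) -> list[ObserverParams]:
    """One heterogeneous observer per subject, from independent sub-streams."""
    streams = rng.spawn(condition.n_subjects)
    return [default_observer(condition, r) for r in streams]


# ---------------------------------------------------------------------------
# group-level shortcut generator


def sample_group_improvements(
    condition: str,
    n: int,
    rng: np.random.Generator,
    task: Optional[str] = None,
) -> pd.DataFrame:
    """Draw per-subject pre/post measures directly from the group-level
    calibration (Normal improvements), bypassing trial simulation.

    For threshold measures (TID, FD) pre/post are log10 thresholds and the
    improvement is ``pre - post`` in log units; for the contrast task pre and
    post are d' values and the improvement is ``post - pre``.  Used to
    exercise the stats module independently of the trial-level engines.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if task is None:
        task = {
            "auditory_single": "tid_aud",
            "visual_single": "tid_vis",
            "visual_double_FD": "tid_vis",
            "FD_control": "fd",
            "auditory_double_CD": "tid_aud",
            "CD_control": "cd",
        }.get(condition)
    key = (condition, task)
    if key not in GROUP_EFFECTS:
        raise KeyError(f"unknown condition/measure {key!r}")
    eff = GROUP_EFFECTS[key]
    if eff.sd == 0:
        raise ValueError("degenerate group: zero between-subject SD")
    improvement = rng.normal(eff.mean, eff.sd, size=n)
    if task == "cd":
        pre = 1.2 + rng.normal(0.0, 0.2, size=n)
        post = pre + improvement
    else:
        baseline = {
            "tid_aud": math.log10(ObserverParams().tid_threshold(AUD)),
            "tid_vis": math.log10(ObserverParams().tid_threshold(VIS)),
            "fd": math.log10(0.058),
        }[task]
        pre = baseline + rng.normal(0.0, _SUBJECT_SCALE_SD, size=n)
        post = pre - improvement
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:02d}" for i in range(n)],
            "condition": condition,
            "task": task,
            "pre": pre,
            "post": post,
            "improvement": improvement,
        }
    )
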