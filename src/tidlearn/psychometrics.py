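"""Threshold and sensitivity estimation from trial logs.

* :func:`fit_logistic` — maximum-likelihood fit of the two-parameter logistic
  psychometric function ``P(delta_t) = 1 / (1 + exp(-k (delta_t - delta_t0)))``
  to trial-level Bernoulli outcomes ("comparison reported longer"), with the
  TID threshold defined as half the interquartile range of the fitted curve,
  which for this logistic is exactly ``ln(3) / k``.
* :func:`staircase_threshold` — mean level over the final window of a
  staircase track (arithmetic by default, geometric optionally).
* :func:`dprime_same_different` — signal-detection sensitivity for the
  same-different contrast task, ``d' = z(hit rate) - z(false-alarm rate)``
  with the 1/(2N) extreme-rate correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .engines import StaircaseTrack, TrialRecord, trials_to_frame

__all__ = [
    "PsychometricFit",
    "DPrimeResult",
    "fit_logistic",
    "fit_logistic_xy",
    "staircase_threshold",
    "dprime_same_different",
    "session_results",
]

LN3 = math.log(3.0)


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted logistic psychometric function.

    ``threshold = ln(3) / k`` (half the interquartile range); ``delta_t0`` is
    the point of subjective equivalence, at which the fitted probability of
    reporting the comparison longer is exactly 0.5.
    """

    k: float
    delta_t0: float
    threshold: float
    n_trials: int
    levels: tuple[float, ...]
    prop_comparison_longer: tuple[float, ...]
    converged: bool
    separated: bool = False
    nll: float = math.nan
    flag: Optional[str] = None

    def predict(self, delta_t):
        """Fitted P(report comparison longer)."""
        return expit(self.k * (np.asarray(delta_t, dtype=float) - self.delta_t0))


def _report_comparison_longer(df: pd.DataFrame) -> np.ndarray:
    """Recover the "comparison judged longer" indicator from presentation
    coordinates."""
    first = df["response"].to_numpy() == "first"
    comp_first = df["order"].to_numpy() == "comparison_first"
    return first == comp_first


def fit_logistic_xy(
    x: np.ndarray, y: np.ndarray, *, max_iter: int = 100, tol: float = 1e-12
) -> PsychometricFit:
    """Trial-level Bernoulli MLE of the logistic psychometric function.

    ``x`` are signed delta-t levels (ms); ``y`` indicates "comparison
    reported longer".  Equivalent to a logistic regression of ``y`` on ``x``;
    fitted by Newton-Raphson on the two-parameter log-likelihood.  Perfectly
    separated data (a cut point on ``x`` classifies every response) have no
    finite MLE: the fit is flagged and the threshold reported at the smallest
    absolute level as an upper bound.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct levels to fit")
    if y.all() or (~y).all():
        raise ValueError("need both response types to fit")
    levels = tuple(float(v) for v in uniq)
    props = tuple(float(y[x == v].mean()) for v in uniq)
    # perfect separation: every "longer" response lies strictly above every
    # "not longer" response on the level axis
    if x[y].min() > x[~y].max():
        floor = float(np.abs(x).min())
        return PsychometricFit(
            k=math.nan, delta_t0=math.nan, threshold=floor,
            n_trials=x.size, levels=levels, prop_comparison_longer=props,
            converged=False, separated=True,
            flag="separated: threshold below smallest |level|",
        )
    beta = np.zeros(2)  # (intercept, slope)
    X = np.column_stack([np.ones_like(x), x])
    yf = y.astype(float)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        grad = X.T @ (yf - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    k = float(beta[1])
    if not np.isfinite(k) or k <= 0:
        raise ValueError(f"fitted slope k = {k:.4g} is not positive")
    delta_t0 = float(-beta[0] / beta[1])
    p = expit(X @ beta)
    eps = 1e-12
    nll = float(-np.sum(yf * np.log(p + eps) + (1 - yf) * np.log(1 - p + eps)))
    return PsychometricFit(
        k=k, delta_t0=delta_t0, threshold=LN3 / k, n_trials=x.size,
        levels=levels, prop_comparison_longer=props, converged=converged,
        nll=nll,
    )


def fit_logistic(
    trials: Union[pd.DataFrame, Sequence[TrialRecord]]
) -> PsychometricFit:
    """Fit the psychometric function to the TID trials of one
    subject/session/task slice of a tidy trial log."""
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    x = df["level"].to_numpy(dtype=float)
    y = _report_comparison_longer(df)
    return fit_logistic_xy(x, y)


def fit_logistic_proportions(
    levels: np.ndarray, proportions: np.ndarray, n_per_level: np.ndarray
) -> PsychometricFit:
    """Least-squares fit to per-level proportions (comparability fallback to
    the trial-level MLE; same parameterization)."""
    from scipy.optimize import least_squares

    levels = np.asarray(levels, dtype=float)
    proportions = np.asarray(proportions, dtype=float)

    def resid(params):
        k, dt0 = params
        return expit(k * (levels - dt0)) - proportions

    res = least_squares(resid, x0=[0.05, 0.0])
    k, dt0 = res.x
    if k <= 0:
        raise ValueError("fitted slope k is not positive")
    return PsychometricFit(
        k=float(k), delta_t0=float(dt0), threshold=LN3 / float(k),
        n_trials=int(np.sum(n_per_level)), levels=tuple(levels),
        prop_comparison_longer=tuple(proportions), converged=res.success,
        flag="least-squares on proportions",
    )


# ---------------------------------------------------------------------------
# staircase threshold


def staircase_threshold(
    track: Union[StaircaseTrack, np.ndarray],
    *,
    window: int = 40,
    method: str = "arithmetic",
) -> float:
    """Threshold of a staircase run: mean level over the last ``window``
    trials (arithmetic mean of Weber fractions by default; a geometric mean
    is available since the staircase steps are multiplicative)."""
    levels = track.levels if isinstance(track, StaircaseTrack) else np.asarray(track)
    if len(levels) < window:
        raise ValueError(f"track has {len(levels)} trials, need >= {window}")
    tail = np.asarray(levels, dtype=float)[-window:]
    if method == "arithmetic":
        return float(tail.mean())
    if method == "geometric":
        return float(np.exp(np.log(tail).mean()))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# same-different sensitivity


@dataclass(frozen=True)
class DPrimeResult:
    """d' for a set of same-different trials (yes/no model, "different" as
    the signal response)."""

    hits: int
    false_alarms: int
    n_signal: int
    n_noise: int
    hit_rate: float
    fa_rate: float
    dprime: float


def _clamp_rate(count: int, n: int) -> float:
    lo = 1.0 / (2.0 * n)
    return min(max(count / n, lo), 1.0 - lo)


def dprime_same_different(
    records: Union[pd.DataFrame, Sequence[TrialRecord]]
) -> DPrimeResult:
    """Score same-different trials: hits are "different" responses on
    different trials (``level != 0``), false alarms "different" responses on
    same trials; extreme rates are clamped to ``1/(2N)`` before the normal
    quantile transform."""
    df = records if isinstance(records, pd.DataFrame) else trials_to_frame(records)
    signal = df["level"].to_numpy(dtype=float) != 0.0
    said_diff = df["response"].to_numpy() == "different"
    n_signal = int(signal.sum())
    n_noise = int((~signal).sum())
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need both same and different trials for d'")
    hits = int(said_diff[signal].sum())
    fas = int(said_diff[~signal].sum())
    hr = _clamp_rate(hits, n_signal)
    far = _clamp_rate(fas, n_noise)
    return DPrimeResult(
        hits=hits, false_alarms=fas, n_signal=n_signal, n_noise=n_noise,
        hit_rate=hr, fa_rate=far, dprime=float(ndtri(hr) - ndtri(far)),
    )


# ---------------------------------------------------------------------------
# session-level results table


def session_results(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject/session/task results from a tidy trial log.

    TID tasks are fitted with the logistic psychometric function (threshold in
    ms), FD staircase blocks are summarized by the mean of each block's last
    40 levels averaged across blocks (Weber fraction), and the contrast task
    by pooled-session d'.  Output columns: ``subject_id, session, task,
    threshold, k, pse, dprime, flag``.
    """
    rows = []
    for (sid, session, task), grp in trials.groupby(
        ["subject_id", "session", "task"], sort=True
    ):
        threshold = k = pse = dprime = math.nan
        flag = None
        if task in ("tid_aud", "tid_vis"):
            fit = fit_logistic(grp)
            threshold, k, pse, flag = fit.threshold, fit.k, fit.delta_t0, fit.flag
        elif task == "fd":
            per_block = [
                staircase_threshold(b.sort_values("trial_index")["level"].to_numpy())
                for _, b in grp.groupby("block")
            ]
            threshold = float(np.mean(per_block))
        elif task == "cd":
            dprime = dprime_same_different(grp).dprime
        rows.append(
            {
                "subject_id": sid,
                "session": int(session),
                "task": task,
                "threshold": threshold,
                "k": k,
                "pse": pse,
                "dprime": dprime,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
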