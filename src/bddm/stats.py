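"""Behavioral summaries and group statistics: consistency scoring,
psychometric/chronometric level summaries, the efficiency index, and Welch's
unequal-variance t-test."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import PerceptualTrial, TrialTable, ValueTrial
from .exceptions import DegenerateInputError

__all__ = [
    "score_trial",
    "summarize_levels",
    "efficiency_index",
    "welch_t",
    "WelchResult",
    "fit_choice_slope",
]


def score_trial(trial) -> float:
    """Consistency/accuracy score in {0, 0.5, 1}.

    Value trials score 1 when the chosen item has the strictly higher value,
    0 when lower, 0.5 on exact ties.  Perceptual trials score 1 when the
    choice matches the sign of the coherence, 0 otherwise, and 0.5 whenever
    the coherence is zero.
    """
    if not trial.valid:
        raise ValueError("score_trial requires a valid trial")
    if isinstance(trial, ValueTrial):
        dv = trial.value_right - trial.value_left
        if dv == 0:
            return 0.5
        return 1.0 if (dv > 0) == bool(trial.chose_right) else 0.0
    if isinstance(trial, PerceptualTrial):
        if trial.coherence == 0:
            return 0.5
        return 1.0 if (trial.coherence > 0) == bool(trial.chose_blue) else 0.0
    raise TypeError(f"unsupported trial type {type(trial)!r}")


def summarize_levels(
    trials: TrialTable, strengths: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-level choice proportion and RT summary.

    ``strengths`` assigns each trial to a level (e.g. the representative
    values from binning); by default perceptual trials group by coherence and
    value trials by raw delta-value.  Returns a frame with columns
    ``level_strength, p_choice, mean_rt, sem_rt, n`` where ``p_choice`` is
    the proportion of right/blue choices.  Only valid trials contribute.
    """
    mask = np.array([t.valid for t in trials], dtype=bool)
    if strengths is None:
        strengths = trials.strengths()
    strengths = np.asarray(strengths, dtype=float)[mask]
    valid = trials.valid_trials()
    chose = valid.choices()
    rts = valid.rts()
    rows = []
    for s in np.unique(strengths):
        sel = strengths == s
        n = int(sel.sum())
        r = rts[sel]
        sem = float(r.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append(
            {
                "level_strength": float(s),
                "p_choice": float(chose[sel].mean()),
                "mean_rt": float(r.mean()),
                "sem_rt": sem,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def efficiency_index(trials: TrialTable) -> pd.DataFrame:
    """Per-subject efficiency: mean accuracy divided by mean RT (1/s).

    Subjects with no valid trials are excluded with a warning.  Returns a
    frame with columns ``subject, group, accuracy, mean_rt, i_e``.
    """
    rows = []
    for subject in trials.subjects():
        sub = [t for t in trials if t.subject == subject and t.valid]
        if not sub:
            warnings.warn(f"subject {subject!r} has no valid trials; excluded",
                          stacklevel=2)
            continue
        scores = np.array([score_trial(t) for t in sub])
        rts = np.array([t.rt for t in sub])
        acc = float(scores.mean())
        mean_rt = float(rts.mean())
        rows.append(
            {
                "subject": subject,
                "group": sub[0].group or trials.group,
                "accuracy": acc,
                "mean_rt": mean_rt,
                "i_e": acc / mean_rt,
            }
        )
    return pd.DataFrame(rows)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's two-sample t-test (unequal variances).

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateInputError("degenerate (zero) variance in both groups")
    na, nb = len(a), len(b)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (na - 1) + se2b**2 / (nb - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p)


def fit_choice_slope(strengths, chose) -> tuple[float, float]:
    """Two-parameter logistic MLE of choice on stimulus strength.

    Returns ``(intercept, slope)``; the slope measures choice sensitivity
    (flatter choice functions give smaller slopes).
    """
    from scipy.optimize import minimize
    from scipy.special import expit

    s = np.asarray(strengths, dtype=float)
    y = np.asarray(chose, dtype=float)

    def nll(beta):
        p = np.clip(expit(beta[0] + beta[1] * s), 1e-12, 1 - 1e-12)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    res = minimize(nll, np.zeros(2), method="BFGS")
    return float(res.x[0]), float(res.x[1])
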