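"""Rule-based alternative to the diffusion model.

Items are classified by two value criteria into highly desirable (``D+``),
highly undesirable (``D-``) or middling (``D~``).  Pairs that the rules
resolve ("trivial": D+ against anything else, or D- against D~) get fast
Gaussian RTs and a near-deterministic choice of the forced side; same-category
pairs ("non-trivial") get slow Gaussian RTs and a logistic choice in the
value difference.

Two likelihood conventions are provided for the trivial choice term:

* ``fit`` mode: probability ``p_trivial`` (0.99 by default) for
  rule-consistent choices, ``1 - p_trivial`` for exceptions.
* ``bic_eval`` mode: the probability is taken from the non-trivial logistic
  evaluated at the dataset's maximum absolute value difference (and its
  complement for exceptions), the convention used for model-comparison
  statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np

from .exceptions import DegenerateInputError

__all__ = [
    "HeuristicParams",
    "ItemCategory",
    "TrialClass",
    "classify_value",
    "trial_class",
    "choice_prob_nontrivial",
    "heuristic_nll",
    "n_free_params",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ItemCategory(Enum):
    D_PLUS = "D+"
    D_MINUS = "D-"
    D_MID = "D~"


@dataclass(frozen=True)
class HeuristicParams:
    """Parameters of the rule-based model.

    ``kappa1 <= kappa2`` are the value criteria separating D-, D~ and D+.
    ``p_trivial`` is the probability assigned to rule-consistent trivial
    choices; it is fixed at 0.99 in the standard variant and free in the
    trembling-hand variant.
    """

    kappa1: float
    kappa2: float
    mu_fast: float
    sigma_fast: float
    mu_slow: float
    sigma_slow: float
    beta0: float
    beta1: float
    p_trivial: float = 0.99

    def __post_init__(self) -> None:
        if self.kappa1 > self.kappa2:
            raise ValueError("kappa1 must not exceed kappa2")
        if not (self.sigma_fast > 0 and self.sigma_slow > 0):
            raise ValueError("RT standard deviations must be positive")
        if not 0.5 < self.p_trivial < 1.0:
            raise ValueError("p_trivial must lie in (0.5, 1)")


@dataclass(frozen=True)
class TrialClass:
    """Trivial/non-trivial designation; trivial trials carry the forced side."""

    trivial: bool
    forced_side: Literal["left", "right", None] = None


def n_free_params(variant: str) -> int:
    """Degrees of freedom: 8 for the fixed-p variant (criteria, two RT
    Gaussians, two logistic coefficients), 9 when p_trivial is free."""
    if variant == "fixed":
        return 8
    if variant == "trembling":
        return 9
    raise ValueError(f"unknown heuristic variant {variant!r}")


def classify_value(v: float, params: HeuristicParams) -> ItemCategory:
    """Category of a single item value; values exactly at a criterion fall in
    the middling class."""
    if v < params.kappa1:
        return ItemCategory.D_MINUS
    if v > params.kappa2:
        return ItemCategory.D_PLUS
    return ItemCategory.D_MID


def trial_class(left: ItemCategory, right: ItemCategory) -> TrialClass:
    """Resolve a pair of item categories to a trial class.

    D+ against any other category forces the D+ item; D- against D~ forces
    the D~ item; same-category pairs are non-trivial.
    """
    if left == right:
        return TrialClass(trivial=False)
    if left == ItemCategory.D_PLUS:
        return TrialClass(trivial=True, forced_side="left")
    if right == ItemCategory.D_PLUS:
        return TrialClass(trivial=True, forced_side="right")
    # remaining mixed case: D- vs D~ -> choose the middling item
    if left == ItemCategory.D_MID:
        return TrialClass(trivial=True, forced_side="left")
    return TrialClass(trivial=True, forced_side="right")


def choice_prob_nontrivial(delta_value: float, params: HeuristicParams) -> float:
    """Probability of choosing the right item on a non-trivial trial:
    ``logistic(beta0 + beta1 * delta_value)``."""
    z = params.beta0 + params.beta1 * delta_value
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def _log_normal_pdf(x: float, mu: float, sigma: float) -> float:
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI


def heuristic_nll(
    trials,
    params: HeuristicParams,
    mode: Literal["fit", "bic_eval"] = "fit",
    floor: float = 1e-10,
) -> float:
    """Joint choice/RT negative log-likelihood of a value trial table.

    RT terms are plain Gaussians (fast for trivial trials, slow for
    non-trivial).  The trivial choice term depends on ``mode`` (see module
    docs).  Only valid trials may be passed.
    """
    trial_list = [t for t in trials if t.valid]
    if not trial_list:
        raise DegenerateInputError("heuristic_nll requires at least one valid trial")
    if mode not in ("fit", "bic_eval"):
        raise ValueError(f"unknown mode {mode!r}")
    vl = np.array([t.value_left for t in trial_list])
    vr = np.array([t.value_right for t in trial_list])
    rt = np.array([t.rt for t in trial_list])
    chose_right = np.array([t.chose_right for t in trial_list], dtype=bool)
    dv = vr - vl
    if mode == "bic_eval":
        p_triv = choice_prob_nontrivial(float(np.max(np.abs(dv))), params)
        p_triv = min(max(p_triv, floor), 1.0 - floor)
    else:
        p_triv = params.p_trivial

    # item categories as ordinals: D- = 0, D~ = 1, D+ = 2
    def cat(v):
        return np.where(v < params.kappa1, 0, np.where(v > params.kappa2, 2, 1))

    cl, cr = cat(vl), cat(vr)
    trivial = cl != cr
    forced_right = cr > cl  # D+ beats all; D~ beats D-

    nll = 0.0
    # RT terms: fast Gaussian on trivial trials, slow on non-trivial
    for mask, mu, sigma in (
        (trivial, params.mu_fast, params.sigma_fast),
        (~trivial, params.mu_slow, params.sigma_slow),
    ):
        if mask.any():
            z = (rt[mask] - mu) / sigma
            nll += float(np.sum(0.5 * z * z)) + mask.sum() * (
                math.log(sigma) + _LOG_SQRT_2PI
            )
    # choice terms
    consistent = forced_right == chose_right
    n_cons = int(np.sum(trivial & consistent))
    n_exc = int(np.sum(trivial & ~consistent))
    nll -= n_cons * math.log(p_triv) + n_exc * math.log(1.0 - p_triv)
    if (~trivial).any():
        z = params.beta0 + params.beta1 * dv[~trivial]
        p_right = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        p = np.where(chose_right[~trivial], p_right, 1.0 - p_right)
        nll -= float(np.sum(np.log(np.maximum(p, floor))))
    return nll
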