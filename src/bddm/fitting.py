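"""Maximum-likelihood fitting (multi-start Nelder-Mead), model variants,
BIC comparison and goodness-of-fit statistics.

Parameters are bounded by a logistic coordinate transform so the simplex
search runs unconstrained; random starts are drawn uniformly within the
bounds from a seeded generator, making multi-start fits reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .datamodel import TrialTable
from .ddm import (
    DDMParams,
    SolverGrid,
    loglik_by_strength,
    rt_density,
)
from .exceptions import DegenerateInputError, OptimizationError
from .heuristic import (
    HeuristicParams,
    choice_prob_nontrivial,
    classify_value,
    heuristic_nll,
    n_free_params,
    trial_class,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "BinResult",
    "DDM_BOUNDS",
    "fit_ddm",
    "fit_heuristic",
    "bin_delta_value",
    "bic_compare",
    "mcfadden_r2",
    "rt_r2",
]

#: fitting bounds for the diffusion parameters (low, high); these cover the
#: published best-fit ranges with margin
DDM_BOUNDS: dict[str, tuple[float, float]] = {
    "kappa": (1e-3, 40.0),
    "b0": (0.2, 5.0),
    "b_del": (0.0, 3.0),
    "b2": (0.01, 10.0),
    "tnd": (0.1, 1.0),
    "sigma_tnd": (0.001, 0.5),
    "mu0": (-5.0, 5.0),
    "plaw": (0.1, 3.0),
}

_DDM_ORDER = ["kappa", "b0", "b_del", "b2", "tnd", "sigma_tnd", "mu0", "plaw"]

_HEUR_ORDER = [
    "kappa1", "gap", "mu_fast", "sigma_fast", "mu_slow", "sigma_slow",
    "beta0", "beta1", "p_trivial",
]


@dataclass
class FitConfig:
    """Settings shared by the DDM and heuristic fitters."""

    n_starts: int = 100
    seed: int = 0
    bounds: dict | None = None
    xatol: float = 1e-3
    fatol: float = 1e-3
    maxiter: int | None = None          # Nelder-Mead iteration cap per start
    n_polish: int = 3                   # best phase-1 starts refined further
    polish_maxiter: int | None = None   # default: 4x the phase-1 cap
    variant: str = "full"
    grid: SolverGrid | None = None      # explicit solver grid (else auto)
    dt: float = 2.5e-3                  # auto-grid resolution used in fitting
    n_x: int = 100
    round_step: float | None = None     # delta-value rounding (dollars)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Best-of-starts maximum-likelihood fit summary.

    ``bic = 2 * nll_bic + n_params * ln(n_trials)`` where ``nll_bic`` defaults
    to the fitted NLL; the fixed-p heuristic substitutes its model-comparison
    (bic-eval) NLL there.
    """

    params: DDMParams | HeuristicParams
    nll: float
    n_trials: int
    n_params: int
    r2_choice: float | None = None
    r2_rt: float | None = None
    nll_bic: float | None = None
    model: str = "ddm"
    variant: str = "full"

    @property
    def bic(self) -> float:
        nll = self.nll if self.nll_bic is None else self.nll_bic
        return 2.0 * nll + self.n_params * math.log(self.n_trials)

    def summary(self) -> dict:
        d = {k: getattr(self.params, k) for k in self.params.__dataclass_fields__}
        d.update(
            model=self.model, variant=self.variant, nll=self.nll, bic=self.bic,
            n_trials=self.n_trials, n_params=self.n_params,
            r2_choice=self.r2_choice, r2_rt=self.r2_rt,
        )
        return d


class _BoundedVector:
    """Logistic mapping between bounded parameters and unconstrained space."""

    def __init__(self, names: Sequence[str], bounds: dict):
        self.names = list(names)
        self.lo = np.array([bounds[n][0] for n in names])
        self.hi = np.array([bounds[n][1] for n in names])

    def external(self, z: np.ndarray) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * expit(z)

    def internal(self, x: np.ndarray) -> np.ndarray:
        frac = np.clip((np.asarray(x) - self.lo) / (self.hi - self.lo), 1e-9, 1 - 1e-9)
        return logit(frac)

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        return self.internal(self.lo + (self.hi - self.lo) * rng.uniform(0.1, 0.9, len(self.lo)))


def _nm(objective, z0, maxiter, xatol, fatol):
    return minimize(
        objective, z0, method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol,
                 "maxiter": maxiter, "maxfev": maxiter},
    )


def _multistart(objective, vec: _BoundedVector, config: FitConfig,
                informed: list[np.ndarray] | None = None):
    """Two-phase multi-start Nelder-Mead.

    Phase 1 runs a capped simplex search from every start (seeded random
    draws within the bounds, plus any data-informed candidates); phase 2
    re-runs the best ``n_polish`` solutions to convergence.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(config.seed)
    maxiter = config.maxiter or 60 * len(vec.names)
    polish_maxiter = config.polish_maxiter or 4 * maxiter
    starts = list(informed or [])
    starts += [vec.random_start(rng) for _ in range(config.n_starts)]
    stage1 = []
    for z0 in starts:
        res = _nm(objective, z0, maxiter, 10 * config.xatol, 10 * config.fatol)
        if math.isfinite(res.fun):
            stage1.append(res)
    if not stage1:
        raise OptimizationError(
            f"all {len(starts)} starts failed to produce a finite objective"
        )
    stage1.sort(key=lambda r: r.fun)
    best = stage1[0]
    for res in stage1[: max(1, config.n_polish)]:
        polished = _nm(objective, res.x, polish_maxiter,
                       config.xatol, config.fatol)
        if math.isfinite(polished.fun) and polished.fun < best.fun:
            best = polished
    return best


# ---------------------------------------------------------------------------
# DDM fitting
# ---------------------------------------------------------------------------

def _ddm_free_names(variant: str) -> tuple[list[str], dict]:
    if variant == "full":
        return list(_DDM_ORDER), {}
    if variant == "no_plaw":
        return [n for n in _DDM_ORDER if n != "plaw"], {"plaw": 1.0}
    if variant in ("no_plaw_flat", "no_plaw_flat_bounds"):
        fixed = {"plaw": 1.0, "b_del": math.inf, "b2": 1.0}
        return [n for n in _DDM_ORDER if n not in fixed], fixed
    raise ValueError(f"unknown DDM variant {variant!r}")


def _make_grid(params: DDMParams, deadline: float, config: FitConfig) -> SolverGrid:
    if config.grid is not None:
        return config.grid
    return SolverGrid.for_params(params, deadline, dt=config.dt, n_x=config.n_x)


def fit_ddm(
    trials: TrialTable,
    config: FitConfig | None = None,
    strengths: np.ndarray | None = None,
) -> FitResult:
    """Fit the bounded diffusion model to a trial table by multi-start
    Nelder-Mead on the joint choice/RT likelihood.

    ``strengths`` overrides per-trial stimulus strengths (e.g. the
    representative values from :func:`bin_delta_value`); otherwise value
    tables use the (optionally rounded) value difference and perceptual
    tables use the signed coherence.

    Variants: ``full`` (8 free parameters), ``no_plaw`` (power law fixed to
    1), ``no_plaw_flat`` (additionally disables the bound collapse).
    """
    config = config or FitConfig()
    valid = trials.valid_trials()
    if strengths is None:
        strengths = valid.strengths(round_step=config.round_step)
    else:
        strengths = np.asarray(strengths, dtype=float)
        if len(strengths) == len(trials) and len(valid) != len(trials):
            strengths = strengths[np.array([t.valid for t in trials])]
    if len(np.unique(strengths)) < 2:
        raise DegenerateInputError("fit_ddm requires >= 2 distinct strength levels")
    chose = valid.choices()
    rts = valid.rts()
    deadline = trials.deadline
    names, fixed = _ddm_free_names(config.variant)
    bounds = dict(DDM_BOUNDS)
    if config.bounds:
        bounds.update(config.bounds)
    vec = _BoundedVector(names, bounds)

    def build(z: np.ndarray) -> DDMParams:
        kw = dict(zip(names, vec.external(z)))
        kw.update(fixed)
        if not math.isfinite(kw["b_del"]):  # flat bounds: collapse never starts
            kw["b_del"] = deadline + 1.0
        return DDMParams(**kw)

    def objective(z: np.ndarray) -> float:
        try:
            params = build(z)
            grid = _make_grid(params, deadline, config)
            return -float(
                np.sum(loglik_by_strength(strengths, chose, rts, params, grid))
            )
        except Exception:
            return math.inf

    informed = [_ddm_informed_start(strengths, chose, rts, names, vec)]
    best = _multistart(objective, vec, config, informed=informed)
    params = build(best.x)
    grid = _make_grid(params, deadline, config)
    r2c, r2t = _ddm_fit_r2(strengths, chose, rts, params, grid)
    return FitResult(
        params=params,
        nll=float(best.fun),
        n_trials=len(valid),
        n_params=len(names),
        r2_choice=r2c,
        r2_rt=r2t,
        model="ddm",
        variant=config.variant,
    )


def _ddm_informed_start(strengths, chose, rts, names, vec: _BoundedVector):
    """Moment-based starting point added to the random multi-start pool.

    The non-decision time starts just below the fastest responses, the drift
    scale comes from the logistic choice slope (P(upper) ~ logistic(2*kappa*
    b0*s) for flat bounds), and the remaining parameters start mid-range.
    """
    from .stats import fit_choice_slope

    b0_guess = 1.0
    tnd_guess = 0.9 * float(np.quantile(rts, 0.02))
    try:
        _, slope = fit_choice_slope(strengths, chose)
        kappa_guess = abs(slope) / (2.0 * b0_guess)
    except Exception:
        kappa_guess = 1.0
    defaults = {
        "kappa": kappa_guess, "b0": b0_guess, "b_del": 0.4, "b2": 1.0,
        "tnd": tnd_guess, "sigma_tnd": 0.05, "mu0": 0.0, "plaw": 1.0,
    }
    x = np.array([
        np.clip(defaults[n], vec.lo[i] + 1e-6 * (vec.hi[i] - vec.lo[i]),
                vec.hi[i] - 1e-6 * (vec.hi[i] - vec.lo[i]))
        for i, n in enumerate(names)
    ])
    return vec.internal(x)


def _ddm_fit_r2(strengths, chose, rts, params, grid):
    """McFadden pseudo-R2 for choices and level-wise R2 for mean RT."""
    uniq = np.unique(strengths)
    p_up = np.empty(len(uniq))
    model_rt = np.empty(len(uniq))
    obs_rt = np.empty(len(uniq))
    p_trial = np.empty(len(strengths))
    for i, s in enumerate(uniq):
        dens = rt_density(float(s), params, grid)
        mu_mass = np.sum(dens.d_upper) * dens.dt
        ml_mass = np.sum(dens.d_lower) * dens.dt
        p_up[i] = mu_mass / (mu_mass + ml_mass)
        tot = dens.d_upper + dens.d_lower
        model_rt[i] = float(
            np.sum(dens.times * tot) / np.sum(tot)
        )
        mask = strengths == s
        obs_rt[i] = rts[mask].mean()
        p_trial[mask] = p_up[i]
    try:
        r2c = mcfadden_r2(chose, p_trial)
    except DegenerateInputError:
        r2c = None
    try:
        r2t = rt_r2(obs_rt, model_rt)
    except DegenerateInputError:
        r2t = None
    return r2c, r2t


# ---------------------------------------------------------------------------
# Heuristic fitting
# ---------------------------------------------------------------------------

def fit_heuristic(
    trials: TrialTable,
    config: FitConfig | None = None,
    variant: Literal["fixed", "trembling"] = "fixed",
) -> FitResult:
    """Fit the rule-based model by multi-start Nelder-Mead.

    The ``fixed`` variant keeps the trivial-choice probability at 0.99 (8
    free parameters, matching the DDM) and reports its model-comparison NLL
    (bic-eval convention) through ``nll_bic``; the ``trembling`` variant
    frees that probability (9 parameters).
    """
    config = config or FitConfig()
    valid = trials.valid_trials()
    if len(valid) == 0:
        raise DegenerateInputError("no valid trials to fit")
    if trials.kind != "value":
        raise ValueError("the heuristic model applies to value trials")
    rts = valid.rts()
    values = np.array([[t.value_left, t.value_right] for t in valid])
    vlo, vhi = float(values.min()), float(values.max())
    vrange = max(vhi - vlo, 1e-6)
    rt_hi = float(rts.max())
    bounds = {
        "kappa1": (vlo - 0.05 * vrange, vhi + 0.05 * vrange),
        "gap": (0.0, 1.1 * vrange),
        "mu_fast": (0.05, 1.5 * rt_hi),
        "sigma_fast": (0.01, rt_hi),
        "mu_slow": (0.05, 1.5 * rt_hi),
        "sigma_slow": (0.01, rt_hi),
        "beta0": (-10.0, 10.0),
        "beta1": (-5.0, 60.0),
        "p_trivial": (0.5 + 1e-6, 1.0 - 1e-6),
    }
    if config.bounds:
        bounds.update(config.bounds)
    names = list(_HEUR_ORDER)
    if variant == "fixed":
        names.remove("p_trivial")
    elif variant != "trembling":
        raise ValueError(f"unknown heuristic variant {variant!r}")
    vec = _BoundedVector(names, bounds)

    def build(z: np.ndarray) -> HeuristicParams:
        kw = dict(zip(names, vec.external(z)))
        gap = kw.pop("gap")
        kw["kappa2"] = kw["kappa1"] + gap
        kw.setdefault("p_trivial", 0.99)
        return HeuristicParams(**kw)

    def objective(z: np.ndarray) -> float:
        try:
            return heuristic_nll(valid, build(z), mode="fit")
        except Exception:
            return math.inf

    # moment-based informed start: criteria at the value quantiles, RT
    # Gaussians from a fast/slow median split, logistic from all choices
    from .stats import fit_choice_slope

    fast, slow = rts[rts <= np.median(rts)], rts[rts > np.median(rts)]
    try:
        b0g, b1g = fit_choice_slope(
            np.array([t.value_right - t.value_left for t in valid]),
            valid.choices(),
        )
    except Exception:
        b0g, b1g = 0.0, 1.0
    guesses = {
        "kappa1": float(np.quantile(values, 0.2)),
        "gap": float(np.quantile(values, 0.8) - np.quantile(values, 0.2)),
        "mu_fast": float(fast.mean()), "sigma_fast": float(fast.std() + 0.01),
        "mu_slow": float(slow.mean()), "sigma_slow": float(slow.std() + 0.01),
        "beta0": b0g, "beta1": b1g, "p_trivial": 0.97,
    }
    x0 = np.array([
        np.clip(guesses[n], vec.lo[i] + 1e-6 * (vec.hi[i] - vec.lo[i]),
                vec.hi[i] - 1e-6 * (vec.hi[i] - vec.lo[i]))
        for i, n in enumerate(names)
    ])
    best = _multistart(objective, vec, config, informed=[vec.internal(x0)])
    params = build(best.x)
    k = n_free_params(variant)
    nll_bic = (
        heuristic_nll(valid, params, mode="bic_eval") if variant == "fixed" else None
    )
    r2c, r2t = _heuristic_fit_r2(valid, params)
    return FitResult(
        params=params,
        nll=float(best.fun),
        n_trials=len(valid),
        n_params=k,
        r2_choice=r2c,
        r2_rt=r2t,
        nll_bic=nll_bic,
        model="heuristic",
        variant=variant,
    )


def _heuristic_fit_r2(valid: TrialTable, params: HeuristicParams):
    chose = valid.choices()
    p_trial = np.empty(len(valid))
    exp_rt = np.empty(len(valid))
    for i, t in enumerate(valid):
        cls = trial_class(
            classify_value(t.value_left, params),
            classify_value(t.value_right, params),
        )
        if cls.trivial:
            p_right = params.p_trivial if cls.forced_side == "right" else 1 - params.p_trivial
            exp_rt[i] = params.mu_fast
        else:
            p_right = choice_prob_nontrivial(t.value_right - t.value_left, params)
            exp_rt[i] = params.mu_slow
        p_trial[i] = p_right
    try:
        r2c = mcfadden_r2(chose, np.clip(p_trial, 1e-9, 1 - 1e-9))
    except DegenerateInputError:
        r2c = None
    # level-wise RT fit on the trial classes' means
    strengths = valid.strengths()
    uniq = np.unique(strengths)
    if len(uniq) >= 2:
        rts = valid.rts()
        obs = np.array([rts[strengths == s].mean() for s in uniq])
        mod = np.array([exp_rt[strengths == s].mean() for s in uniq])
        try:
            r2t = rt_r2(obs, mod)
        except DegenerateInputError:
            r2t = None
    else:
        r2t = None
    return r2c, r2t


# ---------------------------------------------------------------------------
# Binning, comparison, goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class BinResult:
    """Outcome of delta-value binning.

    ``strengths`` maps each input trial to its level's representative value
    (the mean delta-value of the bin's members); ``levels`` lists the
    retained levels.
    """

    strengths: np.ndarray
    levels: list[dict]
    edges: np.ndarray


def bin_delta_value(
    trials: TrialTable,
    n_levels: int = 11,
    round_step: float | None = None,
) -> BinResult:
    """Assign value trials to fixed-boundary delta-value levels.

    Bin edges sit at midpoints between target levels obtained by scaling the
    11-level coherence set to the observed delta-value range (so the value
    levels mirror the perceptual task's discrete levels); each level's
    representative strength is the mean delta-value of its members.  A trial
    exactly on an edge goes to the upper bin.  Empty levels are dropped with
    a warning.
    """
    from .synthetic import COHERENCE_LEVELS

    if trials.kind != "value":
        raise ValueError("bin_delta_value applies to value tables")
    if n_levels != len(COHERENCE_LEVELS):
        template = np.linspace(-2.0, 2.0, n_levels)
    else:
        template = COHERENCE_LEVELS
    dv = trials.strengths(round_step=round_step)
    scale = np.max(np.abs(dv)) / np.max(np.abs(template))
    targets = template * scale
    edges = 0.5 * (targets[1:] + targets[:-1])
    idx = np.searchsorted(edges, dv, side="right")
    strengths = np.empty(len(dv))
    levels = []
    for lev in range(n_levels):
        mask = idx == lev
        if not mask.any():
            warnings.warn(f"delta-value level {lev} is empty; dropped", stacklevel=2)
            continue
        rep = float(dv[mask].mean())
        strengths[mask] = rep
        levels.append({"level": lev, "strength": rep, "n": int(mask.sum())})
    return BinResult(strengths=strengths, levels=levels, edges=edges)


def bic_compare(result_a: FitResult, result_b: FitResult) -> float:
    """BIC difference, b minus a (positive favors model a).

    When the two models have equal degrees of freedom this equals the
    deviance difference ``2*(nll_b - nll_a)``.
    """
    if result_a.n_trials != result_b.n_trials:
        raise ValueError(
            f"mismatched trial counts: {result_a.n_trials} vs {result_b.n_trials}"
        )
    return result_b.bic - result_a.bic


def mcfadden_r2(chose: np.ndarray, p_model: np.ndarray) -> float:
    """McFadden pseudo-R2: ``1 - LL_model / LL_null`` with an intercept-only
    Bernoulli null."""
    chose = np.asarray(chose, dtype=float)
    p_model = np.asarray(p_model, dtype=float)
    if np.any((p_model <= 0) | (p_model >= 1)):
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")
    p_null = chose.mean()
    if p_null in (0.0, 1.0):
        raise DegenerateInputError("all choices identical: null model degenerate")
    ll_model = float(np.sum(np.where(chose > 0, np.log(p_model), np.log1p(-p_model))))
    ll_null = float(
        len(chose) * (p_null * math.log(p_null) + (1 - p_null) * math.log(1 - p_null))
    )
    return 1.0 - ll_model / ll_null


def rt_r2(observed_means: np.ndarray, model_means: np.ndarray) -> float:
    """Coefficient of determination over per-level mean RTs."""
    obs = np.asarray(observed_means, dtype=float)
    mod = np.asarray(model_means, dtype=float)
    if len(obs) < 2:
        raise DegenerateInputError("rt_r2 requires >= 2 levels")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("zero total RT variance across levels")
    ss_res = float(np.sum((obs - mod) ** 2))
    return 1.0 - ss_res / ss_tot
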