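"""Bounded drift-diffusion model: drift, collapsing bounds, first-passage
densities, non-decision-time convolution, and the joint choice/RT likelihood.

The decision variable follows ``dx = mu*dt + dW`` (unit diffusion) from
``x=0`` between symmetric absorbing bounds ``+/-B(t)``.  The bound is constant
at ``b0`` until ``b_del`` and then collapses exponentially towards zero with
time constant ``b2``.  Drift depends on signed stimulus strength through a
power law: ``mu = kappa * sign(s) * |s|**plaw + mu0``.  Observed RT is the
first-passage (decision) time plus a Gaussian non-decision time (mean ``tnd``,
sd ``sigma_tnd``) truncated at zero.

First-passage densities are computed on a discrete grid by propagating the
evidence distribution with the exact Gaussian transition kernel over each
time step and truncating mass beyond the bounds (absorption).  Because the
bound is only monitored at discrete times, the absorption threshold is pulled
inward by the Broadie-Glasserman continuity correction ``0.5826*sqrt(dt)``,
which removes the leading-order discretization bias of discrete monitoring.
Partial grid cells at the bound are split by linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from numba import njit

from .exceptions import SolverAccuracyError

__all__ = [
    "DDMParams",
    "SolverGrid",
    "FirstPassage",
    "RTDensity",
    "drift_rate",
    "bound_height",
    "solve_first_passage",
    "apply_nondecision",
    "rt_density",
    "trial_loglik",
    "loglik_by_strength",
    "choice_prob",
]

#: continuity correction for discretely monitored absorbing barriers
_BG_BETA = 0.5826

#: per-trial likelihood floor keeping the simplex search finite
LIK_FLOOR = 1e-10


@dataclass(frozen=True)
class DDMParams:
    """The eight diffusion-model parameters.

    kappa : drift scale (1 / (evidence-unit**plaw * s))
    b0 : initial bound height (evidence units)
    b_del : collapse onset delay (s)
    b2 : collapse time constant (s)
    tnd : mean non-decision time (s)
    sigma_tnd : sd of non-decision time (s)
    mu0 : drift bias (1/s)
    plaw : power-law exponent on stimulus strength
    """

    kappa: float
    b0: float
    b_del: float
    b2: float
    tnd: float
    sigma_tnd: float
    mu0: float = 0.0
    plaw: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and self.b0 > 0 and self.b2 > 0):
            raise ValueError("kappa, b0 and b2 must be positive")
        if self.b_del < 0:
            raise ValueError("b_del must be non-negative")
        if not self.tnd > 0:
            raise ValueError("tnd must be positive")
        if self.sigma_tnd < 0:
            raise ValueError("sigma_tnd must be non-negative")
        if not self.plaw > 0:
            raise ValueError("plaw must be positive")


@dataclass(frozen=True)
class SolverGrid:
    """Discretization of the Fokker-Planck solve.

    dt : time step (s)
    t_max : horizon (s); should be >= the trial deadline
    dx : evidence-space step
    x_extent : half-width of the evidence grid (must exceed the bound plus
        the transition-kernel spread)
    mass_tol : tolerance on total probability conservation
    """

    dt: float = 5e-4
    t_max: float = 4.0
    dx: float = 0.01
    x_extent: float = 1.5
    mass_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.dx > 0 and self.t_max > 0):
            raise ValueError("dt, dx and t_max must be positive")

    @classmethod
    def for_params(
        cls,
        params: DDMParams,
        deadline: float,
        dt: float = 5e-4,
        n_x: int = 200,
    ) -> "SolverGrid":
        """Grid sized to the bound: about ``n_x`` points span [-b0, b0] and
        the horizon covers the deadline plus the non-decision spread.

        ``dx`` is clamped to [sqrt(dt)/3, sqrt(dt)/2] so the Gaussian
        transition kernel stays well sampled without the grid cost blowing
        up at extreme bound heights."""
        sig = math.sqrt(dt)
        dx = min(max(2.0 * params.b0 / n_x, sig / 3.0), sig / 2.0)
        extent = params.b0 + max(8.0 * math.sqrt(dt), 10 * dx)
        t_max = deadline + 4.0 * params.sigma_tnd
        return cls(dt=dt, t_max=t_max, dx=dx, x_extent=extent)

    @cached_property
    def times(self) -> np.ndarray:
        n_t = int(round(self.t_max / self.dt))
        return np.arange(n_t + 1) * self.dt


@dataclass(frozen=True)
class FirstPassage:
    """Discretized first-passage (decision-time) densities.

    ``g_upper``/``g_lower`` are densities (1/s) on ``times``; ``survivor`` is
    the probability mass not yet absorbed at ``t_max``.
    """

    times: np.ndarray
    g_upper: np.ndarray
    g_lower: np.ndarray
    survivor: float

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def prob_upper(self) -> float:
        return float(np.sum(self.g_upper) * self.dt)

    def prob_lower(self) -> float:
        return float(np.sum(self.g_lower) * self.dt)

    def mean_decision_time(self) -> float:
        """Mean decision time conditional on absorption (either bound)."""
        g = self.g_upper + self.g_lower
        mass = np.sum(g) * self.dt
        return float(np.sum(self.times * g) * self.dt / mass)


@dataclass(frozen=True)
class RTDensity:
    """RT densities per choice after non-decision-time convolution."""

    times: np.ndarray
    d_upper: np.ndarray
    d_lower: np.ndarray
    survivor: float
    tail_mass: float  # mass convolved past t_max

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def drift_rate(strength: float, params: DDMParams) -> float:
    """Drift ``mu = kappa * sign(s) * |s|**plaw + mu0``; zero strength gives
    the bias alone."""
    if strength == 0:
        return params.mu0
    s = math.copysign(1.0, strength)
    return params.kappa * s * abs(strength) ** params.plaw + params.mu0


def bound_height(t: float, params: DDMParams) -> float:
    """Symmetric bound magnitude at time ``t`` (constant, then exponential
    collapse)."""
    if t < params.b_del:
        return params.b0
    return params.b0 * math.exp(-(t - params.b_del) / params.b2)


@njit(cache=True)
def _propagate(p, kern, off_lo, n_t, dt, dx, ic, b0, b_del, b2, beta):
    """Time-step the evidence mass distribution; returns absorbed mass per
    step at each bound and the survivor mass."""
    nx = p.size
    nk = kern.size
    g_up = np.zeros(n_t + 1)
    g_lo = np.zeros(n_t + 1)
    q = np.zeros(nx)
    for it in range(1, n_t + 1):
        t = it * dt
        # exact Gaussian transition over dt
        for i in range(nx):
            acc = 0.0
            for k in range(nk):
                j = i - (off_lo + k)
                if 0 <= j < nx:
                    acc += kern[k] * p[j]
            q[i] = acc
        # collapsing bound with continuity correction
        if t < b_del:
            b = b0
        else:
            b = b0 * math.exp(-(t - b_del) / b2)
        b_eff = b - beta
        if b_eff < dx:
            b_eff = dx  # keep at least one interior cell
        # absorb mass beyond +/- b_eff with partial-cell splitting
        iu = int(math.floor(b_eff / dx + 0.5)) + ic   # cell containing +b_eff
        il = 2 * ic - iu                               # mirror cell at -b_eff
        up = 0.0
        for i in range(iu + 1, nx):
            up += q[i]
            q[i] = 0.0
        lo = 0.0
        for i in range(0, il):
            lo += q[i]
            q[i] = 0.0
        # boundary cells: keep the fraction of the cell inside the bound
        x_iu_lo = (iu - ic) * dx - 0.5 * dx
        frac_keep = (b_eff - x_iu_lo) / dx
        if frac_keep < 0.0:
            frac_keep = 0.0
        elif frac_keep > 1.0:
            frac_keep = 1.0
        up += q[iu] * (1.0 - frac_keep)
        q[iu] *= frac_keep
        lo += q[il] * (1.0 - frac_keep)
        q[il] *= frac_keep
        g_up[it] = up
        g_lo[it] = lo
        tmp = p
        p = q
        q = tmp
    surv = 0.0
    for i in range(p.size):
        surv += p[i]
    return g_up, g_lo, surv


def _transition_kernel(mu: float, grid: SolverGrid) -> tuple[np.ndarray, int]:
    """Discretized Gaussian transition kernel N(mu*dt, dt) on the x grid."""
    sig = math.sqrt(grid.dt)
    shift = mu * grid.dt / grid.dx
    half = int(math.ceil(6.0 * sig / grid.dx)) + 1
    off_lo = int(math.floor(shift)) - half
    off_hi = int(math.ceil(shift)) + half
    offs = np.arange(off_lo, off_hi + 1)
    z = (offs * grid.dx - mu * grid.dt) / sig
    w = np.exp(-0.5 * z * z)
    w /= w.sum()
    return w, off_lo


def solve_first_passage(
    strength: float, params: DDMParams, grid: SolverGrid
) -> FirstPassage:
    """Numerical first-passage densities for one stimulus strength.

    Raises :class:`SolverAccuracyError` if probability mass is not conserved
    within ``grid.mass_tol`` (grid too coarse).
    """
    mu = drift_rate(strength, params)
    if grid.x_extent <= params.b0:
        raise SolverAccuracyError(
            f"x_extent {grid.x_extent} does not span the initial bound {params.b0}"
        )
    nx = 2 * int(round(grid.x_extent / grid.dx)) + 1
    ic = nx // 2
    p = np.zeros(nx)
    p[ic] = 1.0
    kern, off_lo = _transition_kernel(mu, grid)
    n_t = len(grid.times) - 1
    g_up, g_lo, surv = _propagate(
        p, kern, off_lo, n_t, grid.dt, grid.dx, ic,
        params.b0, params.b_del, params.b2, _BG_BETA * math.sqrt(grid.dt),
    )
    total = g_up.sum() + g_lo.sum() + surv
    if abs(total - 1.0) > grid.mass_tol:
        raise SolverAccuracyError(
            f"mass conservation violated: total={total:.6f} (tol {grid.mass_tol})"
        )
    return FirstPassage(
        times=grid.times,
        g_upper=g_up / grid.dt,
        g_lower=g_lo / grid.dt,
        survivor=float(surv),
    )


def _nondecision_kernel(params: DDMParams, dt: float) -> np.ndarray:
    """Mass kernel of the non-decision time: Gaussian(tnd, sigma_tnd)
    truncated at zero and renormalized, on the dt grid."""
    if params.sigma_tnd < dt / 2:
        n = int(round(params.tnd / dt))
        kern = np.zeros(n + 1)
        kern[n] = 1.0
        return kern
    n_hi = int(math.ceil((params.tnd + 6.0 * params.sigma_tnd) / dt))
    t = np.arange(n_hi + 1) * dt
    w = np.exp(-0.5 * ((t - params.tnd) / params.sigma_tnd) ** 2)
    w[t <= 0] = 0.0
    w[0] = 0.0
    return w / w.sum()


def apply_nondecision(fp: FirstPassage, params: DDMParams) -> RTDensity:
    """Convolve decision-time densities with the truncated-Gaussian
    non-decision time; mass spilling past the horizon is reported as
    ``tail_mass``."""
    dt = fp.dt
    kern = _nondecision_kernel(params, dt)
    n_t = len(fp.times)
    up = np.convolve(fp.g_upper * dt, kern)
    lo = np.convolve(fp.g_lower * dt, kern)
    tail = float(up[n_t:].sum() + lo[n_t:].sum())
    return RTDensity(
        times=fp.times,
        d_upper=up[:n_t] / dt,
        d_lower=lo[:n_t] / dt,
        survivor=fp.survivor,
        tail_mass=tail,
    )


def rt_density(strength: float, params: DDMParams, grid: SolverGrid) -> RTDensity:
    """First-passage solve followed by non-decision convolution."""
    return apply_nondecision(solve_first_passage(strength, params, grid), params)


def choice_prob(strength: float, params: DDMParams, grid: SolverGrid) -> float:
    """Probability of the upper-bound (right/blue) choice, conditional on
    absorption before the horizon."""
    fp = solve_first_passage(strength, params, grid)
    pu, pl = fp.prob_upper(), fp.prob_lower()
    return pu / (pu + pl)


def _interp_density(dens: np.ndarray, times: np.ndarray, rt: float) -> float:
    return float(np.interp(rt, times, dens))


def trial_loglik(
    trial,
    params: DDMParams,
    grid: SolverGrid,
    strength: float | None = None,
    floor: float = LIK_FLOOR,
) -> float:
    """Log of the RT density at the observed (choice, RT) for one trial.

    ``strength`` overrides the trial's own strength (e.g. binned or rounded
    delta-value).  Densities below ``floor`` are clipped, not raised.
    """
    from .datamodel import PerceptualTrial, ValueTrial, compute_delta_value

    if not trial.valid:
        raise ValueError("trial_loglik requires a valid trial")
    if strength is None:
        if isinstance(trial, ValueTrial):
            strength = compute_delta_value(trial)
        elif isinstance(trial, PerceptualTrial):
            strength = trial.coherence
        else:  # pragma: no cover - defensive
            raise TypeError(f"unsupported trial type {type(trial)!r}")
    chose_upper = (
        trial.chose_right if hasattr(trial, "chose_right") else trial.chose_blue
    )
    dens = rt_density(strength, params, grid)
    d = dens.d_upper if chose_upper else dens.d_lower
    return math.log(max(_interp_density(d, dens.times, trial.rt), floor))


def loglik_by_strength(
    strengths: np.ndarray,
    chose_upper: np.ndarray,
    rts: np.ndarray,
    params: DDMParams,
    grid: SolverGrid,
    floor: float = LIK_FLOOR,
) -> np.ndarray:
    """Per-trial log-likelihoods, solving the Fokker-Planck equation once per
    unique stimulus strength.  This is the workhorse of dataset fitting."""
    strengths = np.asarray(strengths, dtype=float)
    chose_upper = np.asarray(chose_upper)
    rts = np.asarray(rts, dtype=float)
    out = np.empty(len(strengths))
    for s in np.unique(strengths):
        mask = strengths == s
        dens = rt_density(float(s), params, grid)
        du = np.interp(rts[mask], dens.times, dens.d_upper)
        dl = np.interp(rts[mask], dens.times, dens.d_lower)
        d = np.where(chose_upper[mask] > 0, du, dl)
        out[mask] = np.log(np.maximum(d, floor))
    return out
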