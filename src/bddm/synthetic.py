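"""Generators for task designs, stimuli, and synthetic choice/RT datasets.

Includes the Euler-Maruyama path simulator used as the independent oracle for
the Fokker-Planck solver in :mod:`bddm.ddm` (the two share no density code).

The value-task design follows the session structure of the modeled study:
60 items, 150 unique pairs with each item in exactly 5 pairs, 60 pairs
repeated once, 210 presentations in 3 runs of 70, with the higher-valued
item's side counterbalanced.  The perceptual design draws signed coherences
from an 11-level set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .datamodel import PerceptualTrial, TrialTable, ValueTrial
from .ddm import DDMParams
from .heuristic import HeuristicParams, choice_prob_nontrivial, classify_value, trial_class

__all__ = [
    "COHERENCE_LEVELS",
    "ValueDesign",
    "PerceptualDesign",
    "GroupSpec",
    "CohortSpec",
    "generate_value_design",
    "generate_perceptual_design",
    "pblue_from_coherence",
    "sample_dot_frame",
    "simulate_ddm_trial",
    "simulate_ddm_trials",
    "simulate_heuristic_trial",
    "synthesize_cohort",
]

#: the 11 signed color-coherence levels used by the perceptual task
COHERENCE_LEVELS = np.array(
    [-2.0, -1.0, -0.5, -0.25, -0.125, 0.0, 0.125, 0.25, 0.5, 1.0, 2.0]
)

#: circulant rank offsets building the 150-pair value design; offsets 1 and 10
#: each contribute 60 pairs (degree 2), the antipodal offset 30 contributes 30
#: pairs (degree 1): 5 pairs per item, spanning small to large value gaps.
_PAIR_OFFSETS = (1, 10, 30)

_SIM_DT = 5e-4  # simulator step; bridge crossing removes the O(sqrt(dt)) bias


@dataclass(frozen=True)
class ValueDesign:
    """A value-task session: pairing structure and ordered presentations."""

    items: tuple
    values: dict
    pairs: tuple            # 150 unique unordered (item, item) pairs
    repeats: tuple          # the 60 pairs presented twice
    trials: tuple           # 210 ordered (left_item, right_item) presentations
    n_runs: int = 3

    @property
    def run_length(self) -> int:
        return len(self.trials) // self.n_runs

    def item_counts(self) -> dict:
        counts = {it: 0 for it in self.items}
        for left, right in self.trials:
            counts[left] += 1
            counts[right] += 1
        return counts


@dataclass(frozen=True)
class PerceptualDesign:
    """A perceptual-task session: ordered signed coherences."""

    coherences: tuple
    n_runs: int = 3

    @property
    def run_length(self) -> int:
        return len(self.coherences) // self.n_runs


@dataclass
class GroupSpec:
    """One cohort group driven by a single generating model."""

    label: str
    n_participants: int
    model: str                      # "ddm" or "heuristic"
    params: DDMParams | HeuristicParams
    value_scale: str = "wtp"        # "wtp" ($0-3) or "rating" (0-10, z-scored)
    deadline: float = 3.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.model not in ("ddm", "heuristic"):
            raise ValueError(f"unknown generating model {self.model!r}")


@dataclass
class CohortSpec:
    """Synthetic cohort: groups of agents plus a master seed."""

    groups: list[GroupSpec]
    seed: int = 0
    n_items: int = 60
    experiment: str = "exp2"
    perceptual_params: DDMParams | None = None
    include_perceptual: bool = True
    sim_dt: float = _SIM_DT


def generate_value_design(values: dict, seed: int = 0) -> ValueDesign:
    """Build a 210-trial value session from exactly 60 item values.

    Items are placed on a circle by value rank; pairs connect ranks at
    offsets {1, 10, 30}, which yields 150 unique pairs with every item in
    exactly 5 and a wide spread of value differences.  The 60 offset-1 pairs
    are presented twice (each item gains exactly 2 extra appearances, 7
    total).  Left/right placement of the higher-valued item is
    counterbalanced by a seeded half/half assignment and trial order is a
    seeded shuffle into 3 runs of 70.
    """
    if len(values) != 60:
        raise ValueError(f"value design requires exactly 60 items, got {len(values)}")
    rng = np.random.default_rng(seed)
    ranked = sorted(values, key=lambda it: (values[it], str(it)))
    n = len(ranked)
    pairs = []
    for off in _PAIR_OFFSETS:
        limit = n if off * 2 != n else n // 2
        for i in range(limit):
            a, b = ranked[i], ranked[(i + off) % n]
            pairs.append((a, b))
    repeats = [pairs[i] for i in range(n)]  # the offset-1 cycle
    presentations = list(pairs) + list(repeats)

    # counterbalance: higher-value item on the right in exactly half of trials
    n_trials = len(presentations)
    hi_right = np.zeros(n_trials, dtype=bool)
    hi_right[: n_trials // 2 + n_trials % 2] = True
    rng.shuffle(hi_right)
    order = rng.permutation(n_trials)
    trials = []
    for k, idx in enumerate(order):
        a, b = presentations[idx]
        lo, hi = (a, b) if values[a] <= values[b] else (b, a)
        trials.append((lo, hi) if hi_right[k] else (hi, lo))
    return ValueDesign(
        items=tuple(ranked),
        values=dict(values),
        pairs=tuple(pairs),
        repeats=tuple(repeats),
        trials=tuple(trials),
    )


def generate_perceptual_design(
    n_trials: int = 210, seed: int = 0, n_runs: int = 3
) -> PerceptualDesign:
    """210 signed coherences drawn near-uniformly from the 11-level set,
    shuffled into runs."""
    if n_trials % n_runs:
        raise ValueError("n_trials must be divisible by n_runs")
    rng = np.random.default_rng(seed)
    base = n_trials // len(COHERENCE_LEVELS)
    seq = np.repeat(COHERENCE_LEVELS, base)
    extra = n_trials - len(seq)
    if extra:
        seq = np.concatenate(
            [seq, rng.choice(COHERENCE_LEVELS, size=extra, replace=False)]
        )
    rng.shuffle(seq)
    return PerceptualDesign(coherences=tuple(float(c) for c in seq), n_runs=n_runs)


def pblue_from_coherence(C: float) -> float:
    """Probability a dot is blue: ``logistic(C)``."""
    return 1.0 / (1.0 + math.exp(-C))


def sample_dot_frame(
    C: float,
    aperture_diameter: float = 5.0,
    density: float = 16.7,
    frame_rate: float = 60.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """One video frame of the dot stimulus: positions uniform in the circular
    aperture, colors Bernoulli(pblue(C)), dot count Poisson with mean
    ``density * area / frame_rate``.

    Returns ``(xy, is_blue)`` with ``xy`` of shape (n, 2) in cm centered on
    the aperture.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    radius = aperture_diameter / 2.0
    mean_dots = density * math.pi * radius**2 / frame_rate
    n = rng.poisson(mean_dots)
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    is_blue = rng.uniform(size=n) < pblue_from_coherence(C)
    return xy, is_blue


# ---------------------------------------------------------------------------
# Euler-Maruyama simulator (independent oracle for the FP solver)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _em_paths(mus, b0, b_del, b2, tnd, sig_tnd, deadline, dt, seed):
    np.random.seed(seed)
    n = mus.size
    choices = np.empty(n, np.int8)
    rts = np.empty(n)
    valid = np.empty(n, np.bool_)
    sq = math.sqrt(dt)
    for i in range(n):
        x = 0.0
        t = 0.0
        decided = False
        choice = -1
        while t < deadline:
            t += dt
            x_new = x + mus[i] * dt + sq * np.random.randn()
            if t < b_del:
                b = b0
            else:
                b = b0 * math.exp(-(t - b_del) / b2)
            if x_new >= b:
                choice = 1
                decided = True
                break
            if x_new <= -b:
                choice = 0
                decided = True
                break
            # Brownian-bridge probability of an unobserved within-step
            # crossing; skipped when negligible (< ~2e-9)
            au = (b - x) * (b - x_new)
            al = (b + x) * (b + x_new)
            thresh = 10.0 * dt
            if au < thresh or al < thresh:
                pu = math.exp(-2.0 * au / dt) if au < thresh else 0.0
                pl = math.exp(-2.0 * al / dt) if al < thresh else 0.0
                u = np.random.random()
                if u < pu:
                    choice = 1
                    decided = True
                    break
                if u < pu + pl:
                    choice = 0
                    decided = True
                    break
            x = x_new
        nd = -1.0
        while nd <= 0.0:
            nd = tnd + sig_tnd * np.random.randn()
            if sig_tnd == 0.0:
                nd = tnd
                break
        rt = t + nd
        choices[i] = choice
        rts[i] = rt
        valid[i] = decided and rt <= deadline
    return choices, rts, valid


def simulate_ddm_trials(
    strengths: np.ndarray,
    params: DDMParams,
    deadline: float,
    seed: int = 0,
    dt: float = _SIM_DT,
):
    """Simulate many diffusion trials by explicit Euler-Maruyama paths.

    Returns ``(choices, rts, valid)``; choice 1 is the upper bound, -1 marks
    no decision before the deadline.  ``valid`` is False when no bound was
    reached or the RT (decision + non-decision) exceeded the deadline.
    """
    strengths = np.asarray(strengths, dtype=float)
    from .ddm import drift_rate

    mus = np.array([drift_rate(float(s), params) for s in strengths])
    return _em_paths(
        mus, params.b0, params.b_del, params.b2, params.tnd,
        params.sigma_tnd, deadline, dt, seed,
    )


def simulate_ddm_trial(
    strength: float,
    params: DDMParams,
    deadline: float,
    seed: int = 0,
    dt: float = _SIM_DT,
):
    """Single-trial convenience wrapper around :func:`simulate_ddm_trials`."""
    c, r, v = simulate_ddm_trials(np.array([strength]), params, deadline, seed, dt)
    return int(c[0]), float(r[0]), bool(v[0])


def simulate_heuristic_trial(
    value_left: float,
    value_right: float,
    params: HeuristicParams,
    rng: np.random.Generator,
):
    """One trial from the rule-based agent.

    Trivial pairs choose the forced side with probability ``p_trivial`` and
    draw RT from the fast Gaussian (truncated at 0); non-trivial pairs choose
    by the logistic of the value difference and draw from the slow Gaussian.
    Returns ``(chose_right, rt)``.
    """
    cat_l = classify_value(value_left, params)
    cat_r = classify_value(value_right, params)
    cls = trial_class(cat_l, cat_r)
    if cls.trivial:
        forced_right = 1 if cls.forced_side == "right" else 0
        chose_right = (
            forced_right if rng.uniform() < params.p_trivial else 1 - forced_right
        )
        mu, sigma = params.mu_fast, params.sigma_fast
    else:
        p_right = choice_prob_nontrivial(value_right - value_left, params)
        chose_right = int(rng.uniform() < p_right)
        mu, sigma = params.mu_slow, params.sigma_slow
    rt = -1.0
    while rt <= 0.0:
        rt = rng.normal(mu, sigma)
    return chose_right, rt


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

def _draw_values(scale: str, n_items: int, rng: np.random.Generator) -> dict:
    if scale == "wtp":
        vals = np.round(rng.uniform(0.0, 3.0, size=n_items), 2)
    elif scale == "rating":
        vals = np.round(rng.uniform(0.0, 10.0, size=n_items), 1)
    else:
        raise ValueError(f"unknown value scale {scale!r}")
    return {f"item{i:02d}": float(v) for i, v in enumerate(vals)}


def _agent_values(group: GroupSpec, n_items: int, rng: np.random.Generator):
    """Raw item values plus the evidence-scale values used by the agent."""
    raw = _draw_values(group.value_scale, n_items, rng)
    if group.value_scale == "rating":
        frame_vals = np.array(list(raw.values()))
        z = (frame_vals - frame_vals.mean()) / frame_vals.std(ddof=1)
        scaled = dict(zip(raw.keys(), z.tolist()))
    else:
        scaled = dict(raw)
    return raw, scaled


def synthesize_cohort(spec: CohortSpec):
    """Generate behavior for every agent in the cohort.

    Returns ``(value_table, perceptual_table, manifest)`` where the tables
    are :class:`~bddm.datamodel.TrialTable` instances in the requested
    experiment dialect and the manifest records the ground-truth generating
    parameters per group.
    """
    master = np.random.default_rng(spec.seed)
    value_trials: list[ValueTrial] = []
    percep_trials: list[PerceptualTrial] = []
    manifest = {"seed": spec.seed, "groups": []}
    subject_no = 0
    for group in spec.groups:
        manifest["groups"].append(
            {
                "label": group.label,
                "n_participants": group.n_participants,
                "model": group.model,
                "params": vars(group.params).copy()
                if not hasattr(group.params, "__dataclass_fields__")
                else {k: getattr(group.params, k) for k in group.params.__dataclass_fields__},
                "deadline": group.deadline,
            }
        )
        for _ in range(group.n_participants):
            subject_no += 1
            subject = f"s{subject_no:03d}"
            sub_seed = int(master.integers(2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            raw, scaled = _agent_values(group, spec.n_items, rng)
            design = generate_value_design(scaled, seed=int(rng.integers(2**31 - 1)))
            dvs = np.array(
                [scaled[r] - scaled[l] for l, r in design.trials]
            )
            if group.model == "ddm":
                choices, rts, valid = simulate_ddm_trials(
                    dvs, group.params, group.deadline,
                    seed=int(rng.integers(2**31 - 1)), dt=spec.sim_dt,
                )
            else:
                choices = np.empty(len(dvs), dtype=int)
                rts = np.empty(len(dvs))
                valid = np.ones(len(dvs), dtype=bool)
                for k, (l, r) in enumerate(design.trials):
                    c, t = simulate_heuristic_trial(
                        scaled[l], scaled[r], group.params, rng
                    )
                    choices[k], rts[k] = c, t
                valid &= rts <= group.deadline
            for k, (l, r) in enumerate(design.trials):
                ok = bool(valid[k])
                value_trials.append(
                    ValueTrial(
                        subject=subject,
                        value_left=scaled[l],
                        value_right=scaled[r],
                        chose_right=int(choices[k]) if ok else -1,
                        rt=float(rts[k]) if ok else math.nan,
                        valid=ok,
                        group=group.label,
                        item_left=l,
                        item_right=r,
                        raw_left=raw[l],
                        raw_right=raw[r],
                    )
                )
            # perceptual session for the same agent
            pdesign = generate_perceptual_design(seed=int(rng.integers(2**31 - 1)))
            pparams = spec.perceptual_params or (
                group.params if group.model == "ddm" else None
            )
            if spec.include_perceptual and pparams is not None:
                cohs = np.array(pdesign.coherences)
                pc, prt, pval = simulate_ddm_trials(
                    cohs, pparams, group.deadline,
                    seed=int(rng.integers(2**31 - 1)), dt=spec.sim_dt,
                )
                for k, c in enumerate(cohs):
                    ok = bool(pval[k])
                    percep_trials.append(
                        PerceptualTrial(
                            subject=subject,
                            coherence=float(c),
                            p_blue=pblue_from_coherence(float(c)),
                            chose_blue=int(pc[k]) if ok else -1,
                            rt=float(prt[k]) if ok else math.nan,
                            button_order=1 + (subject_no % 2),
                            valid=ok,
                            group=group.label,
                        )
                    )
    deadline = max(g.deadline for g in spec.groups)
    value_table = TrialTable(
        value_trials, kind="value", experiment=spec.experiment, deadline=deadline
    )
    percep_table = TrialTable(
        percep_trials, kind="perceptual", experiment=spec.experiment,
        deadline=deadline,
    )
    return value_table, percep_table, manifest
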