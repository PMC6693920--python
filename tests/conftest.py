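"""Shared fixtures: small synthetic trial tables and parameter sets."""

import numpy as np
import pytest

from bddm.datamodel import PerceptualTrial, TrialTable, ValueTrial
from bddm.ddm import DDMParams
from bddm.heuristic import HeuristicParams
from bddm.synthetic import COHERENCE_LEVELS, pblue_from_coherence, simulate_ddm_trials


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ddm_params():
    return DDMParams(
        kappa=2.0, b0=1.0, b_del=0.3, b2=0.8, tnd=0.35, sigma_tnd=0.05,
        mu0=0.0, plaw=1.0,
    )


@pytest.fixture
def heuristic_params():
    return HeuristicParams(
        kappa1=-0.8, kappa2=0.8, mu_fast=0.8, sigma_fast=0.15,
        mu_slow=1.6, sigma_slow=0.3, beta0=0.0, beta1=2.0, p_trivial=0.99,
    )


def make_value_table(rng, n=40, dialect="exp1", scale=1.5, subjects=("s1",)):
    """Random hand-rolled value table (not via the simulator)."""
    trials = []
    for i in range(n):
        vl, vr = rng.uniform(0, scale, 2)
        trials.append(
            ValueTrial(
                subject=subjects[i % len(subjects)],
                value_left=round(float(vl), 2),
                value_right=round(float(vr), 2),
                chose_right=int(rng.uniform() < 0.5 + 0.3 * np.sign(vr - vl)),
                rt=round(float(rng.uniform(0.4, 2.5)), 4),
                group="healthy" if dialect == "exp2" else None,
                item_left=f"L{i}",
                item_right=f"R{i}",
                raw_left=round(float(vl * 3), 1) if dialect == "exp2" else None,
                raw_right=round(float(vr * 3), 1) if dialect == "exp2" else None,
            )
        )
    return TrialTable(trials, kind="value", experiment=dialect,
                      deadline=3.0 if dialect == "exp1" else 3.5)


def make_perceptual_table(rng, n=40, dialect="exp1", subjects=("s1",)):
    trials = []
    for i in range(n):
        c = float(rng.choice(COHERENCE_LEVELS))
        trials.append(
            PerceptualTrial(
                subject=subjects[i % len(subjects)],
                coherence=c,
                p_blue=pblue_from_coherence(c),
                chose_blue=int(rng.uniform() < pblue_from_coherence(c)),
                rt=round(float(rng.uniform(0.4, 2.0)), 4),
                button_order=1 + i % 2,
                group="amnesia" if dialect == "exp2" else None,
            )
        )
    return TrialTable(trials, kind="perceptual", experiment=dialect,
                      deadline=2.5 if dialect == "exp1" else 3.5)


def simulate_ddm_table(params, strengths, deadline=3.0, seed=0, dt=1e-3,
                       subject="s1", kind="perceptual"):
    """Trial table generated by the path simulator (oracle-side data)."""
    c, r, v = simulate_ddm_trials(np.asarray(strengths, float), params,
                                  deadline, seed=seed, dt=dt)
    trials = []
    for s, ci, ri, vi in zip(strengths, c, r, v):
        if kind == "perceptual":
            trials.append(
                PerceptualTrial(subject, float(s), pblue_from_coherence(float(s)),
                                int(ci) if vi else -1,
                                float(ri) if vi else float("nan"),
                                1, bool(vi))
            )
        else:
            trials.append(
                ValueTrial(subject, 0.0, float(s),
                           int(ci) if vi else -1,
                           float(ri) if vi else float("nan"), bool(vi))
            )
    return TrialTable(trials, kind=kind, deadline=deadline)
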