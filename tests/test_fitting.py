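"""Fitting-layer tests: binning, BIC algebra, goodness-of-fit statistics, and
small-scale optimizer behavior (full-scale parameter recovery is in
``test_acceptance.py``)."""

import math

import numpy as np
import pytest

from bddm.datamodel import TrialTable, ValueTrial
from bddm.exceptions import DegenerateInputError
from bddm.fitting import (
    FitConfig,
    FitResult,
    bic_compare,
    bin_delta_value,
    fit_ddm,
    fit_heuristic,
    mcfadden_r2,
    rt_r2,
)
from bddm.heuristic import HeuristicParams

from conftest import simulate_ddm_table


def _value_table_from_dvs(dvs, rng=None):
    trials = [
        ValueTrial("s", 0.0, float(dv), int(dv >= 0), 1.0) for dv in dvs
    ]
    return TrialTable(trials, kind="value")


# --- binning --------------------------------------------------------------

def test_bin_count_and_representatives():
    rng = np.random.default_rng(3)
    dvs = rng.uniform(-2.0, 2.0, 400)
    dvs[0], dvs[1] = -2.0, 2.0  # pin the range
    table = _value_table_from_dvs(dvs)
    res = bin_delta_value(table)
    assert len(res.levels) <= 11
    assert len(np.unique(res.strengths)) == len(res.levels)
    # representatives are the means of their members
    for lev in res.levels:
        members = dvs[res.strengths == lev["strength"]]
        assert lev["strength"] == pytest.approx(members.mean())
        assert lev["n"] == len(members)


def test_bin_symmetric_sample_antisymmetric_levels():
    rng = np.random.default_rng(5)
    half = rng.uniform(0, 2.0, 2000)
    dvs = np.concatenate([half, -half])  # exactly symmetric
    res = bin_delta_value(_value_table_from_dvs(dvs))
    reps = sorted(lev["strength"] for lev in res.levels)
    np.testing.assert_allclose(reps, -np.array(reps[::-1]), atol=1e-9)


def test_bin_edge_goes_to_upper_bin():
    # max|dv| = 2 -> targets are the coherence levels; edge between 0.125
    # and 0.25 sits at 0.1875
    dvs = np.array([-2.0, 2.0, 0.1875, 0.24, 0.13])
    res = bin_delta_value(_value_table_from_dvs(dvs))
    upper = [lev for lev in res.levels if 0.18 < lev["strength"] < 0.5]
    assert len(upper) == 1
    # the edge trial landed with 0.24 in the upper bin
    assert upper[0]["n"] == 2
    assert upper[0]["strength"] == pytest.approx((0.1875 + 0.24) / 2)


def test_bin_empty_level_warns():
    dvs = np.array([-2.0, -1.9, 2.0, 1.9])
    with pytest.warns(UserWarning, match="empty"):
        res = bin_delta_value(_value_table_from_dvs(dvs))
    assert len(res.levels) < 11


# --- BIC ------------------------------------------------------------------

def _fit_result(nll, n, k):
    params = HeuristicParams(kappa1=0, kappa2=1, mu_fast=1, sigma_fast=0.1,
                             mu_slow=2, sigma_slow=0.2, beta0=0, beta1=1)
    return FitResult(params=params, nll=nll, n_trials=n, n_params=k)


def test_bic_identity():
    r = _fit_result(100.0, 500, 8)
    assert r.bic == pytest.approx(200.0 + 8 * math.log(500))


def test_bic_compare_identical_zero():
    a = _fit_result(100.0, 500, 8)
    assert bic_compare(a, a) == 0.0


def test_bic_compare_equal_k_is_deviance():
    a = _fit_result(100.0, 500, 8)
    b = _fit_result(110.0, 500, 8)
    assert bic_compare(a, b) == pytest.approx(2 * (110.0 - 100.0))


def test_bic_compare_mismatched_n_raises():
    a = _fit_result(100.0, 500, 8)
    b = _fit_result(100.0, 400, 8)
    with pytest.raises(ValueError):
        bic_compare(a, b)


# --- McFadden pseudo-R2 ---------------------------------------------------

def test_mcfadden_null_probabilities_give_zero():
    chose = np.array([1, 1, 0, 1, 0, 0, 1, 1])
    p = np.full(8, chose.mean())
    assert mcfadden_r2(chose, p) == pytest.approx(0.0, abs=1e-12)


def test_mcfadden_perfect_approaches_one():
    chose = np.array([1, 0, 1, 0])
    p = np.where(chose > 0, 1 - 1e-9, 1e-9)
    assert mcfadden_r2(chose, p) > 0.999


def test_mcfadden_ten_trial_hand_computed():
    chose = np.array([1, 1, 1, 0, 0, 1, 0, 1, 1, 0])
    p = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.6, 0.2, 0.85, 0.75, 0.35])
    ll = sum(math.log(pi) if c else math.log(1 - pi) for c, pi in zip(chose, p))
    pbar = 0.6
    ll0 = 10 * (pbar * math.log(pbar) + 0.4 * math.log(0.4))
    assert mcfadden_r2(chose, p) == pytest.approx(1 - ll / ll0, abs=1e-12)


def test_mcfadden_degenerate_choices_raise():
    with pytest.raises(DegenerateInputError):
        mcfadden_r2(np.ones(5), np.full(5, 0.8))


# --- RT R2 ----------------------------------------------------------------

def test_rt_r2_exact_fit():
    obs = np.array([1.0, 1.2, 1.5])
    assert rt_r2(obs, obs) == pytest.approx(1.0)


def test_rt_r2_grand_mean_zero():
    obs = np.array([1.0, 1.2, 1.5])
    assert rt_r2(obs, np.full(3, obs.mean())) == pytest.approx(0.0)


def test_rt_r2_three_level_hand_computed():
    obs = np.array([1.0, 1.4, 1.6])
    mod = np.array([1.1, 1.3, 1.7])
    ss_res = 0.01 + 0.01 + 0.01
    ss_tot = ((obs - obs.mean()) ** 2).sum()
    assert rt_r2(obs, mod) == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)


def test_rt_r2_zero_variance_raises():
    with pytest.raises(DegenerateInputError):
        rt_r2(np.array([1.0, 1.0]), np.array([1.0, 1.1]))


# --- heuristic fitting ----------------------------------------------------

def _heuristic_table(seed=0, n=300):
    from bddm.synthetic import simulate_heuristic_trial

    truth = HeuristicParams(kappa1=-0.9, kappa2=0.9, mu_fast=0.7,
                            sigma_fast=0.15, mu_slow=1.6, sigma_slow=0.3,
                            beta0=0.0, beta1=2.5, p_trivial=0.97)
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n):
        vl, vr = rng.normal(0, 1.1, 2)
        c, rt = simulate_heuristic_trial(float(vl), float(vr), truth, rng)
        trials.append(ValueTrial("s", float(vl), float(vr), c, rt))
    return TrialTable(trials, kind="value"), truth


def test_fit_heuristic_recovers_and_is_reproducible():
    table, truth = _heuristic_table()
    cfg = FitConfig(n_starts=8, seed=4, maxiter=400, n_polish=2,
                    polish_maxiter=1500)
    a = fit_heuristic(table, cfg, variant="fixed")
    b = fit_heuristic(table, cfg, variant="fixed")
    assert a.nll == b.nll
    assert a.params == b.params  # reproducible given (seed, n_starts)
    assert a.n_params == 8
    assert a.params.mu_fast == pytest.approx(truth.mu_fast, abs=0.1)
    assert a.params.mu_slow == pytest.approx(truth.mu_slow, abs=0.1)
    assert a.nll_bic is not None
    assert a.bic == pytest.approx(2 * a.nll_bic + 8 * math.log(a.n_trials))


def test_fit_heuristic_trembling_has_nine_params():
    table, _ = _heuristic_table(seed=1, n=150)
    cfg = FitConfig(n_starts=4, seed=2, maxiter=300, n_polish=1,
                    polish_maxiter=800)
    res = fit_heuristic(table, cfg, variant="trembling")
    assert res.n_params == 9
    assert res.nll_bic is None
    assert res.bic == pytest.approx(2 * res.nll + 9 * math.log(res.n_trials))


# --- DDM fitting (small scale) -------------------------------------------

@pytest.fixture(scope="module")
def small_sim_table(ddm_params_module):
    strengths = np.tile([-1.0, -0.25, 0.0, 0.25, 1.0], 80)
    return simulate_ddm_table(ddm_params_module, strengths, deadline=3.0,
                              seed=21, dt=1e-3)


@pytest.fixture(scope="module")
def ddm_params_module():
    from bddm.ddm import DDMParams

    return DDMParams(kappa=2.0, b0=1.0, b_del=0.3, b2=0.8, tnd=0.35,
                     sigma_tnd=0.05, mu0=0.0, plaw=1.0)


def test_fit_ddm_requires_two_levels(ddm_params_module):
    table = simulate_ddm_table(ddm_params_module, np.full(20, 0.5), seed=3)
    with pytest.raises(DegenerateInputError):
        fit_ddm(table, FitConfig(n_starts=1))


def test_nested_model_nll_ordering(small_sim_table):
    """Full-model optimum is at least as good as the reduced-model optimum."""
    cfg = dict(n_starts=2, seed=7, dt=8e-3, n_x=60, maxiter=250, n_polish=1,
               polish_maxiter=600, fatol=0.05, xatol=0.02)
    reduced = fit_ddm(small_sim_table, FitConfig(variant="no_plaw", **cfg))
    full = fit_ddm(small_sim_table, FitConfig(variant="full", **cfg))
    assert full.n_params == 8
    assert reduced.n_params == 7
    # data were generated with plaw=1, so the reduced model is well-specified
    # and the full-model NLL can exceed it only by optimizer noise
    assert full.nll <= reduced.nll + 2.0


def test_flat_variant_has_five_params(small_sim_table):
    cfg = FitConfig(variant="no_plaw_flat", n_starts=1, seed=0, dt=8e-3,
                    n_x=60, maxiter=150, n_polish=1, polish_maxiter=300,
                    fatol=0.1, xatol=0.05)
    res = fit_ddm(small_sim_table, cfg)
    assert res.n_params == 5
    assert res.params.plaw == 1.0
    # collapse disabled: bound delay pushed past the horizon
    assert res.params.b_del > small_sim_table.deadline
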