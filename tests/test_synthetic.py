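"""Design-generator, stimulus, simulator and cohort-synthesis tests."""

import math
from collections import Counter

import numpy as np
import pytest

from bddm.datamodel import read_value_trials, write_value_trials
from bddm.ddm import DDMParams
from bddm.synthetic import (
    COHERENCE_LEVELS,
    CohortSpec,
    GroupSpec,
    generate_perceptual_design,
    generate_value_design,
    pblue_from_coherence,
    sample_dot_frame,
    simulate_ddm_trials,
    simulate_heuristic_trial,
    synthesize_cohort,
)


def _values(seed=0):
    rng = np.random.default_rng(seed)
    return {f"item{i:02d}": float(v) for i, v in
            enumerate(np.round(rng.uniform(0, 3, 60), 2))}


# --- value design ---------------------------------------------------------

@pytest.mark.parametrize("seed", range(0, 100, 1))
def test_value_design_invariants_many_seeds(seed):
    design = generate_value_design(_values(seed % 7), seed=seed)
    assert len(design.trials) == 210
    assert len(design.pairs) == 150
    assert len(set(map(frozenset, design.pairs))) == 150
    assert len(design.repeats) == 60
    # every item in exactly 5 unique pairs and 7 presentations
    pair_deg = Counter()
    for a, b in design.pairs:
        pair_deg[a] += 1
        pair_deg[b] += 1
    assert set(pair_deg.values()) == {5}
    assert set(design.item_counts().values()) == {7}
    assert design.run_length == 70


def test_value_design_counterbalanced_sides():
    rng = np.random.default_rng(1)
    values = {f"i{i:02d}": float(v) for i, v in
              enumerate(rng.uniform(0, 3, 60))}  # distinct values
    design = generate_value_design(values, seed=11)
    hi_right = sum(
        design.values[r] > design.values[l] for l, r in design.trials
    )
    assert abs(hi_right - 105) <= 1


def test_value_design_dv_spread():
    design = generate_value_design(_values(2), seed=3)
    dvs = np.abs([design.values[r] - design.values[l] for l, r in design.trials])
    # rank-offset construction yields both near-ties and large gaps
    assert dvs.min() < 0.3
    assert dvs.max() > 1.0


def test_value_design_deterministic():
    a = generate_value_design(_values(3), seed=42)
    b = generate_value_design(_values(3), seed=42)
    assert a.trials == b.trials
    c = generate_value_design(_values(3), seed=43)
    assert a.trials != c.trials


def test_value_design_wrong_item_count():
    with pytest.raises(ValueError):
        generate_value_design({"a": 1.0}, seed=0)


# --- perceptual design ----------------------------------------------------

def test_perceptual_design_levels_and_determinism():
    d = generate_perceptual_design(seed=5)
    assert len(d.coherences) == 210
    assert set(d.coherences) == set(COHERENCE_LEVELS)
    assert d.run_length == 70
    assert d.coherences == generate_perceptual_design(seed=5).coherences
    assert d.coherences != generate_perceptual_design(seed=6).coherences


def test_perceptual_design_sign_balance():
    d = generate_perceptual_design(seed=9)
    signs = np.sign([c for c in d.coherences if c != 0])
    n = len(signs)
    # binomial 3-sigma band around half
    assert abs((signs > 0).sum() - n / 2) <= 3 * math.sqrt(n / 4) + 1


# --- dot stimulus ---------------------------------------------------------

def test_pblue_examples_and_symmetry():
    assert pblue_from_coherence(0.0) == 0.5
    assert pblue_from_coherence(2.0) == pytest.approx(0.88080, abs=1e-5)
    for c in [-2.0, -0.5, 0.125, 1.0]:
        assert pblue_from_coherence(c) + pblue_from_coherence(-c) == pytest.approx(1.0)


def test_dot_frame_statistics(rng):
    counts, blues, total = [], 0, 0
    for _ in range(3000):
        xy, is_blue = sample_dot_frame(0.5, rng=rng)
        counts.append(len(xy))
        blues += is_blue.sum()
        total += len(xy)
        assert np.all(np.hypot(xy[:, 0], xy[:, 1]) <= 2.5 + 1e-12)
    expected = 16.7 * math.pi * 2.5**2 / 60  # ~5.46 dots per frame
    mean_count = np.mean(counts)
    assert mean_count == pytest.approx(expected, abs=4 * math.sqrt(expected / 3000))
    p = pblue_from_coherence(0.5)
    se = math.sqrt(p * (1 - p) / total)
    assert blues / total == pytest.approx(p, abs=4 * se)


# --- diffusion simulator --------------------------------------------------

def test_simulator_zero_drift_symmetric():
    p = DDMParams(kappa=1, b0=1.0, b_del=0.2, b2=0.8, tnd=0.3, sigma_tnd=0.05)
    n = 20_000
    c, r, v = simulate_ddm_trials(np.zeros(n), p, deadline=10.0, seed=2, dt=1e-3)
    frac = (c[v] == 1).mean()
    assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / v.sum())


def test_simulator_flat_bound_closed_form():
    p = DDMParams(kappa=1, b0=1.0, b_del=1e3, b2=1.0, tnd=0.3, sigma_tnd=0.0)
    n = 40_000
    c, r, v = simulate_ddm_trials(np.full(n, 1.0), p, deadline=30.0, seed=3,
                                  dt=1e-3)
    target = 1 / (1 + math.exp(-2))
    se = math.sqrt(target * (1 - target) / n)
    assert (c == 1).mean() == pytest.approx(target, abs=3 * se)
    assert (r - p.tnd).mean() == pytest.approx(math.tanh(1.0), abs=0.01)


def test_simulator_rt_exceeds_nondecision_floor():
    p = DDMParams(kappa=1, b0=1.0, b_del=0.2, b2=0.5, tnd=0.4, sigma_tnd=0.05)
    c, r, v = simulate_ddm_trials(np.full(2000, 0.5), p, deadline=5.0, seed=4,
                                  dt=1e-3)
    assert np.all(r[v] > 0)
    assert r[v].min() >= 1e-3  # at least one step plus a positive nd draw


def test_simulator_deterministic():
    p = DDMParams(kappa=1, b0=1.0, b_del=0.2, b2=0.5, tnd=0.4, sigma_tnd=0.05)
    a = simulate_ddm_trials(np.full(50, 0.5), p, 5.0, seed=7)
    b = simulate_ddm_trials(np.full(50, 0.5), p, 5.0, seed=7)
    np.testing.assert_array_equal(a[1], b[1])


# --- heuristic simulator --------------------------------------------------

def test_heuristic_sim_forced_side(heuristic_params):
    p = heuristic_params
    rng = np.random.default_rng(8)
    n = 5000
    chose_right = sum(
        simulate_heuristic_trial(p.kappa1 - 1.0, p.kappa2 + 1.0, p, rng)[0]
        for _ in range(n)
    )
    se = math.sqrt(p.p_trivial * (1 - p.p_trivial) / n)
    assert chose_right / n == pytest.approx(p.p_trivial, abs=4 * se)


def test_heuristic_sim_nontrivial_even_split(heuristic_params):
    rng = np.random.default_rng(9)
    n = 5000
    chose = [simulate_heuristic_trial(0.1, 0.1, heuristic_params, rng)[0]
             for _ in range(n)]
    assert np.mean(chose) == pytest.approx(0.5, abs=4 * math.sqrt(0.25 / n))


def test_heuristic_sim_fast_rt_mean(heuristic_params):
    p = heuristic_params
    rng = np.random.default_rng(10)
    rts = [simulate_heuristic_trial(0.0, p.kappa2 + 1.0, p, rng)[1]
           for _ in range(4000)]
    se = p.sigma_fast / math.sqrt(len(rts))
    assert np.mean(rts) == pytest.approx(p.mu_fast, abs=4 * se)


# --- cohort synthesis -----------------------------------------------------

@pytest.fixture(scope="module")
def small_cohort():
    healthy = DDMParams(kappa=2.2, b0=1.0, b_del=0.3, b2=1.0, tnd=0.4,
                        sigma_tnd=0.05)
    amnesic = DDMParams(kappa=0.7, b0=1.3, b_del=0.5, b2=2.0, tnd=0.9,
                        sigma_tnd=0.08)
    spec = CohortSpec(
        groups=[
            GroupSpec("healthy", 3, "ddm", healthy, "rating", 3.5),
            GroupSpec("amnesia", 2, "ddm", amnesic, "rating", 3.5),
        ],
        seed=77,
    )
    return synthesize_cohort(spec)


def test_cohort_counts_and_labels(small_cohort):
    value_table, percep_table, manifest = small_cohort
    assert len(value_table) == 5 * 210
    assert len(percep_table) == 5 * 210
    by_group = Counter(t.group for t in value_table)
    assert by_group == {"healthy": 3 * 210, "amnesia": 2 * 210}
    assert len(value_table.subjects()) == 5
    assert {g["label"] for g in manifest["groups"]} == {"healthy", "amnesia"}


def test_cohort_roundtrip_through_readers(small_cohort, tmp_path):
    value_table, _, _ = small_cohort
    path = tmp_path / "cohort.csv"
    write_value_trials(value_table, path)
    back = read_value_trials(path, dialect="exp2")
    assert len(back) == len(value_table)
    for a, b in zip(value_table, back):
        if a.valid:
            assert a.chose_right == b.chose_right
            assert a.value_left == pytest.approx(b.value_left)
            assert a.rt == pytest.approx(b.rt)
        assert a.group == b.group


def test_cohort_slope_ordering(small_cohort):
    """End-to-end: the steeper-drift group keeps the steeper fitted choice
    slope after synthesis, writing, and summary statistics."""
    from bddm.stats import fit_choice_slope

    value_table, _, _ = small_cohort
    slopes = {}
    for label in ("healthy", "amnesia"):
        sub = value_table.filter_group(label).valid_trials()
        _, slopes[label] = fit_choice_slope(sub.strengths(), sub.choices())
    assert slopes["healthy"] > slopes["amnesia"]


def test_cohort_deterministic():
    p = DDMParams(kappa=2.0, b0=1.0, b_del=0.3, b2=1.0, tnd=0.4, sigma_tnd=0.05)
    spec = CohortSpec(groups=[GroupSpec("g", 1, "ddm", p, "wtp", 3.0)], seed=5)
    a = synthesize_cohort(spec)[0]
    b = synthesize_cohort(spec)[0]
    assert [t.rt for t in a if t.valid] == [t.rt for t in b if t.valid]
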