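"""Asynchronous dynamics: successors, fixed points, STG, attractors,
Monte Carlo and exact absorption probabilities."""

import math

import pytest

from g1snet.dynamics import (async_successors, build_stg, enumerate_fixed_points,
                             exact_absorption, find_attractors,
                             monte_carlo_phenotypes, StateBudgetExceeded)
from g1snet.io import loads_bnet
from g1snet.logic import Perturbation
from g1snet.random_nets import (RandomNetworkConfig, brute_force_attractors,
                                brute_force_fixed_points, full_stg, generate)


# --- successors -------------------------------------------------------------

def test_fixed_point_has_no_successors(toggle):
    assert async_successors(toggle, (1, 0)) == set()


def test_mutual_activation_successors_flip_one_node(mutual_activation):
    # at (1,0) both nodes are unstable: A wants 0 (B off), B wants 1 (A on)
    assert async_successors(mutual_activation, (1, 0)) == {(0, 0), (1, 1)}


def test_dimension_mismatch_rejected(toggle):
    with pytest.raises(ValueError):
        async_successors(toggle, (1, 0, 1))


def test_clamped_node_never_updates(toggle):
    p = Perturbation.from_dict({"A": 0})
    # (0,0): unclamped B wants !A = 1; A stays despite its rule saying 1
    assert async_successors(toggle, (0, 0), p) == {(0, 1)}


# --- fixed points -----------------------------------------------------------

def test_self_activator_has_both_fixed_points():
    m = loads_bnet("# kind: A internal\ntargets, factors\nA, A\n")
    assert enumerate_fixed_points(m) == {(0,), (1,)}


def test_toggle_switch_is_bistable(toggle):
    assert enumerate_fixed_points(toggle) == {(0, 1), (1, 0)}


def test_negative_loop_has_no_fixed_point(negative_loop):
    assert enumerate_fixed_points(negative_loop) == set()


@pytest.mark.parametrize("template", ["and_not", "nested_canalyzing",
                                      "random_monotone"])
@pytest.mark.parametrize("seed", range(8))
def test_fixed_points_match_brute_force(template, seed):
    """Branch-and-prune enumeration equals the exhaustive 2^n oracle."""
    m = generate(RandomNetworkConfig(n_nodes=9, max_in_degree=3,
                                     rule_template=template, seed=seed))
    assert enumerate_fixed_points(m) == brute_force_fixed_points(m)


def test_fixed_points_respect_clamps():
    m = generate(RandomNetworkConfig(n_nodes=8, seed=42))
    p = Perturbation.from_dict({"n0": 1, "n3": 0})
    fps = enumerate_fixed_points(m, p)
    assert fps == brute_force_fixed_points(m, p)
    for fp in fps:
        assert fp[0] == 1 and fp[3] == 0


def test_fixed_points_are_update_scheme_independent():
    """Fixed points of the asynchronous scheme are exactly the states
    with x = F(x), i.e. the synchronous fixed points."""
    for seed in range(6):
        m = generate(RandomNetworkConfig(n_nodes=8, seed=seed,
                                         rule_template="random_monotone"))
        sync = set()
        for s in full_stg(m).nodes:
            image = tuple(m.evaluate_rule(n.name, s) for n in m.nodes)
            if image == s:
                sync.add(s)
        assert enumerate_fixed_points(m) == sync


# --- STG and attractors -----------------------------------------------------

def test_stg_of_fixed_point_is_singleton(toggle):
    stg = build_stg(toggle, (1, 0))
    assert stg.number_of_nodes() == 1 and stg.number_of_edges() == 0


def test_toggle_reachable_states_from_undecided_start(toggle):
    # (0,0) resolves to either stable state; (1,1) is not reachable
    stg = build_stg(toggle, (0, 0))
    assert set(stg.nodes) == {(0, 0), (0, 1), (1, 0)}
    assert full_stg(toggle).number_of_nodes() == 4  # the complete graph


def test_state_budget_overflow_raises(bundle):
    root = list(bundle.proliferative_state())
    root[bundle.model.index["DNA_Damage"]] = 1
    with pytest.raises(StateBudgetExceeded):
        build_stg(bundle.model, tuple(root), max_states=2000)


def test_negative_loop_yields_single_cyclic_attractor(negative_loop):
    stg = build_stg(negative_loop, (0, 0))
    atts = find_attractors(stg, negative_loop)
    assert len(atts) == 1
    (att,) = atts
    assert att.kind == "cyclic"
    assert att.states == {(0, 0), (1, 0), (1, 1), (0, 1)}


def test_attractors_match_brute_force_oracle():
    for seed in range(8):
        m = generate(RandomNetworkConfig(n_nodes=8, seed=seed,
                                         rule_template="nested_canalyzing"))
        stg = full_stg(m)
        assert find_attractors(stg, m) == brute_force_attractors(m)


# --- absorption probabilities ----------------------------------------------

def test_exact_absorption_from_absorbed_root(toggle):
    stg = build_stg(toggle, (1, 0))
    dist = exact_absorption(stg, toggle)
    assert list(dist.probabilities.values()) == [1.0]


def test_symmetric_branch_absorbs_half_half(mutual_activation):
    # from (1,0) one step reaches either fixed point with equal chance
    stg = build_stg(mutual_activation, (1, 0))
    dist = exact_absorption(stg, mutual_activation)
    probs = sorted(dist.probabilities.values())
    assert probs == pytest.approx([0.5, 0.5])


def test_monte_carlo_from_fixed_point_is_certain(toggle):
    dist = monte_carlo_phenotypes(toggle, (0, 1), n_runs=50, seed=3)
    (att, prob), = dist.probabilities.items()
    assert prob == 1.0 and att.states == {(0, 1)}


def test_monte_carlo_is_bit_reproducible(bundle):
    root = list(bundle.proliferative_state())
    root[bundle.model.index["DNA_Damage"]] = 1
    a = monte_carlo_phenotypes(bundle.model, tuple(root), n_runs=500, seed=11)
    b = monte_carlo_phenotypes(bundle.model, tuple(root), n_runs=500, seed=11)
    assert a.probabilities == b.probabilities
    c = monte_carlo_phenotypes(bundle.model, tuple(root), n_runs=500, seed=12)
    assert a.probabilities != c.probabilities  # different walk, n=500


def test_monte_carlo_matches_exact_absorption_within_3_sigma():
    """The sampling estimator agrees with the linear-solve oracle."""
    m = generate(RandomNetworkConfig(n_nodes=8, seed=5,
                                     rule_template="random_monotone"))
    root = (0,) * 8
    stg = build_stg(m, root)
    exact = exact_absorption(stg, m)
    n = 20_000
    mc = monte_carlo_phenotypes(m, root, n_runs=n, seed=1)
    ex = {a.representative: p for a, p in exact.probabilities.items()}
    got = {a.representative: p for a, p in mc.probabilities.items()}
    assert set(got) <= set(ex)
    for key, p in ex.items():
        sigma = math.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(got.get(key, 0.0) - p) <= max(3 * sigma, 1e-9)


def test_monte_carlo_absorbs_into_cyclic_attractors(negative_loop):
    dist = monte_carlo_phenotypes(negative_loop, (0, 0), n_runs=20, seed=0,
                                  max_steps=30)
    (att, prob), = dist.probabilities.items()
    assert att.kind == "cyclic" and prob == 1.0


def test_distributions_are_normalized():
    for seed in (2, 9):
        m = generate(RandomNetworkConfig(n_nodes=7, seed=seed))
        dist = monte_carlo_phenotypes(m, (0,) * 7, n_runs=300, seed=seed)
        assert sum(dist.probabilities.values()) == pytest.approx(1.0)
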