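import itertools

import numpy as np
import pytest

from conftest import make_table
from csrpath.ilp import ObjectiveWeights, build_ilp
from csrpath.network import TreatmentCondition
from csrpath.optimize import (
    SolverError,
    edge_frequencies,
    enumerate_pool,
    exhaustive_search,
    fit_error,
    solve,
)
from csrpath.synthetic import (
    SyntheticSpec,
    chain_dataset,
    chain_network,
    full_factorial_conditions,
    generate_network,
    simulate_dataset,
)


def test_no_measurements_prunes_everything(two_path_net):
    cond = TreatmentCondition("k1", stimuli_on=["S"])
    data = make_table([cond], signals={"T": [np.nan]})
    sol = solve(build_ilp(two_path_net, data))
    assert sol.objective_value == 0.0
    assert set(sol.presence.values()) == {0}


def test_chain_worked_example_keeps_all_reactions():
    net = chain_network(12)
    sol = solve(build_ilp(net, chain_dataset(net)))
    assert sum(sol.presence.values()) == 12
    assert sol.objective_value == pytest.approx(0.6)


def test_contradicted_response_edge_removed(response_net):
    # signal measured ON keeps the canonical step; response measured at 0
    # forces the single non-canonical edge out; remaining cost is one beta
    cond = TreatmentCondition("k1", stimuli_on=["S"])
    data = make_table([cond], signals={"G": [1.0]}, responses={"Q": [0.0]})
    sol = solve(build_ilp(response_net, data))
    assert sol.presence == {"r1": 1, "e1": 0}
    assert sol.objective_value == pytest.approx(1 / 20)
    best, _ = exhaustive_search(response_net, data)
    assert best == pytest.approx(sol.objective_value)


def test_unknown_backend_rejected(two_path_net, two_path_data):
    with pytest.raises(SolverError, match="backend"):
        solve(build_ilp(two_path_net, two_path_data), backend="gurobi")


def test_unique_optimum_gives_pool_of_one():
    net = chain_network(3)
    pool = enumerate_pool(build_ilp(net, chain_dataset(net)))
    assert len(pool) == 1


def test_mirror_paths_give_two_solutions_with_half_frequencies(
    two_path_net, two_path_data
):
    pool = enumerate_pool(build_ilp(two_path_net, two_path_data))
    assert len(pool) == 2
    assert pool.optimum == pytest.approx(0.1)
    freq = edge_frequencies(pool)
    assert freq == {"r1": 0.5, "r2": 0.5, "r3": 0.5, "r4": 0.5}
    # presence vectors pairwise distinct, all within tolerance
    vecs = {tuple(sorted(s.presence.items())) for s in pool.solutions}
    assert len(vecs) == 2
    assert all(v <= pool.optimum * 1.1 + 1e-9 for v in pool.objective_values)


def test_pool_complete_when_below_cap(two_path_net, two_path_data):
    # exhaustive enumeration over all presence vectors finds the same
    # near-optimal set as the no-good-cut harvest
    problem = build_ilp(two_path_net, two_path_data)
    pool = enumerate_pool(problem, tolerance=0.10, max_solutions=100)
    cutoff = pool.optimum * 1.1 + 1e-9
    from csrpath.optimize import simulated_objective

    ids = [r.id for r in two_path_net.reactions]
    n_within = sum(
        simulated_objective(
            two_path_net, two_path_data, dict(zip(ids, bits))
        )
        <= cutoff
        for bits in itertools.product((0, 1), repeat=len(ids))
    )
    assert n_within == len(pool)


def test_oracle_equivalence_on_random_small_instances():
    # ILP optimum == brute force over all presence vectors (states by
    # forward simulation) on 50 random instances
    for trial in range(50):
        spec = SyntheticSpec(
            n_stimuli=2,
            n_intermediates=3,
            n_signals=2,
            n_responses=2,
            n_reactions=5,
            n_inhibitors=1,
            n_decoys=1,
            edge_density=0.4,
            noise_sd=0.15,
            seed=1000 + trial,
        )
        gt = generate_network(spec)
        conds = full_factorial_conditions(gt)[:6]
        data = simulate_dataset(gt, conditions=conds, noise_sd=0.15, seed=trial)
        sol = solve(build_ilp(gt.network, data))
        best, _ = exhaustive_search(gt.network, data)
        assert sol.objective_value == pytest.approx(best, abs=1e-6)


def test_empty_pool_frequencies_rejected():
    from csrpath.optimize import SolutionPool

    with pytest.raises(ValueError, match="empty"):
        edge_frequencies(SolutionPool([], 0.1, 0.0))


# --- fit error -------------------------------------------------------------


def test_fit_error_zero_on_perfect_agreement(two_path_net):
    cond = TreatmentCondition("k1", stimuli_on=["S"])
    data = make_table([cond], signals={"T": [1.0]})
    presence = {r.id: 1 for r in two_path_net.reactions}
    assert fit_error(two_path_net, presence, data) == 0.0


def test_fit_error_hundred_when_every_binary_prediction_wrong(two_path_net):
    cond = TreatmentCondition("k1")  # stimulus off -> T predicted 0
    data = make_table([cond], signals={"T": [1.0]})
    presence = {r.id: 1 for r in two_path_net.reactions}
    assert fit_error(two_path_net, presence, data) == 100.0


def test_fit_error_is_mean_absolute_deviation_percent(two_path_net):
    # 10 measured entries, one deviating by 0.5 -> 5%
    conds = [TreatmentCondition(f"k{i}", stimuli_on=["S"]) for i in range(10)]
    vals = [1.0] * 10
    vals[3] = 0.5
    data = make_table(conds, signals={"T": vals})
    presence = {r.id: 1 for r in two_path_net.reactions}
    assert fit_error(two_path_net, presence, data) == pytest.approx(5.0)


def test_fit_error_requires_measured_entries(two_path_net):
    cond = TreatmentCondition("k1")
    data = make_table([cond], signals={"T": [np.nan]})
    with pytest.raises(ValueError, match="no measured"):
        fit_error(two_path_net, {r.id: 1 for r in two_path_net.reactions}, data)


def test_optimised_topology_never_fits_worse_than_generic():
    # with beta = 0 the optimal presence minimises pure L1 mismatch, so its
    # fit error cannot exceed the all-edges topology's
    for seed in range(5):
        spec = SyntheticSpec(
            n_stimuli=3,
            n_intermediates=4,
            n_signals=3,
            n_responses=2,
            n_reactions=8,
            n_inhibitors=2,
            n_decoys=2,
            edge_density=0.5,
            noise_sd=0.1,
            seed=seed,
        )
        gt = generate_network(spec)
        data = simulate_dataset(gt)
        net = gt.network
        sol = solve(build_ilp(net, data, ObjectiveWeights(beta_size=0.0)))
        generic = {i: 1 for i in sol.presence}
        assert fit_error(net, sol.presence, data) <= fit_error(net, generic, data) + 1e-9
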