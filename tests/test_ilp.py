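import numpy as np
import pytest

from conftest import make_table
from csrpath.ilp import ObjectiveWeights, build_ilp, yield_bounds
from csrpath.network import (
    ExtendedNetwork,
    NonCanonicalEdge,
    Reaction,
    Role,
    Species,
    TreatmentCondition,
)
from csrpath.optimize import objective_from_presence, solve
from csrpath.synthetic import chain_dataset, chain_network


@pytest.mark.parametrize(
    "weights, expected",
    [
        ([0.5, 0.3], (0.0, 0.8)),
        ([-0.2, 0.7], (-0.2, 0.7)),
        ([], (0.0, 0.0)),
    ],
)
def test_yield_bounds_are_signed_sums(weights, expected):
    edges = [NonCanonicalEdge(f"e{i}", "G", "Q", w) for i, w in enumerate(weights)]
    yb = yield_bounds(edges)
    assert (yb.b_min, yb.b_max) == pytest.approx(expected)
    assert yb.b_min <= 0 <= yb.b_max


def test_yield_bounds_rejects_mixed_targets():
    edges = [
        NonCanonicalEdge("e1", "G", "Q1", 0.5),
        NonCanonicalEdge("e2", "G", "Q2", 0.5),
    ]
    with pytest.raises(ValueError, match="same response"):
        yield_bounds(edges)


def test_objective_weight_defaults_and_validation():
    w = ObjectiveWeights()
    assert (w.alpha_signal, w.alpha_response, w.beta_size) == (1.0, 1.0, 1 / 20)
    with pytest.raises(ValueError):
        ObjectiveWeights(beta_size=-0.1)


def test_chain_size_term_contributes_12_beta():
    # keeping the full 12-reaction chain costs exactly 12 size units
    net = chain_network(12)
    data = chain_dataset(net)
    problem = build_ilp(net, data)
    all_on = {r.id: 1 for r in net.reactions}
    assert objective_from_presence(problem, all_on) == pytest.approx(12 / 20)


def test_without_response_edges_no_response_terms():
    net = chain_network(3)
    data = chain_dataset(net)
    problem = build_ilp(net, data)
    assert not problem.e_index
    # signal mismatch terms: one per measured entry; size terms: one per y
    assert problem.offset == pytest.approx(2.0)  # two entries measured at 1


def test_single_edge_scaled_prediction_equals_activation(response_net):
    # with one positive edge the scaled prediction is exactly z
    cond = TreatmentCondition("k1", stimuli_on=["S"])
    data = make_table([cond], signals={"G": [1.0]}, responses={"Q": [1.0]})
    problem = build_ilp(response_net, data)
    sol = solve(problem)
    assert sol.presence == {"r1": 1, "e1": 1}
    assert sol.objective_value == pytest.approx(2 / 20)


def test_scaled_prediction_invariant_random_edge_sets():
    # s = (sum w z - b_min) / (b_max - b_min) always lies in [0, 1]
    rng = np.random.default_rng(11)
    for _ in range(1000):
        k = rng.integers(1, 7)
        ws = rng.uniform(-1, 1, k)
        z = rng.integers(0, 2, k)
        b_min = ws[ws < 0].sum()
        b_max = ws[ws > 0].sum()
        raw = float(ws @ z)
        if b_max - b_min <= 0:
            continue
        s = (raw - b_min) / (b_max - b_min)
        assert -1e-12 <= s <= 1 + 1e-12
        edges = [NonCanonicalEdge(f"e{i}", f"G{i}", "Q", w) for i, w in enumerate(ws)]
        from csrpath.simulate import predict_responses

        states = {f"G{i}": int(v) for i, v in enumerate(z)}
        assert predict_responses(states, edges)["Q"] == pytest.approx(s)


def test_objective_equals_independent_recomputation(two_path_net, two_path_data):
    problem = build_ilp(two_path_net, two_path_data)
    sol = solve(problem)
    assert objective_from_presence(problem, sol.presence) == pytest.approx(
        sol.objective_value, abs=1e-9
    )


def test_mismatch_lower_bound_is_monotone_in_beta(two_path_net, two_path_data):
    def mismatch(beta):
        problem = build_ilp(
            two_path_net, two_path_data, ObjectiveWeights(beta_size=beta)
        )
        sol = solve(problem)
        return sol.objective_value - beta * sum(sol.presence.values())

    assert mismatch(0.0) <= mismatch(0.05) + 1e-9
    assert mismatch(0.0) <= mismatch(0.5) + 1e-9


def test_degenerate_yield_bounds_drop_response_with_warning(response_net):
    net = ExtendedNetwork(
        response_net.species,
        response_net.reactions,
        [NonCanonicalEdge("e1", "G", "Q", 0.0)],
    )
    cond = TreatmentCondition("k1", stimuli_on=["S"])
    data = make_table([cond], signals={"G": [1.0]}, responses={"Q": [0.5]})
    problem = build_ilp(net, data)
    assert problem.dropped_responses == ["Q"]
    assert problem.warnings


def test_cyclic_network_refused_without_flag():
    species = [
        Species("S", Role.STIMULUS),
        Species("A", Role.INTERMEDIATE),
        Species("B", Role.MEASURED_SIGNAL),
    ]
    reactions = [
        Reaction("r1", ["S"], [], "A"),
        Reaction("r2", ["A"], [], "B"),
        Reaction("r3", ["B"], [], "A"),
    ]
    net = ExtendedNetwork(species, reactions)
    cond = TreatmentCondition("k1")  # stimulus OFF
    data = make_table([cond], signals={"B": [1.0]})
    with pytest.raises(ValueError, match="cyclic"):
        build_ilp(net, data)
    # with least-fixed-point semantics the A<->B loop cannot self-sustain:
    # B measured ON without the stimulus is an unavoidable mismatch of 1
    problem = build_ilp(net, data, allow_cycles=True)
    sol = solve(problem)
    assert sol.objective_value == pytest.approx(1.0)
    assert all(v == 0 for v in sol.states.values())


def test_invalid_topology_rejected_at_build(two_path_data, two_path_net):
    two_path_net.reactions.append(Reaction("rbad", ["NOPE"], [], "T"))
    with pytest.raises(ValueError, match="invalid topology"):
        build_ilp(two_path_net, two_path_data)


def test_lp_export_contains_all_variables(two_path_net, two_path_data):
    from csrpath.ilp import to_lp_string

    problem = build_ilp(two_path_net, two_path_data)
    lp = to_lp_string(problem)
    assert lp.startswith("Minimize") and lp.rstrip().endswith("End")
    for rid in ("r1", "r2", "r3", "r4"):
        assert f"y_{rid}" in lp
    assert "x_T_k1" in lp and "Binary" in lp


def test_ilp_states_match_forward_simulation_at_fixed_presence():
    # restrict the constraint set to a random presence vector: the unique
    # feasible states must equal the least fixed point of forward simulation
    import numpy as np

    from csrpath.optimize import solve as _solve
    from csrpath.simulate import simulate
    from csrpath.synthetic import (
        SyntheticSpec,
        full_factorial_conditions,
        generate_network,
        simulate_dataset,
    )

    rng = np.random.default_rng(23)
    for trial in range(15):
        gt = generate_network(
            SyntheticSpec(
                n_stimuli=2,
                n_intermediates=4,
                n_signals=2,
                n_responses=2,
                n_reactions=7,
                n_inhibitors=2,
                edge_density=0.5,
                noise_sd=0.1,
                seed=400 + trial,
            )
        )
        conds = full_factorial_conditions(gt)[:4]
        data = simulate_dataset(gt, conditions=conds, noise_sd=0.1, seed=trial)
        problem = build_ilp(gt.network, data)
        fixed = {eid: int(rng.integers(0, 2)) for eid in problem.y_index}
        sol = _solve(problem, fixed=fixed)
        assert sol.presence == fixed
        for cond in conds:
            states = simulate(gt.network, fixed, cond).states
            for name, v in states.items():
                if (name, cond.id) in sol.states:
                    assert sol.states[(name, cond.id)] == v
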