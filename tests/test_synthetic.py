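import numpy as np
import pytest

from csrpath.network import validate_topology
from csrpath.optimize import fit_error
from csrpath.synthetic import (
    SyntheticSpec,
    chain_network,
    full_factorial_conditions,
    generate_network,
    perturb_topology,
    simulate_dataset,
    subsample_conditions,
)

SMALL = SyntheticSpec(
    n_stimuli=3,
    n_intermediates=5,
    n_signals=3,
    n_responses=2,
    n_reactions=10,
    n_inhibitors=2,
    n_decoys=2,
    edge_density=0.5,
    noise_sd=0.05,
    seed=42,
)

STUDY = SyntheticSpec()  # defaults emulate the study design


def net_key(net):
    return (
        {(r.id, r.activators, r.inhibitors, r.product) for r in net.reactions},
        {(e.id, e.source, e.target, e.weight) for e in net.response_edges},
    )


def test_same_seed_reproduces_network_exactly():
    assert net_key(generate_network(SMALL).network) == net_key(
        generate_network(SMALL).network
    )


def test_generated_network_is_valid_and_acyclic():
    gt = generate_network(SMALL)
    report = validate_topology(gt.network)
    assert report.ok and not report.cycles
    assert len(gt.network.reactions) == SMALL.n_reactions + SMALL.n_decoys
    assert sum(gt.presence[r.id] for r in gt.network.reactions) == SMALL.n_reactions


def test_study_defaults_match_emulated_design():
    gt = generate_network(STUDY)
    net = gt.network
    assert len(net.stimuli) == 7
    assert len(net.measured_signals) == 16
    assert len(net.responses) == 22
    assert len(net.reactions) == 113
    assert len(net.response_edges) == 352  # full candidate set at density 1
    assert len(full_factorial_conditions(gt)) == 48


def test_chain_mode_builds_the_worked_example():
    gt = generate_network(SyntheticSpec(n_reactions=12, topology="chain"))
    net = gt.network
    assert [r.id for r in net.reactions] == [f"R{i}" for i in range(1, 13)]
    assert net.measured_signals == ["C1", "C12"]
    assert net_key(net) == net_key(chain_network(12))


def test_zero_edge_density_gives_no_response_edges():
    spec = SyntheticSpec(
        n_stimuli=2,
        n_intermediates=3,
        n_signals=2,
        n_responses=2,
        n_reactions=6,
        edge_density=0.0,
        seed=1,
    )
    assert generate_network(spec).network.response_edges == []


def test_requesting_more_reactions_than_acyclic_capacity_errors():
    with pytest.raises(ValueError, match="capacity"):
        generate_network(
            SyntheticSpec(
                n_stimuli=1,
                n_intermediates=2,
                n_signals=1,
                n_responses=1,
                n_reactions=50,
                seed=0,
            )
        )


def test_dataset_values_clipped_and_reproducible():
    gt = generate_network(SMALL)
    d1 = simulate_dataset(gt, noise_sd=0.05, seed=3)
    d2 = simulate_dataset(gt, noise_sd=0.05, seed=3)
    d3 = simulate_dataset(gt, noise_sd=0.05, seed=4)
    assert d1.signals.equals(d2.signals)
    assert not d1.signals.equals(d3.signals)
    for df in (d1.signals, d1.responses):
        assert ((df >= 0) & (df <= 1)).all().all()


def test_two_seeds_share_the_noiseless_component():
    gt = generate_network(SMALL)
    clean = simulate_dataset(gt, noise_sd=0.0, seed=0)
    n1 = simulate_dataset(gt, noise_sd=0.05, seed=1)
    # noiseless signal states are binary; noisy values stay within the
    # noise envelope of the same underlying states
    assert set(np.unique(clean.signals.values)) <= {0.0, 1.0}
    assert (np.abs(n1.signals.values - clean.signals.values) < 0.4).all()


def test_noiseless_truth_has_zero_fit_error():
    gt = generate_network(SMALL)
    data = simulate_dataset(gt, noise_sd=0.0, seed=0)
    assert fit_error(gt.network, gt.presence, data) == pytest.approx(0.0)


# --- perturbation ----------------------------------------------------------


def test_perturb_fraction_zero_is_identity():
    gt = generate_network(SMALL)
    assert net_key(perturb_topology(gt.network, 0.0, seed=1)) == net_key(gt.network)


def test_perturb_substitutes_round_fraction_of_reactions():
    gt = generate_network(SyntheticSpec(seed=7))  # 113 reactions
    net2 = perturb_topology(gt.network, 0.10, seed=9)
    orig = {r.id: (r.activators, r.inhibitors, r.product) for r in gt.network.reactions}
    changed = [
        r.id
        for r in net2.reactions
        if (r.activators, r.inhibitors, r.product) != orig[r.id]
    ]
    assert len(changed) == 11  # round(0.10 * 113)
    assert validate_topology(net2).ok and not validate_topology(net2).cycles


def test_perturb_deterministic_per_seed():
    gt = generate_network(SMALL)
    assert net_key(perturb_topology(gt.network, 0.3, seed=5)) == net_key(
        perturb_topology(gt.network, 0.3, seed=5)
    )
    assert net_key(perturb_topology(gt.network, 0.3, seed=5)) != net_key(
        perturb_topology(gt.network, 0.3, seed=6)
    )


# --- subsampling -----------------------------------------------------------


def test_subsample_full_fraction_is_identity():
    gt = generate_network(SMALL)
    data = simulate_dataset(gt)
    sub = subsample_conditions(data, 1.0, seed=0)
    assert [c.id for c in sub.conditions] == [c.id for c in data.conditions]


def test_subsample_half_of_48_keeps_24():
    gt = generate_network(STUDY)
    data = simulate_dataset(gt)
    sub = subsample_conditions(data, 0.5, seed=0)
    assert sub.n_conditions == 24
    assert sub.signals.shape[0] == 24


def test_subsample_seeds_pick_different_subsets():
    gt = generate_network(STUDY)
    data = simulate_dataset(gt)
    ids = lambda t: [c.id for c in t.conditions]
    assert ids(subsample_conditions(data, 0.5, seed=1)) != ids(
        subsample_conditions(data, 0.5, seed=2)
    )


def test_subsample_rejects_empty_result():
    gt = generate_network(SMALL)
    data = simulate_dataset(gt)
    with pytest.raises(ValueError):
        subsample_conditions(data, 0.001, seed=0)
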