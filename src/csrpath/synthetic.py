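"""Synthetic ground-truth networks, noisy CSR datasets, and the
sensitivity harness (topology perturbation, treatment subsampling).

The generator emulates the study design this tool targets: a combinatorial
single-stimulus x single-inhibitor treatment grid (8 x 6 = 48 conditions by
default), ~16 measured phosphoprotein signals, ~22 response species, values
on [0, 1] with additive assay noise.  Ground truth is explicit: the
candidate network may carry *decoy* reactions whose true presence is 0;
datasets are always simulated from the presence-1 subnetwork, so decoys are
exactly the edges the data argues against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExperimentTable
from .network import (
    ExtendedNetwork,
    NonCanonicalEdge,
    Reaction,
    Role,
    Species,
    TreatmentCondition,
)
from .regression import edge_id
from .simulate import BLOCK_ACTIVITY, simulate

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_network",
    "chain_network",
    "chain_dataset",
    "full_factorial_conditions",
    "simulate_dataset",
    "perturb_topology",
    "subsample_conditions",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters, defaulting to the emulated study design."""

    n_stimuli: int = 7
    n_intermediates: int = 34
    n_signals: int = 16
    n_responses: int = 22
    n_reactions: int = 113
    n_inhibitors: int = 5
    n_decoys: int = 0
    edge_density: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0
    topology: str = "dag"  # "dag" | "chain"
    and_gate_prob: float = 0.1
    inhibitor_gate_prob: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "n_stimuli",
            "n_intermediates",
            "n_signals",
            "n_responses",
            "n_reactions",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.edge_density <= 1):
            raise ValueError("edge_density must be in [0, 1]")


@dataclass
class GroundTruth:
    """A candidate network with its true presence vector and treatment
    vocabulary."""

    network: ExtendedNetwork
    presence: dict[str, int]
    inhibitor_targets: dict[str, str] = field(default_factory=dict)
    spec: SyntheticSpec | None = None

    @property
    def true_subnetwork_presence(self) -> dict[str, int]:
        return dict(self.presence)


def _topological_names(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    stim = [f"STIM{i + 1}" for i in range(spec.n_stimuli)]
    inter = [f"INT{i + 1}" for i in range(spec.n_intermediates)]
    sig = [f"SIG{i + 1}" for i in range(spec.n_signals)]
    return stim, inter, sig


def generate_network(spec: SyntheticSpec) -> GroundTruth:
    """Random acyclic ground-truth network (deterministic per seed).

    Species are laid out in a fixed topological order (stimuli, then
    intermediates, then measured signals); every reaction points forward in
    that order, so the canonical sub-network is acyclic by construction.
    Each non-stimulus species first receives one backbone producing
    reaction (reachability), then extra reactions are sampled up to
    ``n_reactions``; ``n_decoys`` additional reactions are appended with
    ground-truth presence 0.  Non-canonical edge weights are drawn
    uniformly from [-1, -0.1] u [0.1, 1] at ``edge_density``.
    """
    if spec.topology == "chain":
        net = chain_network(spec.n_reactions)
        presence = {r.id: 1 for r in net.reactions}
        return GroundTruth(network=net, presence=presence, spec=spec)

    rng = np.random.default_rng(spec.seed)
    stim, inter, sig = _topological_names(spec)
    order = stim + inter + sig
    pos = {n: i for i, n in enumerate(order)}
    products = inter + sig

    capacity = sum(pos[p] for p in products)
    if spec.n_reactions + spec.n_decoys > capacity:
        raise ValueError(
            f"requested {spec.n_reactions + spec.n_decoys} reactions exceed "
            f"acyclic capacity {capacity}"
        )

    used_pairs: set[tuple[str, str]] = set()
    reactions: list[Reaction] = []

    def add_reaction(activators, inhibitors, product) -> None:
        reactions.append(
            Reaction(
                id=f"r{len(reactions) + 1}",
                activators=activators,
                inhibitors=inhibitors,
                product=product,
            )
        )

    # backbone: one producer per non-stimulus species, in order
    for p in products:
        if len(reactions) >= spec.n_reactions:
            break
        a = order[rng.integers(0, pos[p])]
        used_pairs.add((a, p))
        add_reaction([a], [], p)

    attempts = 0
    while len(reactions) < spec.n_reactions and attempts < 50_000:
        attempts += 1
        p = products[rng.integers(0, len(products))]
        if pos[p] == 0:
            continue
        a = order[rng.integers(0, pos[p])]
        if (a, p) in used_pairs:
            continue
        inhibitors: list[str] = []
        activators = [a]
        if pos[p] > 1 and rng.random() < spec.inhibitor_gate_prob:
            q = order[rng.integers(0, pos[p])]
            if q != a:
                inhibitors = [q]
        elif pos[p] > 1 and rng.random() < spec.and_gate_prob:
            a2 = order[rng.integers(0, pos[p])]
            if a2 != a:
                activators.append(a2)
        used_pairs.add((a, p))
        add_reaction(activators, inhibitors, p)
    if len(reactions) < spec.n_reactions:
        raise ValueError("could not place the requested number of reactions")

    presence = {r.id: 1 for r in reactions}
    for d in range(spec.n_decoys):
        while True:
            p = products[rng.integers(0, len(products))]
            if pos[p] == 0:
                continue
            a = order[rng.integers(0, pos[p])]
            if (a, p) not in used_pairs:
                break
        used_pairs.add((a, p))
        rid = f"decoy{d + 1}"
        reactions.append(Reaction(id=rid, activators=[a], inhibitors=[], product=p))
        presence[rid] = 0

    responses = [f"RES{i + 1}" for i in range(spec.n_responses)]
    edges: list[NonCanonicalEdge] = []
    for r in responses:
        for s in sig:
            if rng.random() < spec.edge_density:
                w = rng.uniform(0.1, 1.0) * (1 if rng.random() < 0.5 else -1)
                edges.append(NonCanonicalEdge(id=edge_id(s, r), source=s, target=r, weight=w))
                presence[edge_id(s, r)] = 1

    species = (
        [Species(nm, Role.STIMULUS) for nm in stim]
        + [Species(nm, Role.INTERMEDIATE) for nm in inter]
        + [Species(nm, Role.MEASURED_SIGNAL) for nm in sig]
        + [Species(nm, Role.RESPONSE) for nm in responses]
    )
    net = ExtendedNetwork(species=species, reactions=reactions, response_edges=edges)

    # inhibitors silence frequently-used upstream species
    activator_use: dict[str, int] = {}
    for r in reactions:
        for a in r.activators:
            if a not in stim:
                activator_use[a] = activator_use.get(a, 0) + 1
    ranked = sorted(activator_use, key=lambda k: (-activator_use[k], k))
    targets = ranked[: spec.n_inhibitors]
    inhibitor_targets = {f"INH{i + 1}": t for i, t in enumerate(targets)}
    return GroundTruth(
        network=net, presence=presence, inhibitor_targets=inhibitor_targets, spec=spec
    )


def chain_network(n: int = 12) -> ExtendedNetwork:
    """Linear chain worked example: a stimulus feeding n consecutive
    reactions R1..Rn; the first and last products are measured."""
    names = ["S0"] + [f"C{i}" for i in range(1, n + 1)]
    species = [Species("S0", Role.STIMULUS)]
    for i in range(1, n + 1):
        role = Role.MEASURED_SIGNAL if i in (1, n) else Role.INTERMEDIATE
        species.append(Species(f"C{i}", role))
    reactions = [
        Reaction(id=f"R{i}", activators=[names[i - 1]], inhibitors=[], product=names[i])
        for i in range(1, n + 1)
    ]
    return ExtendedNetwork(species=species, reactions=reactions, response_edges=[])


def chain_dataset(net: ExtendedNetwork) -> ExperimentTable:
    """Single stimulated condition with the first and last chain species
    measured active (the relation "first = 1 implies last = 1")."""
    cond = TreatmentCondition(id="k1", stimuli_on=net.stimuli)
    sig = net.measured_signals
    signals = pd.DataFrame([[1.0] * len(sig)], index=["k1"], columns=sig)
    responses = pd.DataFrame(index=["k1"], columns=[], dtype=float)
    return ExperimentTable(conditions=[cond], signals=signals, responses=responses)


def parallel_motifs(n_motifs: int = 7) -> tuple[ExtendedNetwork, ExperimentTable]:
    """Degenerate-optimum benchmark: independent stimulus -> A -> target
    motifs in which A is reachable through two interchangeable parallel
    routes, so the instance has exactly 2**n_motifs equally optimal
    topologies.  Every target is measured active in a single condition."""
    species: list[Species] = []
    reactions: list[Reaction] = []
    sig: list[str] = []
    for m in range(1, n_motifs + 1):
        s, b1, b2, a, t = f"S{m}", f"B1_{m}", f"B2_{m}", f"A{m}", f"T{m}"
        species += [
            Species(s, Role.STIMULUS),
            Species(b1, Role.INTERMEDIATE),
            Species(b2, Role.INTERMEDIATE),
            Species(a, Role.INTERMEDIATE),
            Species(t, Role.MEASURED_SIGNAL),
        ]
        reactions += [
            Reaction(f"m{m}_sb1", [s], [], b1),
            Reaction(f"m{m}_sb2", [s], [], b2),
            Reaction(f"m{m}_b1a", [b1], [], a),
            Reaction(f"m{m}_b2a", [b2], [], a),
            Reaction(f"m{m}_at", [a], [], t),
        ]
        sig.append(t)
    net = ExtendedNetwork(species=species, reactions=reactions)
    cond = TreatmentCondition("k1", stimuli_on=[f"S{m}" for m in range(1, n_motifs + 1)])
    data = ExperimentTable(
        conditions=[cond],
        signals=pd.DataFrame([[1.0] * len(sig)], index=["k1"], columns=sig),
        responses=pd.DataFrame(index=["k1"], columns=[], dtype=float),
    )
    return net, data


def full_factorial_conditions(gt: GroundTruth) -> list[TreatmentCondition]:
    """(no stimulus + each single stimulus) x (no inhibitor + each single
    inhibitor) — the emulated experimental design."""
    stim = gt.network.stimuli
    inhs = sorted(gt.inhibitor_targets)
    conds = []
    k = 0
    for s in [None] + stim:
        for i in [None] + inhs:
            k += 1
            conds.append(
                TreatmentCondition(
                    id=f"c{k:02d}",
                    stimuli_on=[s] if s else [],
                    inhibitors_on=[i] if i else [],
                    inhibitor_targets=gt.inhibitor_targets,
                )
            )
    return conds


def simulate_dataset(
    gt: GroundTruth,
    conditions: list[TreatmentCondition] | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
    inhibitor_mode: str = BLOCK_ACTIVITY,
) -> ExperimentTable:
    """Noisy measurements of the true (presence-1) subnetwork.

    Signal measurements are the Boolean states of the measured signals;
    response measurements are the yield-scaled predictions.  Additive
    Gaussian noise (sd ``noise_sd``) is applied and values are clipped to
    [0, 1], mimicking a normalised assay.
    """
    net = gt.network
    conditions = conditions if conditions is not None else full_factorial_conditions(gt)
    noise_sd = gt.spec.noise_sd if noise_sd is None and gt.spec else (noise_sd or 0.0)
    seed = gt.spec.seed if seed is None and gt.spec else (seed or 0)
    rng = np.random.default_rng(seed)

    sig_names = net.measured_signals
    resp_names = sorted({e.target for e in net.response_edges})
    sig_rows, resp_rows = [], []
    for cond in conditions:
        assignment = simulate(net, gt.presence, cond, inhibitor_mode=inhibitor_mode)
        sig_rows.append([float(assignment.states[s]) for s in sig_names])
        resp_rows.append(
            [assignment.response_values.get(r, 0.0) for r in resp_names]
        )
    ids = [c.id for c in conditions]
    signals = pd.DataFrame(sig_rows, index=ids, columns=sig_names)
    responses = pd.DataFrame(resp_rows, index=ids, columns=resp_names)
    if noise_sd > 0:
        signals += rng.normal(0.0, noise_sd, signals.shape)
        responses += rng.normal(0.0, noise_sd, responses.shape)
    signals = signals.clip(0.0, 1.0)
    responses = responses.clip(0.0, 1.0)
    return ExperimentTable(conditions=conditions, signals=signals, responses=responses)


def perturb_topology(
    net: ExtendedNetwork, fraction: float, seed: int = 0
) -> ExtendedNetwork:
    """Replace round(fraction * |reactions|) reactions with random valid
    ones (acyclicity preserved), mirroring the random-substitution
    sensitivity protocol.  Deterministic per seed."""
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    n_sub = round(fraction * len(net.reactions))
    if n_sub == 0:
        return ExtendedNetwork(
            species=list(net.species),
            reactions=list(net.reactions),
            response_edges=list(net.response_edges),
        )
    rng = np.random.default_rng(seed)
    import networkx as nx

    order = list(nx.topological_sort(net.canonical_graph()))
    non_resp = {
        s.name for s in net.species if s.role not in (Role.RESPONSE, Role.STIMULUS)
    }
    for s in net.species:  # orphans missing from the graph
        if s.role != Role.RESPONSE and s.name not in order:
            order.append(s.name)
    pos = {n: i for i, n in enumerate(order)}
    victims = set(
        rng.choice(len(net.reactions), size=n_sub, replace=False).tolist()
    )
    # avoid duplicating reactions that remain; substituted pairs are free
    existing = {
        (next(iter(r.activators)), r.product)
        for idx, r in enumerate(net.reactions)
        if idx not in victims and len(r.activators) == 1 and not r.inhibitors
    }
    reactions = []
    products = sorted(non_resp, key=pos.__getitem__)
    for idx, r in enumerate(net.reactions):
        if idx not in victims:
            reactions.append(r)
            continue
        for _ in range(10_000):
            p = products[rng.integers(0, len(products))]
            if pos[p] == 0:
                continue
            a = order[rng.integers(0, pos[p])]
            if a == p or (a, p) in existing:
                continue
            existing.add((a, p))
            reactions.append(
                Reaction(id=r.id, activators=[a], inhibitors=[], product=p)
            )
            break
        else:
            raise RuntimeError("could not place a substitute reaction")
    return ExtendedNetwork(
        species=list(net.species),
        reactions=reactions,
        response_edges=list(net.response_edges),
    )


def forced_edges(
    problem,
    tolerance: float = 0.10,
    backend: str = "highs",
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Classify presence variables against the near-optimal pool.

    An edge is *forced in* (identifiable from the data) when pinning it to
    0 pushes the optimum above the pool cutoff — every pooled solution must
    then contain it.  It is *forced out* (contradicted by the data) when
    pinning it to 1 does.  Exact with respect to pool semantics.
    """
    from .optimize import pool_cutoff, solve

    base = solve(problem, backend=backend, seed=seed)
    cutoff = pool_cutoff(base.objective_value, tolerance, problem.weights.beta_size)
    cutoff += 1e-9 + 1e-7 * max(1.0, abs(base.objective_value))
    forced_in: set[str] = set()
    forced_out: set[str] = set()
    for eid in problem.y_index:
        if base.presence[eid] == 1:
            alt = solve(problem, backend=backend, seed=seed, fixed={eid: 0})
            if alt.objective_value > cutoff:
                forced_in.add(eid)
        else:
            alt = solve(problem, backend=backend, seed=seed, fixed={eid: 1})
            if alt.objective_value > cutoff:
                forced_out.add(eid)
    return forced_in, forced_out


def optimise_and_evaluate(
    net: ExtendedNetwork,
    train: ExperimentTable,
    evaluate: ExperimentTable | None = None,
    weights=None,
    inhibitor_mode: str = BLOCK_ACTIVITY,
    backend: str = "highs",
    seed: int = 0,
) -> float:
    """Optimise the topology against ``train`` and return the fit error (%)
    of the optimal topology on ``evaluate`` (default: the training table).
    The workhorse of the sensitivity harness."""
    from .ilp import ObjectiveWeights, build_ilp
    from .optimize import fit_error, solve

    weights = weights or ObjectiveWeights()
    problem = build_ilp(net, train, weights, inhibitor_mode=inhibitor_mode)
    sol = solve(problem, backend=backend, seed=seed)
    return fit_error(
        net, sol.presence, evaluate if evaluate is not None else train, inhibitor_mode
    )


def subsample_conditions(
    data: ExperimentTable, fraction: float, seed: int = 0
) -> ExperimentTable:
    """Keep round(fraction * K) conditions, uniformly without replacement;
    deterministic per seed."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = round(fraction * data.n_conditions)
    if k == 0:
        raise ValueError("fraction leaves zero conditions")
    rng = np.random.default_rng(seed)
    keep_idx = sorted(rng.choice(data.n_conditions, size=k, replace=False).tolist())
    ids = [data.conditions[i].id for i in keep_idx]
    return data.subset(ids)
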