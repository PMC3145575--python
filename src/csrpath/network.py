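"""Domain model for extended signalling networks.

An extended network couples a literature-derived Boolean signalling map
(stimuli, intermediates and measured phosphoprotein signals connected by
signed hyperedge reactions) with regression-weighted *non-canonical* edges
that link measured signals to downstream response species (e.g. secreted
cytokines).  The canonical part carries on/off semantics; the non-canonical
part carries real-valued stoichiometric yields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Role",
    "Species",
    "Reaction",
    "NonCanonicalEdge",
    "TreatmentCondition",
    "ExtendedNetwork",
    "ValidationReport",
    "validate_topology",
]


class Role(str, Enum):
    """Functional role of a species in the cue-signal-response layout."""

    STIMULUS = "stimulus"
    INTERMEDIATE = "intermediate"
    MEASURED_SIGNAL = "measured_signal"
    RESPONSE = "response"


@dataclass(frozen=True)
class Species:
    name: str
    role: Role

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class Reaction:
    """A signed Boolean hyperedge.

    The reaction fires when every activator is active and every
    inhibitor-reactant is inactive; firing switches the product on.
    """

    id: str
    activators: frozenset[str]
    inhibitors: frozenset[str]
    product: str

    def __init__(
        self,
        id: str,
        activators: Iterable[str] = (),
        inhibitors: Iterable[str] = (),
        product: str = "",
    ) -> None:
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "activators", frozenset(activators))
        object.__setattr__(self, "inhibitors", frozenset(inhibitors))
        object.__setattr__(self, "product", product)

    @property
    def reactants(self) -> frozenset[str]:
        return self.activators | self.inhibitors


@dataclass(frozen=True)
class NonCanonicalEdge:
    """Weighted signal-to-response edge; the weight is an MLR coefficient
    acting as the stoichiometric yield of the edge."""

    id: str
    source: str
    target: str
    weight: float


@dataclass(frozen=True)
class TreatmentCondition:
    """One experimental condition: which stimuli and drugs are applied.

    ``inhibitor_targets`` maps each drug name to the species whose activity
    it blocks; two drugs may share a target (e.g. two EGFR inhibitors).
    """

    id: str
    stimuli_on: frozenset[str] = frozenset()
    inhibitors_on: frozenset[str] = frozenset()
    inhibitor_targets: Mapping[str, str] = field(default_factory=dict)

    def __init__(
        self,
        id: str,
        stimuli_on: Iterable[str] = (),
        inhibitors_on: Iterable[str] = (),
        inhibitor_targets: Mapping[str, str] | None = None,
    ) -> None:
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "stimuli_on", frozenset(stimuli_on))
        object.__setattr__(self, "inhibitors_on", frozenset(inhibitors_on))
        object.__setattr__(self, "inhibitor_targets", dict(inhibitor_targets or {}))

    def silenced_species(self) -> frozenset[str]:
        """Species whose activity is blocked by an applied drug."""
        return frozenset(
            self.inhibitor_targets[i]
            for i in self.inhibitors_on
            if i in self.inhibitor_targets
        )


@dataclass
class ExtendedNetwork:
    species: list[Species]
    reactions: list[Reaction]
    response_edges: list[NonCanonicalEdge] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def species_by_name(self) -> dict[str, Species]:
        return {s.name: s for s in self.species}

    def names_with_role(self, role: Role) -> list[str]:
        return [s.name for s in self.species if s.role == role]

    @property
    def stimuli(self) -> list[str]:
        return self.names_with_role(Role.STIMULUS)

    @property
    def measured_signals(self) -> list[str]:
        return self.names_with_role(Role.MEASURED_SIGNAL)

    @property
    def responses(self) -> list[str]:
        return self.names_with_role(Role.RESPONSE)

    def producers_of(self, name: str) -> list[Reaction]:
        return [r for r in self.reactions if r.product == name]

    def edges_into(self, response: str) -> list[NonCanonicalEdge]:
        return [e for e in self.response_edges if e.target == response]

    def canonical_graph(self) -> "nx.DiGraph":
        """Directed reactant->product graph of the canonical sub-network
        restricted to non-response species."""
        g = nx.DiGraph()
        responses = set(self.responses)
        for s in self.species:
            if s.role != Role.RESPONSE:
                g.add_node(s.name)
        for r in self.reactions:
            for src in r.reactants:
                if src not in responses and r.product not in responses:
                    g.add_edge(src, r.product)
        return g


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    cycles: list[list[str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_topology(net: ExtendedNetwork) -> ValidationReport:
    """Structural validation; returns a report, never raises.

    Errors: duplicate species names, dangling references, response species
    used as canonical reactants/products, stimulus products, overlapping
    activator/inhibitor sets, duplicate (source, target) response edges.
    Warnings: directed cycles in the canonical sub-network, each enumerated.
    """
    report = ValidationReport()
    names = [s.name for s in net.species]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            report.errors.append(f"duplicate species name: {n}")
        seen.add(n)
    by_name = net.species_by_name()
    responses = set(net.responses)
    stimuli = set(net.stimuli)

    rids: set[str] = set()
    for r in net.reactions:
        if r.id in rids:
            report.errors.append(f"duplicate reaction id: {r.id}")
        rids.add(r.id)
        if not r.reactants:
            report.errors.append(f"reaction {r.id}: empty reactant set")
        if r.activators & r.inhibitors:
            report.errors.append(
                f"reaction {r.id}: activators and inhibitors overlap"
            )
        for ref in sorted(r.reactants | {r.product}):
            if ref not in by_name:
                report.errors.append(
                    f"reaction {r.id}: unknown species '{ref}'"
                )
        if r.product in stimuli:
            report.errors.append(
                f"reaction {r.id}: product {r.product} is a stimulus"
            )
        for ref in sorted((r.reactants | {r.product}) & responses):
            report.errors.append(
                f"reaction {r.id}: response species '{ref}' used canonically"
            )

    pairs: set[tuple[str, str]] = set()
    for e in net.response_edges:
        if (e.source, e.target) in pairs:
            report.errors.append(
                f"edge {e.id}: duplicate pair ({e.source}, {e.target})"
            )
        pairs.add((e.source, e.target))
        src = by_name.get(e.source)
        tgt = by_name.get(e.target)
        if src is None:
            report.errors.append(f"edge {e.id}: unknown source '{e.source}'")
        elif src.role != Role.MEASURED_SIGNAL:
            report.errors.append(
                f"edge {e.id}: source {e.source} is not a measured signal"
            )
        if tgt is None:
            report.errors.append(f"edge {e.id}: unknown target '{e.target}'")
        elif tgt.role != Role.RESPONSE:
            report.errors.append(
                f"edge {e.id}: target {e.target} is not a response species"
            )

    if not report.errors:
        g = net.canonical_graph()
        for cyc in nx.simple_cycles(g):
            report.cycles.append(list(cyc))
            report.warnings.append(
                "cycle in canonical sub-network: " + " -> ".join(cyc)
            )
    return report
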