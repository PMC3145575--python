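"""Deterministic Boolean forward simulation of a fixed topology.

States are the least fixed point reached from the all-off initial state:
a species switches on iff some present, un-silenced producing reaction has
all activators on and all inhibitor-reactants off.  Response species are
not Boolean; their value is the yield-scaled sum of active incoming
non-canonical edges (see :func:`predict_responses`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .network import (
    ExtendedNetwork,
    NonCanonicalEdge,
    Reaction,
    Role,
    TreatmentCondition,
)

__all__ = ["StateAssignment", "simulate", "predict_responses", "yield_bounds_of"]

BLOCK_ACTIVITY = "block-activity"
CLAMP_NODE = "clamp-node"


@dataclass
class StateAssignment:
    states: dict[str, int]
    response_values: dict[str, float] = field(default_factory=dict)
    activations: dict[str, int] = field(default_factory=dict)


def yield_bounds_of(edges: Iterable[NonCanonicalEdge]) -> tuple[float, float]:
    """(b_min, b_max) = (sum of negative, sum of positive) weights; empty
    sums are zero, so b_min <= 0 <= b_max always holds."""
    ws = [e.weight for e in edges]
    return (sum(w for w in ws if w < 0), sum(w for w in ws if w > 0))


def _activity(
    name: str,
    states: Mapping[str, int],
    silenced: frozenset[str],
    mode: str,
) -> int:
    """Effective downstream activity of a species.

    Under ``block-activity`` an applied drug masks the *output* of its
    target: the target may itself be on (phosphorylated) but contributes
    nothing downstream.  Under ``clamp-node`` the state itself is clamped,
    so no extra masking is needed here.
    """
    if mode == BLOCK_ACTIVITY and name in silenced:
        return 0
    return states[name]


def _fires(
    r: Reaction,
    states: Mapping[str, int],
    silenced: frozenset[str],
    mode: str,
) -> bool:
    return all(_activity(a, states, silenced, mode) == 1 for a in r.activators) and all(
        _activity(q, states, silenced, mode) == 0 for q in r.inhibitors
    )


def simulate(
    net: ExtendedNetwork,
    presence: Mapping[str, int],
    condition: TreatmentCondition,
    inhibitor_mode: str = BLOCK_ACTIVITY,
) -> StateAssignment:
    """Least-fixed-point Boolean states plus scaled response values.

    ``presence`` maps reaction/edge ids to {0, 1}; missing ids default to
    present.  Raises ``RuntimeError`` if iteration does not converge within
    2 * |species| sweeps (possible only on cyclic networks).
    """
    silenced = condition.silenced_species()
    states: dict[str, int] = {}
    for s in net.species:
        if s.role == Role.STIMULUS:
            states[s.name] = 1 if s.name in condition.stimuli_on else 0
        elif s.role != Role.RESPONSE:
            states[s.name] = 0

    non_response = [
        s.name for s in net.species if s.role not in (Role.STIMULUS, Role.RESPONSE)
    ]
    producers = {n: net.producers_of(n) for n in non_response}

    # synchronous sweeps so the result is update-order independent
    max_sweeps = 2 * len(net.species) + 2
    for sweep in range(max_sweeps):
        new_states = dict(states)
        for n in non_response:
            if mode_clamped(n, silenced, inhibitor_mode):
                new_states[n] = 0
            else:
                new_states[n] = int(
                    any(
                        presence.get(r.id, 1) == 1
                        and _fires(r, states, silenced, inhibitor_mode)
                        for r in producers[n]
                    )
                )
        if new_states == states:
            break
        states = new_states
    else:
        raise RuntimeError(
            f"state iteration did not converge within {max_sweeps} sweeps "
            "(cyclic network)"
        )

    activations = {
        r.id: int(
            presence.get(r.id, 1) == 1
            and _fires(r, states, silenced, inhibitor_mode)
        )
        for r in net.reactions
    }
    responses = predict_responses(
        states,
        net.response_edges,
        presence=presence,
        silenced=silenced,
        inhibitor_mode=inhibitor_mode,
    )
    return StateAssignment(states=states, response_values=responses, activations=activations)


def mode_clamped(name: str, silenced: frozenset[str], mode: str) -> bool:
    return mode == CLAMP_NODE and name in silenced


def predict_responses(
    states: Mapping[str, int],
    response_edges: Iterable[NonCanonicalEdge],
    presence: Mapping[str, int] | None = None,
    silenced: frozenset[str] = frozenset(),
    inhibitor_mode: str = BLOCK_ACTIVITY,
) -> dict[str, float]:
    """Scaled response predictions.

    For response j with candidate edges E_j and yield bounds (b_min, b_max)
    computed over *all* of E_j (present or not, so the scale is fixed by the
    candidate topology), the raw yield is the weight sum over present edges
    with an active source, and the returned value is
    (raw - b_min) / (b_max - b_min), or 0 when the bounds are degenerate.
    """
    presence = presence or {}
    edges = list(response_edges)
    targets: dict[str, list[NonCanonicalEdge]] = {}
    for e in edges:
        targets.setdefault(e.target, []).append(e)
    out: dict[str, float] = {}
    for tgt, es in targets.items():
        b_min, b_max = yield_bounds_of(es)
        raw = sum(
            e.weight
            for e in es
            if presence.get(e.id, 1) == 1
            and _activity(e.source, states, silenced, inhibitor_mode) == 1
        )
        if b_max - b_min <= 0:
            out[tgt] = 0.0
        else:
            out[tgt] = (raw - b_min) / (b_max - b_min)
    return out
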