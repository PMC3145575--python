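"""Readers/writers: SIF topologies, MIDAS-style measurement CSV, annotated
result networks, YAML config.

SIF dialect
-----------
One interaction per line, tab- or whitespace-separated::

    source <relation> target

with relation ``1`` (activating) or ``-1`` (inhibiting).  AND-gates are
encoded by joining sources with ``+``; a ``!`` prefix inside a gate flips
the role of that one source, so ``a+!b 1 c`` is "a AND NOT b activates c".
Each line is one reaction; several lines with the same target are
alternative (OR) reactions.

MIDAS-style CSV
---------------
``TR:`` columns are 0/1 treatments (stimuli, or inhibitors when listed in
the schema's ``inhibitor_targets``); ``DV:`` columns are measured values.
``DV:`` columns named in ``schema.responses`` are response readouts, all
others are signal readouts.  Blank cells are missing values.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd

from .network import (
    ExtendedNetwork,
    NonCanonicalEdge,
    Reaction,
    Role,
    Species,
    TreatmentCondition,
)

__all__ = [
    "SifParseError",
    "MidasSchema",
    "ExperimentTable",
    "read_sif",
    "write_sif",
    "read_measurements",
    "write_measurements",
    "write_result_network",
    "read_result_network",
]


class SifParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SIF


def _as_text(stream: IO | str) -> IO:
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


def read_sif(stream: IO | str) -> tuple[list[Species], list[Reaction]]:
    """Parse SIF interactions into species and reactions.

    Species roles are inferred structurally: names that never appear as a
    product become stimuli, everything else an intermediate.  Callers that
    know which species are measured re-assign roles afterwards (see
    :func:`assign_roles`).
    """
    reactions: list[Reaction] = []
    mentioned: list[str] = []
    products: set[str] = set()
    n_lines = 0
    for lineno, line in enumerate(_as_text(stream), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n_lines += 1
        parts = line.split()
        if len(parts) != 3 or parts[1] not in ("1", "-1"):
            raise SifParseError(f"line {lineno}: malformed SIF line: {line!r}")
        gate, rel, target = parts
        activators: list[str] = []
        inhibitors: list[str] = []
        for tok in gate.split("+"):
            if not tok or tok == "!":
                raise SifParseError(f"line {lineno}: empty source in gate {gate!r}")
            neg = tok.startswith("!")
            name = tok[1:] if neg else tok
            # line relation sets the default role; '!' flips it
            if (rel == "1") != neg:
                activators.append(name)
            else:
                inhibitors.append(name)
            mentioned.append(name)
        mentioned.append(target)
        products.add(target)
        reactions.append(
            Reaction(
                id=f"r{len(reactions) + 1}",
                activators=activators,
                inhibitors=inhibitors,
                product=target,
            )
        )
    if n_lines == 0:
        raise SifParseError("empty SIF input")
    species = []
    seen: set[str] = set()
    for name in mentioned:
        if name not in seen:
            seen.add(name)
            role = Role.INTERMEDIATE if name in products else Role.STIMULUS
            species.append(Species(name, role))
    return species, reactions


def assign_roles(
    species: Iterable[Species],
    measured_signals: Iterable[str] = (),
    responses: Iterable[str] = (),
) -> list[Species]:
    """Re-role species by name (measured signals / responses)."""
    sig, res = set(measured_signals), set(responses)
    out = []
    for s in species:
        if s.name in res:
            out.append(Species(s.name, Role.RESPONSE))
        elif s.name in sig:
            out.append(Species(s.name, Role.MEASURED_SIGNAL))
        else:
            out.append(s)
    return out


def _gate_str(r: Reaction) -> tuple[str, str]:
    """Return (gate, relation) encoding a reaction in the SIF dialect."""
    if r.activators:
        rel = "1"
        toks = sorted(r.activators) + ["!" + q for q in sorted(r.inhibitors)]
    else:
        rel = "-1"
        toks = sorted(r.inhibitors)
    return "+".join(toks), rel


def write_sif(reactions: Iterable[Reaction], stream: IO) -> None:
    for r in reactions:
        gate, rel = _gate_str(r)
        stream.write(f"{gate}\t{rel}\t{r.product}\n")


# ---------------------------------------------------------------------------
# MIDAS-style measurements


@dataclass
class MidasSchema:
    """Column interpretation for the MIDAS-style CSV dialect.

    ``inhibitor_targets`` maps a TR: column name (without prefix) to the
    species it silences; TR: columns not listed are stimuli.  ``responses``
    names the DV: columns that are response readouts.  ``raw_range``
    declares the admissible value range; values outside it are rejected.
    """

    inhibitor_targets: dict[str, str] = field(default_factory=dict)
    responses: set[str] = field(default_factory=set)
    raw_range: tuple[float, float] = (0.0, 1.0)


@dataclass
class ExperimentTable:
    """Per-condition treatments plus measurement matrices.

    ``signals`` and ``responses`` are condition x readout DataFrames whose
    row order matches ``conditions``; NaN marks a missing measurement.
    """

    conditions: list[TreatmentCondition]
    signals: pd.DataFrame
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [c.id for c in self.conditions]
        for name, df in (("signals", self.signals), ("responses", self.responses)):
            if list(df.index) != ids:
                raise ValueError(f"{name} rows do not match condition order")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def subset(self, condition_ids: list[str]) -> "ExperimentTable":
        keep = set(condition_ids)
        conds = [c for c in self.conditions if c.id in keep]
        ids = [c.id for c in conds]
        return ExperimentTable(
            conditions=conds,
            signals=self.signals.loc[ids],
            responses=self.responses.loc[ids],
        )


def read_measurements(stream: IO | str, schema: MidasSchema) -> ExperimentTable:
    df = pd.read_csv(_as_text(stream))
    tr_cols = [c for c in df.columns if c.startswith("TR:")]
    dv_cols = [c for c in df.columns if c.startswith("DV:")]
    other = [c for c in df.columns if not (c.startswith(("TR:", "DV:", "ID:")))]
    if other:
        raise ValueError(f"unknown column prefix in columns: {other}")
    if not dv_cols:
        raise ValueError("no DV: columns — nothing to fit")

    lo, hi = schema.raw_range
    for c in dv_cols:
        vals = df[c].dropna()
        bad = vals[(vals < lo) | (vals > hi)]
        if len(bad):
            raise ValueError(
                f"column {c}: value {bad.iloc[0]} outside declared range [{lo}, {hi}]"
            )

    sig_cols = [c for c in dv_cols if c[3:] not in schema.responses]
    res_cols = [c for c in dv_cols if c[3:] in schema.responses]

    conditions = []
    for i, row in df.iterrows():
        stim, inh = [], []
        for c in tr_cols:
            name = c[3:]
            on = row[c] == 1 or row[c] == 1.0
            if on:
                (inh if name in schema.inhibitor_targets else stim).append(name)
        cid = str(row["ID:condition"]) if "ID:condition" in df.columns else f"c{i + 1}"
        conditions.append(
            TreatmentCondition(
                id=cid,
                stimuli_on=stim,
                inhibitors_on=inh,
                inhibitor_targets=schema.inhibitor_targets,
            )
        )
    ids = [c.id for c in conditions]
    signals = df[sig_cols].copy()
    signals.columns = [c[3:] for c in sig_cols]
    signals.index = ids
    responses = df[res_cols].copy()
    responses.columns = [c[3:] for c in res_cols]
    responses.index = ids
    return ExperimentTable(conditions=conditions, signals=signals, responses=responses)


def write_measurements(table: ExperimentTable, stream: IO) -> None:
    stim_names = sorted({s for c in table.conditions for s in c.stimuli_on})
    inh_names = sorted({s for c in table.conditions for s in c.inhibitors_on})
    rows = []
    for c in table.conditions:
        row: dict[str, object] = {"ID:condition": c.id}
        for s in stim_names:
            row[f"TR:{s}"] = int(s in c.stimuli_on)
        for s in inh_names:
            row[f"TR:{s}"] = int(s in c.inhibitors_on)
        for col in table.signals.columns:
            row[f"DV:{col}"] = table.signals.loc[c.id, col]
        for col in table.responses.columns:
            row[f"DV:{col}"] = table.responses.loc[c.id, col]
        rows.append(row)
    pd.DataFrame(rows).to_csv(stream, index=False, lineterminator="\n")


def average_time_replicates(df: pd.DataFrame, sep: str = "@") -> pd.DataFrame:
    """Collapse per-time readout columns into their mean.

    Columns named ``readout@time`` (e.g. ``ERK@5``, ``ERK@25``) are averaged
    into a single ``readout`` column — the "average early response"
    convention for pooled lysate time points.  Columns without the
    separator pass through unchanged; NaNs are ignored in the mean.
    """
    groups: dict[str, list[str]] = {}
    for c in df.columns:
        base = c.split(sep, 1)[0] if sep in c else c
        groups.setdefault(base, []).append(c)
    out = {base: df[cols].mean(axis=1) for base, cols in groups.items()}
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# Annotated result networks


def write_result_network(
    net: ExtendedNetwork,
    frequencies: Mapping[str, float],
    sif_stream: IO,
    json_stream: IO,
    objective_values: Iterable[float] = (),
) -> None:
    """Write the topology as SIF plus a JSON sidecar of per-edge pool
    frequencies (and pool objective values)."""
    freq: dict[str, float] = {}
    for item in list(net.reactions) + list(net.response_edges):
        if item.id not in frequencies:
            raise ValueError(f"no frequency for edge {item.id}")
        f = float(frequencies[item.id])
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"frequency for {item.id} outside [0,1]: {f}")
        freq[item.id] = f
    write_sif(net.reactions, sif_stream)
    for e in net.response_edges:
        sif_stream.write(f"{e.source}\t1\t{e.target}\n")
    roles = {s.name: s.role.value for s in net.species}
    json.dump(
        {
            "frequencies": freq,
            "objective_values": [float(v) for v in objective_values],
            "roles": roles,
            "response_edge_weights": {e.id: e.weight for e in net.response_edges},
            "response_edge_ends": {
                e.id: [e.source, e.target] for e in net.response_edges
            },
        },
        json_stream,
        indent=1,
        sort_keys=True,
    )


def read_result_network(
    sif_stream: IO | str, json_stream: IO | str
) -> tuple[ExtendedNetwork, dict[str, float]]:
    meta = json.load(_as_text(json_stream))
    roles = meta["roles"]
    ends = {tuple(v): k for k, v in meta["response_edge_ends"].items()}
    species_raw, reactions_raw = read_sif(sif_stream)
    reactions, edges = [], []
    for r in reactions_raw:
        key = None
        if len(r.activators) == 1 and not r.inhibitors:
            key = (next(iter(r.activators)), r.product)
        if key in ends:
            eid = ends[key]
            edges.append(
                NonCanonicalEdge(
                    id=eid,
                    source=key[0],
                    target=key[1],
                    weight=meta["response_edge_weights"][eid],
                )
            )
        else:
            reactions.append(
                Reaction(
                    id=f"r{len(reactions) + 1}",
                    activators=r.activators,
                    inhibitors=r.inhibitors,
                    product=r.product,
                )
            )
    species = [Species(name, Role(roles[name])) for name in roles]
    net = ExtendedNetwork(species=species, reactions=reactions, response_edges=edges)
    return net, dict(meta["frequencies"])
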