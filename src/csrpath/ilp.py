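"""Compile an extended network plus a measurement table into an ILP.

Decision variables (all binary except the deviation variables):

* presence ``y_i`` per canonical reaction and per non-canonical edge —
  whether the edge exists in the optimised topology;
* activation ``z_i^k`` per reaction/edge and condition — whether it fires;
* state ``x_j^k`` per non-stimulus, non-response species and condition;
* deviation ``e_j^k`` in [0, 1] per measured response entry.

Constraints encode deterministic Boolean propagation (a reaction fires iff
present, all activators on, all inhibitor-reactants off, and not silenced
by an applied drug; a species is the OR of its producing reactions) and the
yield scaling of response predictions.  The objective is

    alpha_signal * L1 signal mismatch
  + alpha_response * L1 scaled-response mismatch
  + beta_size * (number of retained edges)

with binary-state signal mismatch |x - m| encoded exactly by the affine
form m + (1 - 2m) * x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io import ExperimentTable
from .network import ExtendedNetwork, NonCanonicalEdge, Role, validate_topology
from .simulate import BLOCK_ACTIVITY, CLAMP_NODE, yield_bounds_of

__all__ = ["ObjectiveWeights", "YieldBounds", "ILPProblem", "yield_bounds", "build_ilp"]


@dataclass
class ObjectiveWeights:
    """Weights of the three objective terms.

    The two mismatch terms default to equal weight 1.  The map-size weight
    defaults to 1/20: pruning an essential chain of up to 20 reactions can
    never pay for the >= 1 unit of mismatch it would introduce.
    """

    alpha_signal: float = 1.0
    alpha_response: float = 1.0
    beta_size: float = 1.0 / 20.0

    def __post_init__(self) -> None:
        if min(self.alpha_signal, self.alpha_response, self.beta_size) < 0:
            raise ValueError("objective weights must be >= 0")


@dataclass(frozen=True)
class YieldBounds:
    b_min: float
    b_max: float

    @property
    def width(self) -> float:
        return self.b_max - self.b_min


def yield_bounds(edges: Iterable[NonCanonicalEdge]) -> YieldBounds:
    """Minimal/maximal total yield of one response species: the sums of
    negative and positive incoming weights (empty sums are 0)."""
    edges = list(edges)
    if len({e.target for e in edges}) > 1:
        raise ValueError("edges must all target the same response")
    return YieldBounds(*yield_bounds_of(edges))


@dataclass
class ILPProblem:
    """A compiled problem: sparse constraints plus variable index maps."""

    c: np.ndarray
    offset: float
    a: sp.csr_matrix
    con_lb: np.ndarray
    con_ub: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray
    y_index: dict[str, int]
    z_index: dict[tuple[str, str], int]
    x_index: dict[tuple[str, str], int]
    e_index: dict[tuple[str, str], int]
    net: ExtendedNetwork
    data: ExperimentTable
    weights: ObjectiveWeights
    inhibitor_mode: str
    dropped_responses: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return self.c.size

    def presence_ids(self) -> list[str]:
        return sorted(self.y_index, key=self.y_index.__getitem__)


def to_lp_string(problem: "ILPProblem") -> str:
    """Render the compiled problem in CPLEX LP format (solver-independent
    debugging aid).  Variables are named y_<edge>, z_<edge>_<cond>,
    x_<species>_<cond>, e_<response>_<cond>."""

    def clean(s: str) -> str:
        return "".join(ch if ch.isalnum() or ch in "_" else "_" for ch in s)

    names = [""] * problem.n_vars
    for eid, col in problem.y_index.items():
        names[col] = f"y_{clean(eid)}"
    for (eid, cid), col in problem.z_index.items():
        names[col] = f"z_{clean(eid)}_{clean(cid)}"
    for (spc, cid), col in problem.x_index.items():
        names[col] = f"x_{clean(spc)}_{clean(cid)}"
    for (rsp, cid), col in problem.e_index.items():
        names[col] = f"e_{clean(rsp)}_{clean(cid)}"
    for col, nm in enumerate(names):
        if not nm:
            names[col] = f"v{col}"

    def expr(cols, vals) -> str:
        terms = [
            f"{'+' if v >= 0 else '-'} {abs(v):.12g} {names[c]}"
            for c, v in zip(cols, vals)
            if v
        ]
        return " ".join(terms) if terms else "0 " + names[0]

    lines = ["Minimize", " obj: " + expr(range(problem.n_vars), problem.c)]
    lines.append("Subject To")
    a = problem.a.tocsr()
    for i in range(a.shape[0]):
        row = a.getrow(i)
        e = expr(row.indices, row.data)
        lo, hi = problem.con_lb[i], problem.con_ub[i]
        if lo == hi:
            lines.append(f" c{i}: {e} = {lo:.12g}")
        else:
            if hi < math.inf:
                lines.append(f" c{i}u: {e} <= {hi:.12g}")
            if lo > -math.inf:
                lines.append(f" c{i}l: {e} >= {lo:.12g}")
    lines.append("Bounds")
    for col in range(problem.n_vars):
        lines.append(
            f" {problem.var_lb[col]:.12g} <= {names[col]} <= {problem.var_ub[col]:.12g}"
        )
    binaries = [names[c] for c in range(problem.n_vars) if problem.integrality[c]]
    if binaries:
        lines.append("Binary")
        lines.append(" " + " ".join(binaries))
    lines.append("End")
    return "\n".join(lines) + "\n"


class _Builder:
    def __init__(self) -> None:
        self.rows: list[dict[int, float]] = []
        self.lb: list[float] = []
        self.ub: list[float] = []

    def add(self, coeffs: dict[int, float], lb: float, ub: float) -> None:
        self.rows.append(coeffs)
        self.lb.append(lb)
        self.ub.append(ub)

    def matrix(self, n_vars: int) -> sp.csr_matrix:
        data, ri, ci = [], [], []
        for i, row in enumerate(self.rows):
            for j, v in row.items():
                ri.append(i)
                ci.append(j)
                data.append(v)
        return sp.coo_matrix(
            (data, (ri, ci)), shape=(len(self.rows), n_vars)
        ).tocsr()


def _check_cycles(net: ExtendedNetwork, allow_cycles: bool) -> list[list[str]]:
    report = validate_topology(net)
    if report.errors:
        raise ValueError("invalid topology: " + "; ".join(report.errors))
    if report.cycles:
        if not allow_cycles:
            raise ValueError(
                "canonical sub-network is cyclic "
                f"({len(report.cycles)} cycle(s)); pass allow_cycles=True "
                "for least-fixed-point semantics"
            )
        g = net.canonical_graph()
        for r in net.reactions:
            for q in r.inhibitors:
                if g.has_node(r.product) and nx.has_path(g, r.product, q):
                    raise ValueError(
                        f"inhibitory input {q} of reaction {r.id} lies on a "
                        "cycle; least-fixed-point semantics undefined"
                    )
    return report.cycles


def build_ilp(
    net: ExtendedNetwork,
    data: ExperimentTable,
    weights: ObjectiveWeights = ObjectiveWeights(),
    inhibitor_mode: str = BLOCK_ACTIVITY,
    allow_cycles: bool = False,
) -> ILPProblem:
    """Compile the network + data into the three-term ILP.

    Stimulus states are substituted as constants per condition, so states
    are uniquely determined by the presence vector on acyclic networks and
    ILP optima are directly comparable to forward simulation.  On cyclic
    networks (``allow_cycles=True``) an acyclic-justification encoding
    restricts feasible states to the least fixed point.
    """
    cycles = _check_cycles(net, allow_cycles)
    cyclic = bool(cycles)

    stimuli = set(net.stimuli)
    responses = set(net.responses)
    non_response = [
        s.name for s in net.species if s.role not in (Role.STIMULUS, Role.RESPONSE)
    ]
    producers = {n: net.producers_of(n) for n in non_response}
    conds = data.conditions

    # ---- variable layout
    y_index: dict[str, int] = {}
    for r in net.reactions:
        y_index[r.id] = len(y_index)
    for e in net.response_edges:
        y_index[e.id] = len(y_index)
    n = len(y_index)

    z_index: dict[tuple[str, str], int] = {}
    x_index: dict[tuple[str, str], int] = {}
    for c in conds:
        for r in net.reactions:
            z_index[(r.id, c.id)] = n
            n += 1
        for e in net.response_edges:
            z_index[(e.id, c.id)] = n
            n += 1
        for s in non_response:
            x_index[(s, c.id)] = n
            n += 1

    e_index: dict[tuple[str, str], int] = {}
    measured_resp: list[tuple[str, str, float]] = []
    dropped: list[str] = []
    warn: list[str] = []
    bounds_by_resp: dict[str, YieldBounds] = {}
    for resp in data.responses.columns:
        if resp not in responses:
            raise ValueError(f"measured response {resp!r} is not a response species")
        bounds_by_resp[resp] = yield_bounds(net.edges_into(resp))
    for resp in data.responses.columns:
        yb = bounds_by_resp[resp]
        has_edges = bool(net.edges_into(resp))
        if has_edges and yb.width <= 0:
            dropped.append(resp)
            warn.append(
                f"response {resp}: degenerate yield bounds; dropped from objective"
            )
            continue
        for c in conds:
            v = data.responses.loc[c.id, resp]
            if not np.isnan(v):
                measured_resp.append((resp, c.id, float(v)))
                if has_edges:
                    e_index[(resp, c.id)] = n
                    n += 1

    # cyclic mode: justification vars u per (canonical reaction, condition)
    # and rank vars per (species, condition)
    u_index: dict[tuple[str, str], int] = {}
    rank_index: dict[tuple[str, str], int] = {}
    if cyclic:
        for c in conds:
            for r in net.reactions:
                u_index[(r.id, c.id)] = n
                n += 1
            for s in non_response:
                rank_index[(s, c.id)] = n
                n += 1

    c_obj = np.zeros(n)
    var_lb = np.zeros(n)
    var_ub = np.ones(n)
    integrality = np.ones(n, dtype=int)
    for (resp, cid), col in e_index.items():
        integrality[col] = 0
    big = len(net.species) + 1.0
    for col in rank_index.values():
        integrality[col] = 0
        var_ub[col] = big - 1

    b = _Builder()

    def eff(name: str, cond) -> tuple[bool, float | int]:
        """(is_const, value-or-column) of a species' downstream activity."""
        silenced = cond.silenced_species()
        if name in silenced and inhibitor_mode == BLOCK_ACTIVITY:
            return True, 0
        if name in stimuli:
            return True, int(name in cond.stimuli_on)
        if name in silenced and inhibitor_mode == CLAMP_NODE:
            return True, 0
        return False, x_index[(name, cond.id)]

    for cond in conds:
        silenced = cond.silenced_species()
        # species-state constraints
        for s in non_response:
            xc = x_index[(s, cond.id)]
            if inhibitor_mode == CLAMP_NODE and s in silenced:
                var_ub[xc] = 0
                continue
            prods = producers[s]
            if not prods:
                var_ub[xc] = 0
                continue
            link = u_index if cyclic else z_index
            row = {xc: 1.0}
            for r in prods:
                b.add(
                    {xc: 1.0, z_index[(r.id, cond.id)]: -1.0}, 0.0, math.inf
                )  # firing producer turns the product on
                lc = link[(r.id, cond.id)]
                row[lc] = row.get(lc, 0.0) - 1.0
            # product on only with a (justified, in cyclic mode) producer
            b.add(row, -math.inf, 0.0)

        # reaction activation constraints
        for r in net.reactions:
            zc = z_index[(r.id, cond.id)]
            yc = y_index[r.id]
            blocked = False
            n_inputs = len(r.activators) + len(r.inhibitors)
            sat_const = 0
            var_act: list[int] = []
            var_inh: list[int] = []
            for a in sorted(r.activators):
                const, val = eff(a, cond)
                if const:
                    if val == 0:
                        blocked = True
                    else:
                        sat_const += 1
                else:
                    var_act.append(int(val))
            for q in sorted(r.inhibitors):
                const, val = eff(q, cond)
                if const:
                    if val == 1:
                        blocked = True
                    else:
                        sat_const += 1
                else:
                    var_inh.append(int(val))
            if blocked:
                var_ub[zc] = 0
                continue
            b.add({zc: 1.0, yc: -1.0}, -math.inf, 0.0)
            for xa in var_act:
                b.add({zc: 1.0, xa: -1.0}, -math.inf, 0.0)
            for xq in var_inh:
                b.add({zc: 1.0, xq: 1.0}, -math.inf, 1.0)
            row = {zc: 1.0, yc: -1.0}
            for xa in var_act:
                row[xa] = row.get(xa, 0.0) - 1.0
            for xq in var_inh:
                row[xq] = row.get(xq, 0.0) + 1.0
            rhs = sat_const + len(var_inh) - n_inputs
            b.add(row, rhs, math.inf)

        # non-canonical edge activations
        for e in net.response_edges:
            zc = z_index[(e.id, cond.id)]
            yc = y_index[e.id]
            const, val = eff(e.source, cond)
            if const:
                if val == 0:
                    var_ub[zc] = 0
                    continue
                b.add({zc: 1.0, yc: -1.0}, 0.0, 0.0)  # z == y
            else:
                xs = int(val)
                b.add({zc: 1.0, yc: -1.0}, -math.inf, 0.0)
                b.add({zc: 1.0, xs: -1.0}, -math.inf, 0.0)
                b.add({zc: 1.0, yc: -1.0, xs: -1.0}, -1.0, math.inf)

        # cyclic mode: grounded-justification encoding
        if cyclic:
            for r in net.reactions:
                uc = u_index[(r.id, cond.id)]
                zc = z_index[(r.id, cond.id)]
                b.add({uc: 1.0, zc: -1.0}, -math.inf, 0.0)  # u <= z
                if r.product in responses or r.product in stimuli:
                    continue
                rp = rank_index[(r.product, cond.id)]
                for a in sorted(r.activators):
                    const, val = eff(a, cond)
                    if const:
                        continue
                    ra = rank_index.get((a, cond.id))
                    if ra is None:
                        continue
                    # rank(product) >= rank(activator) + 1 when u = 1
                    b.add({rp: 1.0, ra: -1.0, uc: -big}, 1.0 - big, math.inf)

    # ---- objective
    alpha_s, alpha_r, beta = (
        weights.alpha_signal,
        weights.alpha_response,
        weights.beta_size,
    )
    offset = 0.0
    for col in y_index.values():
        c_obj[col] += beta

    sig_names = set(net.measured_signals)
    for sig in data.signals.columns:
        if sig not in sig_names:
            raise ValueError(f"measured signal {sig!r} is not a measured_signal species")
        for cond in conds:
            v = data.signals.loc[cond.id, sig]
            if np.isnan(v):
                continue
            xc = x_index[(sig, cond.id)]
            c_obj[xc] += alpha_s * (1.0 - 2.0 * float(v))
            offset += alpha_s * float(v)

    for resp, cid, v in measured_resp:
        edges = net.edges_into(resp)
        if not edges:
            offset += alpha_r * v  # prediction is identically 0
            continue
        yb = bounds_by_resp[resp]
        d = yb.width
        ec = e_index[(resp, cid)]
        c_obj[ec] += alpha_r
        row_lo = {ec: 1.0}
        row_hi = {ec: 1.0}
        for e in edges:
            zc = z_index[(e.id, cid)]
            row_lo[zc] = row_lo.get(zc, 0.0) - e.weight / d
            row_hi[zc] = row_hi.get(zc, 0.0) + e.weight / d
        b.add(row_lo, -yb.b_min / d - v, math.inf)  # e >= s - v
        b.add(row_hi, v + yb.b_min / d, math.inf)  # e >= v - s

    return ILPProblem(
        c=c_obj,
        offset=offset,
        a=b.matrix(n),
        con_lb=np.array(b.lb),
        con_ub=np.array(b.ub),
        var_lb=var_lb,
        var_ub=var_ub,
        integrality=integrality,
        y_index=y_index,
        z_index=z_index,
        x_index=x_index,
        e_index=e_index,
        net=net,
        data=data,
        weights=weights,
        inhibitor_mode=inhibitor_mode,
        dropped_responses=dropped,
        warnings=warn,
    )
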