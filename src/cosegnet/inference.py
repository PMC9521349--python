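"""Parameter fitting and probabilistic inference on a learned gene network.

Conditional probability tables (CPTs) are Dirichlet-smoothed frequency
estimates on a DAG.  Queries run either by exact variable elimination
(preferred for the small networks arising from panel data) or by damped
sum-product loopy belief propagation on the factor graph, which is exact
on trees and approximate on loopy graphs.

The headline query is the *relative risk of co-segregation*: how much more
(or less) likely an anchor gene's mutation is when a set of condition
genes is mutated versus unmutated, or the reverse conditioning direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import MutationMatrix
from .structure import Dag

logger = logging.getLogger(__name__)

__all__ = [
    "CptSet",
    "FactorGraph",
    "BPResult",
    "RiskEstimate",
    "fit_cpts",
    "loopy_bp",
    "variable_elimination",
    "event_probability",
    "relative_risk",
    "empirical_relative_risk",
    "write_rr_tsv",
]

#: Above this node count, RR queries fall back from exact elimination to BP.
EXACT_NODE_LIMIT = 20


class InferenceError(ValueError):
    """Raised for invalid or degenerate inference requests."""


@dataclass(frozen=True)
class CptSet:
    """P(node = 1 | parent configuration) for every node of a DAG.

    ``tables[node]`` has 2^k entries for k parents (ordered as in
    ``parents[node]``; configuration j has bit i set iff parent i = 1).
    After smoothing every probability lies strictly in (0, 1); unseen
    configurations sit at the symmetric prior 0.5.
    """

    parents: Mapping[str, tuple[str, ...]]
    tables: Mapping[str, np.ndarray]
    pseudo_count: float

    def nodes(self) -> tuple[str, ...]:
        return tuple(self.tables)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for node, table in self.tables.items():
            pa = self.parents[node]
            for j, p in enumerate(np.asarray(table)):
                config = ";".join(
                    f"{parent}={j >> i & 1}" for i, parent in enumerate(pa)
                )
                rows.append((node, config, float(p)))
        pd.DataFrame(rows, columns=["node", "parent_config", "p_mut"]).to_csv(
            path, sep="\t", index=False
        )


def fit_cpts(
    matrix: MutationMatrix, dag: Dag, pseudo_count: float = 0.1
) -> CptSet:
    """Dirichlet-smoothed CPT estimates on a DAG.

    P(node=1 | config) = (count(node=1, config) + pseudo_count) /
    (count(config) + 2·pseudo_count).  Unseen configurations therefore get
    0.5.  The default pseudo-count is light (0.1): it keeps every factor
    strictly positive for belief propagation while keeping the relative
    bias on rare-configuration conditionals (counts of a few events in a
    cohort of thousands) to a few percent; pass a larger value for
    stronger regularisation or 0 for plain maximum likelihood.
    """
    if pseudo_count < 0:
        raise InferenceError("pseudo_count must be non-negative")
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    for node in dag.nodes:
        pa = tuple(sorted(dag.parent_sets[node]))
        child = matrix.column(node)
        config = np.zeros(matrix.n_patients, dtype=np.int64)
        for i, p in enumerate(pa):
            config |= matrix.column(p).astype(np.int64) << i
        q = 2 ** len(pa)
        joint = np.bincount(2 * config + child, minlength=2 * q).reshape(-1, 2)
        nj = joint.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = (joint[:, 1] + pseudo_count) / (nj + 2.0 * pseudo_count)
        p1 = np.where(nj + 2.0 * pseudo_count > 0, p1, 0.5)
        parents[node] = pa
        tables[node] = p1
    return CptSet(parents=parents, tables=tables, pseudo_count=pseudo_count)


# ---------------------------------------------------------------------------
# Factors


def _family_factor(node: str, pa: tuple[str, ...], p1: np.ndarray):
    """(variables, tensor) for one CPT family; axis 0 is the child."""
    variables = (node, *pa)
    shape = (2,) * len(variables)
    tensor = np.empty(shape)
    for j in range(2 ** len(pa)):
        idx = tuple(j >> i & 1 for i in range(len(pa)))
        tensor[(1, *idx)] = p1[j]
        tensor[(0, *idx)] = 1.0 - p1[j]
    return variables, tensor


def _multiply(f1, f2):
    """Pointwise product of two factors, aligning shared variables."""
    vars1, t1 = f1
    vars2, t2 = f2
    out_vars = tuple(vars1) + tuple(v for v in vars2 if v not in vars1)
    t1b = t1.reshape(t1.shape + (1,) * (len(out_vars) - len(vars1)))
    shape2 = tuple(2 if v in vars2 else 1 for v in out_vars)
    # align t2 onto out_vars by transposing its axes into order of appearance
    order = sorted(range(len(vars2)), key=lambda i: out_vars.index(vars2[i]))
    t2t = np.transpose(t2, order)
    t2b = t2t.reshape(shape2)
    return out_vars, t1b * t2b


def _sum_out(factor, variable: str):
    variables, tensor = factor
    axis = variables.index(variable)
    return (
        tuple(v for v in variables if v != variable),
        tensor.sum(axis=axis),
    )


def _reduce(factor, evidence: Mapping[str, int]):
    variables, tensor = factor
    keep = []
    index: list = []
    for v in variables:
        if v in evidence:
            index.append(int(evidence[v]))
        else:
            index.append(slice(None))
            keep.append(v)
    return tuple(keep), tensor[tuple(index)]


# ---------------------------------------------------------------------------
# Variable elimination (exact)


def _eliminate_all(
    factors: list, keep: Sequence[str]
):
    """Sum out every variable not in ``keep``, min-degree order."""
    factors = list(factors)
    keep = set(keep)
    variables = {v for f in factors for v in f[0]} - keep
    while variables:
        # min-degree: variable whose elimination touches the fewest others
        def degree(v: str) -> int:
            scope: set[str] = set()
            for f in factors:
                if v in f[0]:
                    scope |= set(f[0])
            return len(scope)

        target = min(sorted(variables), key=degree)
        involved = [f for f in factors if target in f[0]]
        rest = [f for f in factors if target not in f[0]]
        product = involved[0]
        for f in involved[1:]:
            product = _multiply(product, f)
        factors = rest + [_sum_out(product, target)]
        variables.discard(target)
    product = factors[0]
    for f in factors[1:]:
        product = _multiply(product, f)
    return product


def _dag_factors(dag: Dag, cpts: CptSet, evidence: Mapping[str, int]):
    factors = []
    for node in dag.nodes:
        f = _family_factor(node, cpts.parents[node], np.asarray(cpts.tables[node]))
        factors.append(_reduce(f, evidence))
    return factors


def event_probability(
    dag: Dag, cpts: CptSet, assignment: Mapping[str, int]
) -> float:
    """P(assignment) under the fitted network, by exact elimination."""
    factors = _dag_factors(dag, cpts, assignment)
    _, tensor = _eliminate_all(factors, keep=())
    return float(tensor)


def variable_elimination(
    dag: Dag,
    cpts: CptSet,
    evidence: Mapping[str, int] | None = None,
    query: str = "",
) -> float:
    """Exact P(query = 1 | evidence) by sum-product elimination."""
    evidence = dict(evidence or {})
    if query in evidence:
        raise InferenceError("query gene must not appear in the evidence")
    if query not in dag.nodes:
        raise InferenceError(f"query gene {query!r} not in network")
    factors = _dag_factors(dag, cpts, evidence)
    variables, tensor = _eliminate_all(factors, keep=(query,))
    assert variables == (query,) and tensor.ndim == 1
    norm = float(tensor.sum())
    if norm <= 0.0:
        raise InferenceError("evidence event has probability zero")
    return float(tensor[1] / norm)


# ---------------------------------------------------------------------------
# Loopy belief propagation


@dataclass
class FactorGraph:
    """Bipartite variable/factor graph for sum-product message passing."""

    variables: tuple[str, ...]
    factors: list  # list of (name, variables, tensor)

    @classmethod
    def from_network(cls, dag: Dag, cpts: CptSet) -> "FactorGraph":
        factors = []
        for node in dag.nodes:
            variables, tensor = _family_factor(
                node, cpts.parents[node], np.asarray(cpts.tables[node])
            )
            factors.append((f"cpt:{node}", variables, tensor))
        return cls(variables=tuple(dag.nodes), factors=factors)


@dataclass(frozen=True)
class BPResult:
    marginals: Mapping[str, np.ndarray]
    converged: bool
    iterations: int


def loopy_bp(
    graph: FactorGraph,
    evidence: Mapping[str, int] | None = None,
    max_iters: int = 200,
    tol: float = 1e-8,
    damping: float = 0.5,
) -> BPResult:
    """Synchronous (flooding) damped sum-product on the factor graph.

    Evidence enters as unary indicator factors.  Stops when the largest
    absolute message change drops below ``tol`` or after ``max_iters``
    sweeps; returns normalised per-variable beliefs and a convergence
    flag.  Exact on trees; approximate on loopy graphs.
    """
    evidence = dict(evidence or {})
    unknown = set(evidence) - set(graph.variables)
    if unknown:
        raise InferenceError(f"evidence genes not in graph: {sorted(unknown)}")
    factors = list(graph.factors)
    for v, value in sorted(evidence.items()):
        indicator = np.zeros(2)
        indicator[int(value)] = 1.0
        factors.append((f"evidence:{v}", (v,), indicator))

    # message containers keyed by (factor index, variable)
    edges = [
        (fi, v) for fi, (_, variables, _) in enumerate(factors) for v in variables
    ]
    msg_fv = {edge: np.full(2, 0.5) for edge in edges}
    msg_vf = {edge: np.full(2, 0.5) for edge in edges}
    var_edges: dict[str, list[int]] = {v: [] for v in graph.variables}
    for fi, (_, variables, _) in enumerate(factors):
        for v in variables:
            var_edges[v].append(fi)

    converged = False
    iteration = 0
    for iteration in range(1, max_iters + 1):
        delta = 0.0
        # variable -> factor messages (from previous factor -> var messages)
        new_vf = {}
        for fi, v in edges:
            product = np.ones(2)
            for fj in var_edges[v]:
                if fj != fi:
                    product = product * msg_fv[(fj, v)]
            total = product.sum()
            if total <= 0.0:
                name = factors[fi][0]
                raise InferenceError(
                    f"evidence contradicts a zero-probability configuration near {name}"
                )
            new_vf[(fi, v)] = product / total
        # factor -> variable messages
        new_fv = {}
        for fi, (name, variables, tensor) in enumerate(factors):
            for v in variables:
                work = tensor
                for axis, u in enumerate(variables):
                    if u == v:
                        continue
                    shape = [1] * tensor.ndim
                    shape[axis] = 2
                    work = work * new_vf[(fi, u)].reshape(shape)
                axes = tuple(i for i, u in enumerate(variables) if u != v)
                message = work.sum(axis=axes) if axes else work
                total = message.sum()
                if total <= 0.0:
                    raise InferenceError(
                        f"evidence contradicts a zero-probability configuration in {name}"
                    )
                message = message / total
                if name.startswith("evidence:"):
                    # indicator messages are constant; damping them would
                    # only blur the exact zeros that flag contradictions
                    new_fv[(fi, v)] = message
                else:
                    new_fv[(fi, v)] = (
                        damping * msg_fv[(fi, v)] + (1 - damping) * message
                    )
        for edge in edges:
            delta = max(delta, float(np.max(np.abs(new_fv[edge] - msg_fv[edge]))))
            delta = max(delta, float(np.max(np.abs(new_vf[edge] - msg_vf[edge]))))
        msg_fv, msg_vf = new_fv, new_vf
        if delta < tol:
            converged = True
            break

    # a factor whose entire scope is excluded by the evidence marks a
    # zero-probability configuration (marginal beliefs alone cannot see it)
    for fi, (name, variables, tensor) in enumerate(factors):
        mass = tensor
        for axis, u in enumerate(variables):
            shape = [1] * tensor.ndim
            shape[axis] = 2
            mass = mass * msg_vf[(fi, u)].reshape(shape)
        if float(np.sum(mass)) == 0.0:
            raise InferenceError(
                f"evidence contradicts a zero-probability configuration in {name}"
            )

    marginals: dict[str, np.ndarray] = {}
    for v in graph.variables:
        belief = np.ones(2)
        for fi in var_edges[v]:
            belief = belief * msg_fv[(fi, v)]
        total = belief.sum()
        if total <= 0.0:
            raise InferenceError(f"belief of {v} vanished under the evidence")
        marginals[v] = belief / total
    return BPResult(marginals=marginals, converged=converged, iterations=iteration)


# ---------------------------------------------------------------------------
# Relative-risk queries


@dataclass(frozen=True)
class RiskEstimate:
    """Relative risk of co-segregation for an (anchor, condition-set) query.

    ``direction`` is ``anchor_given_genes`` —
    P(anchor=1 | condition all mutated) / P(anchor=1 | condition all
    unmutated) — or ``genes_given_anchor`` for the reverse conditioning.
    """

    anchor: str
    condition: frozenset[str]
    rr: float
    direction: str
    numerator: float
    denominator: float
    method: str = "exact"
    converged: bool = True
    degenerate: bool = False


def _check_query(anchor: str, condition: Iterable[str]) -> tuple[str, ...]:
    condition = tuple(sorted(set(condition)))
    if anchor in condition:
        raise InferenceError("anchor must not appear in the condition set")
    if not condition:
        raise InferenceError("condition set must be non-empty")
    return condition


def _subnetwork(dag: Dag, cpts: CptSet, genes: Iterable[str]) -> tuple[Dag, CptSet]:
    """Restrict to the ancestral closure of ``genes`` (barren-node removal)."""
    closure: set[str] = set()
    stack = list(genes)
    while stack:
        g = stack.pop()
        if g in closure:
            continue
        closure.add(g)
        stack.extend(dag.parent_sets[g])
    nodes = tuple(n for n in dag.nodes if n in closure)
    sub = Dag(nodes=nodes, parent_sets={n: dag.parent_sets[n] for n in nodes})
    sub_cpts = CptSet(
        parents={n: cpts.parents[n] for n in nodes},
        tables={n: cpts.tables[n] for n in nodes},
        pseudo_count=cpts.pseudo_count,
    )
    return sub, sub_cpts


def _bp_conditional(
    dag: Dag, cpts: CptSet, targets: Sequence[str], evidence: Mapping[str, int]
) -> tuple[float, bool]:
    """P(all targets = 1 | evidence) via BP and the chain rule."""
    graph = FactorGraph.from_network(dag, cpts)
    prob = 1.0
    converged = True
    running = dict(evidence)
    for t in targets:
        result = loopy_bp(graph, evidence=running)
        converged &= result.converged
        prob *= float(result.marginals[t][1])
        running[t] = 1
    return prob, converged


def relative_risk(
    dag: Dag,
    cpts: CptSet,
    anchor: str,
    condition: Iterable[str],
    direction: str = "anchor_given_genes",
) -> RiskEstimate:
    """Model-based relative risk of co-segregation.

    Probabilities come from exact variable elimination when the relevant
    subnetwork has at most ``EXACT_NODE_LIMIT`` nodes, otherwise from
    loopy belief propagation (with a logged approximation notice).  A zero
    denominator yields rr = inf with the ``degenerate`` flag set.
    """
    condition = _check_query(anchor, condition)
    if direction not in {"anchor_given_genes", "genes_given_anchor"}:
        raise InferenceError(f"unknown direction {direction!r}")
    sub, sub_cpts = _subnetwork(dag, cpts, (anchor, *condition))
    use_exact = len(sub.nodes) <= EXACT_NODE_LIMIT
    if not use_exact:
        logger.info(
            "RR query subnetwork has %d nodes; using loopy BP approximation",
            len(sub.nodes),
        )

    if use_exact:
        p_joint = {
            (a, c): event_probability(
                sub, sub_cpts, {anchor: a, **{g: c for g in condition}}
            )
            for a in (0, 1)
            for c in (0, 1)
        }
        if direction == "anchor_given_genes":
            den1 = p_joint[(0, 1)] + p_joint[(1, 1)]
            den0 = p_joint[(0, 0)] + p_joint[(1, 0)]
            num = p_joint[(1, 1)] / den1 if den1 > 0 else math.nan
            den = p_joint[(1, 0)] / den0 if den0 > 0 else math.nan
        else:
            # denominators are the anchor marginals, not the corner events:
            # with several condition genes the four corners do not partition.
            p_anchor1 = event_probability(sub, sub_cpts, {anchor: 1})
            p_anchor0 = event_probability(sub, sub_cpts, {anchor: 0})
            num = p_joint[(1, 1)] / p_anchor1 if p_anchor1 > 0 else math.nan
            den = p_joint[(0, 1)] / p_anchor0 if p_anchor0 > 0 else math.nan
        converged = True
        method = "exact"
    else:
        if direction == "anchor_given_genes":
            num, c1 = _bp_conditional(
                sub, sub_cpts, (anchor,), {g: 1 for g in condition}
            )
            den, c2 = _bp_conditional(
                sub, sub_cpts, (anchor,), {g: 0 for g in condition}
            )
        else:
            num, c1 = _bp_conditional(sub, sub_cpts, condition, {anchor: 1})
            den, c2 = _bp_conditional(sub, sub_cpts, condition, {anchor: 0})
        converged = c1 and c2
        method = "bp"

    if den is None or (isinstance(den, float) and (math.isnan(den) or den <= 0.0)):
        return RiskEstimate(
            anchor=anchor,
            condition=frozenset(condition),
            rr=math.inf,
            direction=direction,
            numerator=float(num),
            denominator=float(den) if den == den else 0.0,
            method=method,
            converged=converged,
            degenerate=True,
        )
    return RiskEstimate(
        anchor=anchor,
        condition=frozenset(condition),
        rr=float(num / den),
        direction=direction,
        numerator=float(num),
        denominator=float(den),
        method=method,
        converged=converged,
    )


def empirical_relative_risk(
    matrix: MutationMatrix,
    anchor: str,
    condition: Iterable[str],
    direction: str = "anchor_given_genes",
) -> RiskEstimate:
    """Count-based relative risk from the raw cohort.

    Strata are patients with all condition genes mutated versus all
    unmutated (for ``anchor_given_genes``), or anchor-positive versus
    anchor-negative (for ``genes_given_anchor``).  When any stratum count
    or event count is zero, a 0.5 continuity correction
    (k + 0.5) / (n + 1) is applied to both strata and the ``degenerate``
    flag is set.
    """
    condition = _check_query(anchor, condition)
    a_col = matrix.column(anchor)
    cond_all_1 = np.ones(matrix.n_patients, dtype=bool)
    cond_all_0 = np.ones(matrix.n_patients, dtype=bool)
    for g in condition:
        col = matrix.column(g)
        cond_all_1 &= col
        cond_all_0 &= ~col
    if direction == "anchor_given_genes":
        strata = (cond_all_1, cond_all_0)
        event = a_col
    elif direction == "genes_given_anchor":
        strata = (a_col, ~a_col)
        event = cond_all_1
    else:
        raise InferenceError(f"unknown direction {direction!r}")
    n1, n0 = int(strata[0].sum()), int(strata[1].sum())
    k1, k0 = int(event[strata[0]].sum()), int(event[strata[1]].sum())
    corrected = min(n1, n0, k1, k0) == 0
    if corrected:
        num = (k1 + 0.5) / (n1 + 1.0)
        den = (k0 + 0.5) / (n0 + 1.0)
    else:
        num = k1 / n1
        den = k0 / n0
    return RiskEstimate(
        anchor=anchor,
        condition=frozenset(condition),
        rr=float(num / den),
        direction=direction,
        numerator=float(num),
        denominator=float(den),
        method="empirical",
        degenerate=corrected,
    )


def write_rr_tsv(estimates: Iterable[RiskEstimate], path: str | Path) -> None:
    estimates = list(estimates)
    frame = pd.DataFrame(
        {
            "anchor": [e.anchor for e in estimates],
            "condition": [";".join(sorted(e.condition)) for e in estimates],
            "direction": [e.direction for e in estimates],
            "numerator": [e.numerator for e in estimates],
            "denominator": [e.denominator for e in estimates],
            "rr": [e.rr for e in estimates],
            "method": [e.method for e in estimates],
            "converged": [int(e.converged) for e in estimates],
            "degenerate": [int(e.degenerate) for e in estimates],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
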