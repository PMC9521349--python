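"""Bayesian-network structure learning over binary mutation indicators.

Two-stage discovery, as used for gene-interdependency analysis on panel
cohorts where scoring all genes exactly is too costly:

1. an *approximate* stage — greedy hill-climbing over DAGs (add / delete /
   reverse moves, random restarts) on the full gene set, from which the
   anchors' Markov blankets give a candidate neighbor set; and
2. an *exact* stage — A* search over the order lattice (the dynamic-
   programming state space of variable subsets) that returns a globally
   score-optimal DAG over the candidates for the given local-score table.

Scores are decomposable: BDeu (Bayesian Dirichlet equivalent uniform,
equivalent sample size ``ess``) by default, or BIC.  BDeu assigns equal
scores to Markov-equivalent DAGs; the A* heuristic (sum of each remaining
node's unconstrained best parent-set score) is admissible and consistent,
so the first goal expansion is optimal.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .cohort import MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dag",
    "LocalScoreTable",
    "SearchResult",
    "local_scores",
    "exact_search",
    "hill_climb",
    "approximate_neighbors",
    "enumerate_all_dags",
    "to_dot",
    "to_graphml",
]


class StructureError(ValueError):
    """Raised for invalid structure-learning inputs."""


@dataclass(frozen=True)
class Dag:
    """A directed acyclic graph given by per-node parent sets."""

    nodes: tuple[str, ...]
    parent_sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "parent_sets",
            {n: frozenset(self.parent_sets.get(n, frozenset())) for n in self.nodes},
        )
        for node, parents in self.parent_sets.items():
            if node in parents:
                raise StructureError(f"{node} is its own parent")
            unknown = parents - set(self.nodes)
            if unknown:
                raise StructureError(f"unknown parents {sorted(unknown)} of {node}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise StructureError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        for node, parents in self.parent_sets.items():
            graph.add_edges_from((p, node) for p in parents)
        return graph

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (p, n) for n, parents in self.parent_sets.items() for p in parents
        )

    def children(self, node: str) -> frozenset[str]:
        return frozenset(
            n for n, parents in self.parent_sets.items() if node in parents
        )

    def markov_blanket(self, node: str) -> frozenset[str]:
        """Parents, children, and co-parents of ``node``."""
        blanket = set(self.parent_sets[node])
        for child in self.children(node):
            blanket.add(child)
            blanket |= self.parent_sets[child] - {node}
        blanket.discard(node)
        return frozenset(blanket)

    def moral_skeleton(self) -> set[frozenset[str]]:
        """Undirected edges of the moralised graph."""
        edges: set[frozenset[str]] = set()
        for node, parents in self.parent_sets.items():
            for p in parents:
                edges.add(frozenset({p, node}))
            for p, q in itertools.combinations(sorted(parents), 2):
                edges.add(frozenset({p, q}))
        return edges


@dataclass(frozen=True)
class SearchResult:
    dag: Dag
    total_score: float
    expansions: int


# ---------------------------------------------------------------------------
# Local scores


def _family_counts(
    child: np.ndarray, parents: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Counts N_jk of (parent configuration j, child state k) and N_j."""
    k = len(parents)
    config = np.zeros(child.shape[0], dtype=np.int64)
    for i, column in enumerate(parents):
        config |= column.astype(np.int64) << i
    joint = np.bincount(2 * config + child.astype(np.int64), minlength=2 ** (k + 1))
    njk = joint.reshape(-1, 2)  # rows = configurations, cols = child state
    return njk, njk.sum(axis=1)


def _bdeu_family(njk: np.ndarray, nj: np.ndarray, ess: float) -> float:
    q = njk.shape[0]
    alpha_j = ess / q
    alpha_jk = ess / (2.0 * q)
    return float(
        np.sum(gammaln(alpha_j) - gammaln(alpha_j + nj))
        + np.sum(gammaln(alpha_jk + njk) - gammaln(alpha_jk))
    )


def _bic_family(njk: np.ndarray, nj: np.ndarray, n: int) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(njk > 0, njk / np.maximum(nj, 1)[:, None], 1.0)
        ll = float(np.sum(njk * np.log(ratio)))
    return ll - 0.5 * np.log(n) * njk.shape[0]


class _ScoreCache:
    """Memoised decomposable family scores over a fixed matrix."""

    def __init__(
        self,
        matrix: MutationMatrix,
        nodes: Sequence[str],
        score: str = "bdeu",
        ess: float = 1.0,
    ) -> None:
        if score not in {"bdeu", "bic"}:
            raise StructureError(f"unknown score {score!r}")
        self.nodes = tuple(nodes)
        self.score = score
        self.ess = ess
        self.n = matrix.n_patients
        self._columns = {g: matrix.column(g) for g in nodes}
        self._memo: dict[tuple[str, frozenset[str]], float] = {}

    def family_score(self, child: str, parents: Iterable[str]) -> float:
        key = (child, frozenset(parents))
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        columns = [self._columns[p] for p in sorted(key[1])]
        njk, nj = _family_counts(self._columns[child], columns)
        if self.score == "bdeu":
            value = _bdeu_family(njk, nj, self.ess)
        else:
            value = _bic_family(njk, nj, self.n)
        self._memo[key] = value
        return value


@dataclass
class LocalScoreTable:
    """Decomposable local scores: node → {parent set → score}."""

    nodes: tuple[str, ...]
    scores: dict[str, dict[frozenset[str], float]]
    max_parents: int
    score_kind: str = "bdeu"

    def score_of(self, dag: Dag) -> float:
        return sum(self.scores[n][dag.parent_sets[n]] for n in self.nodes)

    def best_unconstrained(self, node: str) -> float:
        return max(self.scores[node].values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("node\tparents\tscore\n")
            for node in self.nodes:
                for parents, value in sorted(
                    self.scores[node].items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                ):
                    handle.write(f"{node}\t{';'.join(sorted(parents))}\t{value!r}\n")


def local_scores(
    matrix: MutationMatrix,
    nodes: Sequence[str],
    score: str = "bdeu",
    ess: float = 1.0,
    max_parents: int = 4,
) -> LocalScoreTable:
    """Score every node against every parent set of size ≤ max_parents."""
    nodes = tuple(nodes)
    unknown = set(nodes) - set(matrix.genes)
    if unknown:
        raise StructureError(f"nodes not in matrix: {sorted(unknown)}")
    if max_parents < 0:
        raise StructureError("max_parents must be non-negative")
    if max_parents >= len(nodes):
        warnings.warn(
            f"max_parents {max_parents} capped at {len(nodes) - 1}", stacklevel=2
        )
        max_parents = len(nodes) - 1
    cache = _ScoreCache(matrix, nodes, score=score, ess=ess)
    tables: dict[str, dict[frozenset[str], float]] = {}
    for node in nodes:
        others = [g for g in nodes if g != node]
        entries: dict[frozenset[str], float] = {}
        for size in range(max_parents + 1):
            for combo in itertools.combinations(others, size):
                entries[frozenset(combo)] = cache.family_score(node, combo)
        tables[node] = entries
    return LocalScoreTable(
        nodes=nodes, scores=tables, max_parents=max_parents, score_kind=score
    )


# ---------------------------------------------------------------------------
# Exact search: A* over the order lattice


def exact_search(table: LocalScoreTable) -> SearchResult:
    """Globally score-optimal DAG for a local-score table.

    A* over subsets S of nodes: a state is the set of already-placed nodes,
    a transition places node v with its best scored parent set within S.
    The heuristic sums each remaining node's unconstrained best score; it
    is admissible and consistent, so the first expansion of the full set is
    optimal.  States with equal f-value are expanded in ascending subset-
    mask order (deterministic tie-break).
    """
    m = len(table.nodes)
    if m == 0:
        raise StructureError("empty score table")
    if m > 25:
        raise StructureError(
            f"{m} nodes exceeds the exact-search guard (25); "
            "use the approximate (hill-climbing) mode"
        )
    node_bit = {node: 1 << i for i, node in enumerate(table.nodes)}
    size = 1 << m

    # bss[i][S]: best score of node i over scored parent sets ⊆ S.
    bss = np.full((m, size), -np.inf)
    for i, node in enumerate(table.nodes):
        arr = bss[i]
        for parents, value in table.scores[node].items():
            mask = 0
            for p in parents:
                mask |= node_bit[p]
            if value > arr[mask]:
                arr[mask] = value
        # superset max transform: arr[S] = max over scored subsets of S
        for j in range(m):
            view = arr.reshape(-1, 2, 1 << j)
            np.maximum(view[:, 1, :], view[:, 0, :], out=view[:, 1, :])
    best_full = bss[:, size - 1]

    def heuristic(mask: int) -> float:
        h = 0.0
        remaining = ~mask & (size - 1)
        while remaining:
            low = remaining & -remaining
            h += best_full[low.bit_length() - 1]
            remaining ^= low
        return h

    g_score = {0: 0.0}
    came_from: dict[int, tuple[int, int]] = {}
    heap: list[tuple[float, int]] = [(-heuristic(0), 0)]
    closed: set[int] = set()
    expansions = 0
    full = size - 1
    while heap:
        neg_f, mask = heapq.heappop(heap)
        if mask in closed:
            continue
        closed.add(mask)
        expansions += 1
        if mask == full:
            break
        base = g_score[mask]
        for i in range(m):
            bit = 1 << i
            if mask & bit:
                continue
            new_mask = mask | bit
            new_g = base + bss[i][mask]
            if new_g > g_score.get(new_mask, -np.inf):
                g_score[new_mask] = new_g
                came_from[new_mask] = (mask, i)
                heapq.heappush(heap, (-(new_g + heuristic(new_mask)), new_mask))
    else:  # pragma: no cover - the lattice always reaches the full set
        raise StructureError("order-lattice search failed to reach the goal")

    # Recover the order, then each node's best parent set among predecessors.
    order: list[int] = []
    mask = full
    while mask:
        mask, i = came_from[mask]
        order.append(i)
    order.reverse()

    parent_sets: dict[str, frozenset[str]] = {}
    placed: set[str] = set()
    for i in order:
        node = table.nodes[i]
        candidates = [
            (value, len(parents), tuple(sorted(parents)), parents)
            for parents, value in table.scores[node].items()
            if parents <= placed
        ]
        # highest score; ties: smallest set, then lexicographic
        candidates.sort(key=lambda item: (-item[0], item[1], item[2]))
        parent_sets[node] = candidates[0][3]
        placed.add(node)
    dag = Dag(nodes=table.nodes, parent_sets=parent_sets)
    return SearchResult(dag=dag, total_score=table.score_of(dag), expansions=expansions)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (test oracle)


def enumerate_all_dags(nodes: Sequence[str]) -> list[Dag]:
    """Every labeled DAG on ≤ 5 nodes, exactly once (oracle for tests)."""
    nodes = tuple(nodes)
    m = len(nodes)
    if m > 5:
        raise StructureError("enumeration limited to 5 nodes")
    pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
    dags: list[Dag] = []
    for mask in range(1 << len(pairs)):
        children: dict[int, set[int]] = {i: set() for i in range(m)}
        for k, (i, j) in enumerate(pairs):
            if mask >> k & 1:
                children[i].add(j)
        # acyclicity by iterated sink removal
        remaining = set(range(m))
        while True:
            sinks = [v for v in remaining if not (children[v] & remaining)]
            if not sinks:
                break
            remaining -= set(sinks)
        if remaining:
            continue
        parent_sets = {
            nodes[j]: frozenset(nodes[i] for i in range(m) if j in children[i])
            for j in range(m)
        }
        dags.append(Dag(nodes=nodes, parent_sets=parent_sets))
    return dags


# ---------------------------------------------------------------------------
# Hill climbing and neighbor discovery


def _creates_cycle(
    parent_sets: dict[str, set[str]], source: str, target: str
) -> bool:
    """Would adding source → target create a directed cycle?"""
    stack, seen = [source], set()
    while stack:
        node = stack.pop()
        if node == target:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(parent_sets[node])
    return False


def _random_dag(
    nodes: Sequence[str], rng: np.random.Generator, max_parents: int
) -> dict[str, set[str]]:
    order = list(rng.permutation(len(nodes)))
    parent_sets: dict[str, set[str]] = {n: set() for n in nodes}
    for pos, idx in enumerate(order):
        predecessors = [nodes[order[t]] for t in range(pos)]
        for p in predecessors:
            if len(parent_sets[nodes[idx]]) >= max_parents:
                break
            if rng.random() < 0.15:
                parent_sets[nodes[idx]].add(p)
    return parent_sets


def hill_climb(
    matrix: MutationMatrix,
    nodes: Sequence[str],
    score: str = "bdeu",
    ess: float = 1.0,
    max_parents: int = 4,
    restarts: int = 10,
    max_moves: int = 500,
    seed: int = 0,
) -> tuple[Dag, float]:
    """Greedy DAG search with add/delete/reverse moves and random restarts.

    Restart 0 starts from the empty graph; later restarts start from
    seeded random DAGs.  Deterministic for a fixed seed: candidate moves
    are evaluated in sorted node order and the single best strictly
    improving move is applied each step.
    """
    nodes = tuple(sorted(nodes))
    cache = _ScoreCache(matrix, nodes, score=score, ess=ess)
    rng = np.random.Generator(np.random.Philox(key=seed))
    best_dag: Dag | None = None
    best_total = -np.inf
    for restart in range(max(1, restarts)):
        if restart == 0:
            parent_sets: dict[str, set[str]] = {n: set() for n in nodes}
        else:
            parent_sets = _random_dag(nodes, rng, max_parents)
        local = {n: cache.family_score(n, parent_sets[n]) for n in nodes}
        for _ in range(max_moves):
            best_delta = 0.0
            best_move: tuple | None = None
            for target in nodes:
                pa = parent_sets[target]
                sc = local[target]
                for source in nodes:
                    if source == target:
                        continue
                    if source not in pa:
                        if len(pa) >= max_parents:
                            continue
                        if _creates_cycle(parent_sets, source, target):
                            continue
                        delta = cache.family_score(target, pa | {source}) - sc
                        move = ("add", source, target)
                    else:
                        delta = cache.family_score(target, pa - {source}) - sc
                        move = ("del", source, target)
                    if delta > best_delta + 1e-12:
                        best_delta, best_move = delta, move
                # reversals: pa(target) edges source→target become target→source
                for source in sorted(pa):
                    if len(parent_sets[source]) >= max_parents:
                        continue
                    trial = {n: set(ps) for n, ps in parent_sets.items()}
                    trial[target].discard(source)
                    if _creates_cycle(trial, target, source):
                        continue
                    delta = (
                        cache.family_score(target, pa - {source})
                        - sc
                        + cache.family_score(source, parent_sets[source] | {target})
                        - local[source]
                    )
                    if delta > best_delta + 1e-12:
                        best_delta, best_move = delta, ("rev", source, target)
            if best_move is None:
                break
            kind, source, target = best_move
            if kind == "add":
                parent_sets[target].add(source)
            elif kind == "del":
                parent_sets[target].discard(source)
            else:
                parent_sets[target].discard(source)
                parent_sets[source].add(target)
                local[source] = cache.family_score(source, parent_sets[source])
            local[target] = cache.family_score(target, parent_sets[target])
        total = sum(local.values())
        if total > best_total:
            best_total = total
            best_dag = Dag(
                nodes=nodes,
                parent_sets={n: frozenset(ps) for n, ps in parent_sets.items()},
            )
    assert best_dag is not None
    return best_dag, float(best_total)


def approximate_neighbors(
    matrix: MutationMatrix,
    anchors: Sequence[str],
    k: int = 15,
    score: str = "bdeu",
    ess: float = 1.0,
    max_parents: int = 4,
    restarts: int = 10,
    max_moves: int = 500,
    seed: int = 0,
) -> list[str]:
    """Candidate neighbor genes of the anchors via hill-climbing.

    Runs the greedy search on the full gene set and returns the union of
    the anchors' Markov blankets (anchors excluded).  If that union
    exceeds ``k``, the k genes with the largest single-edge score
    improvement when linked to an anchor are kept.  The returned list is
    ranked by that improvement, descending.
    """
    anchors = list(anchors)
    unknown = set(anchors) - set(matrix.genes)
    if unknown:
        raise StructureError(f"anchors not in matrix: {sorted(unknown)}")
    if k < 1:
        raise StructureError("k must be ≥ 1")
    dag, _ = hill_climb(
        matrix,
        matrix.genes,
        score=score,
        ess=ess,
        max_parents=max_parents,
        restarts=restarts,
        max_moves=max_moves,
        seed=seed,
    )
    blanket: set[str] = set()
    for anchor in anchors:
        blanket |= dag.markov_blanket(anchor)
    blanket -= set(anchors)
    cache = _ScoreCache(matrix, matrix.genes, score=score, ess=ess)

    def improvement(gene: str) -> float:
        base = cache.family_score(gene, ())
        return max(cache.family_score(gene, (a,)) - base for a in anchors)

    ranked = sorted(blanket, key=lambda g: (-improvement(g), g))
    return ranked[:k]


# ---------------------------------------------------------------------------
# Export


def to_dot(dag: Dag, frequencies: Mapping[str, float] | None = None) -> str:
    """Graphviz DOT text for a learned network."""
    lines = ["digraph cosegnet {"]
    for node in dag.nodes:
        label = node
        if frequencies and node in frequencies:
            label = f"{node}\\n{frequencies[node]:.3f}"
        lines.append(f'  "{node}" [label="{label}"];')
    for parent, child in dag.edges():
        lines.append(f'  "{parent}" -> "{child}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(
    dag: Dag,
    path: str | Path,
    frequencies: Mapping[str, float] | None = None,
) -> None:
    graph = dag.to_networkx()
    for node in graph.nodes:
        graph.nodes[node]["gene"] = node
        if frequencies and node in frequencies:
            graph.nodes[node]["frequency"] = float(frequencies[node])
    nx.write_graphml(graph, path)
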