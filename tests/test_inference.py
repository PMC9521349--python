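"""CPT fitting, variable elimination, loopy BP, and relative-risk queries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cosegnet.cohort import MutationMatrix
from cosegnet.inference import (
    CptSet,
    FactorGraph,
    InferenceError,
    empirical_relative_risk,
    event_probability,
    fit_cpts,
    loopy_bp,
    relative_risk,
    variable_elimination,
)
from cosegnet.structure import Dag


def make_dag(parent_sets):
    return Dag(nodes=tuple(parent_sets), parent_sets={
        k: frozenset(v) for k, v in parent_sets.items()
    })


def make_cpts(parents, tables):
    return CptSet(
        parents={k: tuple(v) for k, v in parents.items()},
        tables={k: np.asarray(v, dtype=float) for k, v in tables.items()},
        pseudo_count=0.0,
    )


CHAIN_DAG = make_dag({"A": (), "B": ("A",), "C": ("B",)})
CHAIN_CPTS = make_cpts(
    {"A": (), "B": ("A",), "C": ("B",)},
    {"A": [0.3], "B": [0.2, 0.7], "C": [0.1, 0.6]},
)


def joint_enumeration_oracle(dag, cpts, evidence, query):
    """P(query=1 | evidence) by summing the full 2^n joint (test oracle)."""
    nodes = list(dag.nodes)
    num = den = 0.0
    for values in itertools.product((0, 1), repeat=len(nodes)):
        state = dict(zip(nodes, values))
        if any(state[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for g in nodes:
            pa = cpts.parents[g]
            idx = sum(state[x] << i for i, x in enumerate(pa))
            p1 = float(cpts.tables[g][idx])
            p *= p1 if state[g] else 1 - p1
        den += p
        num += p * state[query]
    return num / den


def panel_network(rng, n_nodes, extra_edges=1):
    """Random polytree plus loop-forming edges, with CPTs shaped like
    fitted mutation-panel tables: base rates 2-30%, each parent scaling
    the risk by a factor in [0.5, 3] (capped at 0.95)."""
    nodes = tuple(f"V{i}" for i in range(n_nodes))
    parent_sets: dict[str, set] = {nodes[0]: set()}
    for i in range(1, n_nodes):
        parent_sets[nodes[i]] = {nodes[rng.integers(i)]}
    added = tries = 0
    while added < extra_edges and tries < 50:
        tries += 1
        i, j = sorted(rng.choice(n_nodes, size=2, replace=False))
        if nodes[i] not in parent_sets[nodes[j]] and len(parent_sets[nodes[j]]) < 3:
            parent_sets[nodes[j]].add(nodes[i])
            added += 1
    dag = Dag(
        nodes=nodes,
        parent_sets={k: frozenset(v) for k, v in parent_sets.items()},
    )
    parents = {n: tuple(sorted(parent_sets[n])) for n in nodes}
    tables = {}
    for n in nodes:
        base = rng.uniform(0.02, 0.3)
        k = len(parents[n])
        factors = rng.uniform(0.5, 3.0, size=max(1, k))
        table = np.empty(2 ** k)
        for j in range(2 ** k):
            scale = np.prod([factors[i] for i in range(k) if j >> i & 1]) if k else 1.0
            table[j] = min(0.95, base * scale)
        tables[n] = table
    return dag, make_cpts(parents, tables)


def random_network(rng, n_nodes, tree=False):
    """Random DAG + CPTs; ``tree`` gives a random polytree."""
    nodes = tuple(f"V{i}" for i in range(n_nodes))
    parent_sets: dict[str, frozenset] = {nodes[0]: frozenset()}
    for i in range(1, n_nodes):
        if tree:
            parent_sets[nodes[i]] = frozenset({nodes[rng.integers(i)]})
        else:
            k = min(i, int(rng.integers(0, 4)))
            parents = rng.choice(i, size=k, replace=False) if k else []
            parent_sets[nodes[i]] = frozenset(nodes[j] for j in parents)
    dag = Dag(nodes=nodes, parent_sets=parent_sets)
    parents = {n: tuple(sorted(parent_sets[n])) for n in nodes}
    tables = {
        n: rng.uniform(0.05, 0.95, size=2 ** len(parents[n])) for n in nodes
    }
    return dag, make_cpts(parents, tables)


class TestFitCpts:
    def test_root_node_hand_arithmetic(self):
        col = np.zeros(1000, dtype=int)
        col[:46] = 1
        matrix = MutationMatrix.from_arrays(
            [f"p{i}" for i in range(1000)], ["G"], col[:, None]
        )
        dag = make_dag({"G": ()})
        cpts = fit_cpts(matrix, dag, pseudo_count=1.0)
        assert cpts.tables["G"][0] == pytest.approx(47 / 1002)

    def test_unseen_parent_configuration_gets_half(self):
        values = np.array([[0, 0], [1, 0], [0, 0]])  # parent P never mutated
        matrix = MutationMatrix.from_arrays(["p1", "p2", "p3"], ["C", "P"], values)
        dag = make_dag({"P": (), "C": ("P",)})
        cpts = fit_cpts(matrix, dag, pseudo_count=1.0)
        # configuration P=1 unseen for rows of C
        assert cpts.tables["C"][1] == pytest.approx(0.5)

    def test_zero_pseudo_count_recovers_empirical_frequency(self):
        values = np.array([[1, 1], [1, 0], [0, 1], [0, 0], [1, 1]])
        matrix = MutationMatrix.from_arrays(
            [f"p{i}" for i in range(5)], ["C", "P"], values
        )
        dag = make_dag({"P": (), "C": ("P",)})
        cpts = fit_cpts(matrix, dag, pseudo_count=0.0)
        # P=1 rows: patients p0, p2, p4 → C = 1, 0, 1
        assert cpts.tables["C"][1] == pytest.approx(2 / 3)

    def test_smoothed_probabilities_strictly_interior(self, planted_cohort):
        dag = make_dag({"BRCA1": (), "BRCA2": ("BRCA1",)})
        cpts = fit_cpts(planted_cohort.matrix, dag)
        for table in cpts.tables.values():
            assert np.all((table > 0) & (table < 1))


class TestVariableElimination:
    def test_independent_nodes_ignore_evidence(self):
        dag = make_dag({"A": (), "B": ()})
        cpts = make_cpts({"A": (), "B": ()}, {"A": [0.3], "B": [0.8]})
        assert variable_elimination(dag, cpts, {"B": 1}, "A") == pytest.approx(0.3)

    def test_chain_posterior_hand_value(self):
        # P(C=1 | A=1) = P(C=1|B=1)P(B=1|A=1) + P(C=1|B=0)P(B=0|A=1)
        expected = 0.6 * 0.7 + 0.1 * 0.3
        assert variable_elimination(
            CHAIN_DAG, CHAIN_CPTS, {"A": 1}, "C"
        ) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_full_joint_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        dag, cpts = random_network(rng, int(rng.integers(3, 11)))
        evidence_nodes = [n for n in dag.nodes[1:] if rng.random() < 0.3]
        evidence = {n: int(rng.integers(2)) for n in evidence_nodes}
        query = dag.nodes[0]
        assert variable_elimination(dag, cpts, evidence, query) == pytest.approx(
            joint_enumeration_oracle(dag, cpts, evidence, query), abs=1e-12
        )

    def test_impossible_evidence_is_an_error(self):
        dag = make_dag({"A": (), "B": ("A",)})
        cpts = make_cpts({"A": (), "B": ("A",)}, {"A": [0.3], "B": [0.0, 0.0]})
        with pytest.raises(InferenceError, match="zero"):
            variable_elimination(dag, cpts, {"B": 1}, "A")

    def test_query_in_evidence_rejected(self):
        with pytest.raises(InferenceError):
            variable_elimination(CHAIN_DAG, CHAIN_CPTS, {"C": 1}, "C")

    def test_event_probability_factorises_for_independents(self):
        dag = make_dag({"A": (), "B": ()})
        cpts = make_cpts({"A": (), "B": ()}, {"A": [0.3], "B": [0.8]})
        assert event_probability(dag, cpts, {"A": 1, "B": 0}) == pytest.approx(
            0.3 * 0.2
        )


class TestLoopyBP:
    def test_edgeless_graph_returns_priors(self):
        dag = make_dag({"A": (), "B": ()})
        cpts = make_cpts({"A": (), "B": ()}, {"A": [0.25], "B": [0.9]})
        result = loopy_bp(FactorGraph.from_network(dag, cpts), tol=1e-12)
        assert result.converged
        assert result.marginals["A"][1] == pytest.approx(0.25, abs=1e-9)
        assert result.marginals["B"][1] == pytest.approx(0.9, abs=1e-9)

    def test_chain_with_evidence_matches_elimination(self):
        graph = FactorGraph.from_network(CHAIN_DAG, CHAIN_CPTS)
        result = loopy_bp(graph, evidence={"A": 1}, tol=1e-12, max_iters=500)
        expected = variable_elimination(CHAIN_DAG, CHAIN_CPTS, {"A": 1}, "C")
        assert result.converged
        assert result.marginals["C"][1] == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_on_random_polytrees(self, seed):
        rng = np.random.default_rng(200 + seed)
        dag, cpts = random_network(rng, int(rng.integers(3, 9)), tree=True)
        result = loopy_bp(
            FactorGraph.from_network(dag, cpts), tol=1e-12, max_iters=500
        )
        assert result.converged
        for node in dag.nodes:
            exact = variable_elimination(dag, cpts, {}, node)
            assert result.marginals[node][1] == pytest.approx(exact, abs=1e-8)

    def test_marginals_normalised(self):
        rng = np.random.default_rng(5)
        dag, cpts = random_network(rng, 7)
        result = loopy_bp(FactorGraph.from_network(dag, cpts))
        for belief in result.marginals.values():
            assert belief.sum() == pytest.approx(1.0, abs=1e-12)

    def test_contradictory_evidence_names_factor(self):
        graph = FactorGraph(
            variables=("A", "B"),
            factors=[("coupling", ("A", "B"), np.array([[1.0, 0.0], [0.0, 1.0]]))],
        )
        with pytest.raises(InferenceError, match="coupling|evidence"):
            loopy_bp(graph, evidence={"A": 1, "B": 0})

    def test_unknown_evidence_gene_rejected(self):
        graph = FactorGraph.from_network(CHAIN_DAG, CHAIN_CPTS)
        with pytest.raises(InferenceError):
            loopy_bp(graph, evidence={"ZZZ": 1})


class TestRelativeRisk:
    def test_independent_condition_gives_unit_rr(self):
        dag = make_dag({"A": (), "B": ()})
        cpts = make_cpts({"A": (), "B": ()}, {"A": [0.3], "B": [0.8]})
        estimate = relative_risk(dag, cpts, "A", ["B"])
        assert estimate.rr == pytest.approx(1.0, abs=1e-12)

    def test_mutual_exclusivity_drives_rr_to_zero(self):
        dag = make_dag({"A": (), "B": ("A",)})
        cpts = make_cpts({"A": (), "B": ("A",)}, {"A": [0.3], "B": [0.2, 1e-9]})
        estimate = relative_risk(dag, cpts, "B", ["A"])
        assert estimate.rr == pytest.approx(0.0, abs=1e-6)

    def test_two_node_hand_arithmetic_both_directions(self):
        dag = make_dag({"A": (), "B": ("A",)})
        cpts = make_cpts({"A": (), "B": ("A",)}, {"A": [0.3], "B": [0.2, 0.6]})
        forward = relative_risk(dag, cpts, "B", ["A"], direction="anchor_given_genes")
        assert forward.rr == pytest.approx(0.6 / 0.2)
        # reverse: P(A=1|B=1)/P(A=1|B=0) via Bayes
        p_b = 0.3 * 0.6 + 0.7 * 0.2
        p_a_given_b = 0.3 * 0.6 / p_b
        p_a_given_not_b = 0.3 * 0.4 / (1 - p_b)
        reverse = relative_risk(dag, cpts, "A", ["B"], direction="anchor_given_genes")
        assert reverse.rr == pytest.approx(p_a_given_b / p_a_given_not_b)

    @given(perm=st.permutations(["B", "C", "D"]))
    def test_condition_order_invariance(self, perm):
        dag = make_dag({"A": (), "B": ("A",), "C": ("A",), "D": ("A",)})
        cpts = make_cpts(
            {"A": (), "B": ("A",), "C": ("A",), "D": ("A",)},
            {"A": [0.2], "B": [0.1, 0.5], "C": [0.2, 0.4], "D": [0.3, 0.6]},
        )
        base = relative_risk(dag, cpts, "A", ["B", "C", "D"]).rr
        assert relative_risk(dag, cpts, "A", list(perm)).rr == pytest.approx(base)

    def test_genes_given_anchor_multi_gene_joint(self):
        dag = make_dag({"A": (), "B": ("A",), "C": ("A",)})
        cpts = make_cpts(
            {"A": (), "B": ("A",), "C": ("A",)},
            {"A": [0.2], "B": [0.1, 0.5], "C": [0.2, 0.4]},
        )
        estimate = relative_risk(
            dag, cpts, "A", ["B", "C"], direction="genes_given_anchor"
        )
        # children independent given A
        assert estimate.rr == pytest.approx((0.5 * 0.4) / (0.1 * 0.2))

    def test_anchor_in_condition_rejected(self):
        with pytest.raises(InferenceError):
            relative_risk(CHAIN_DAG, CHAIN_CPTS, "A", ["A", "B"])

    def test_monotone_on_generator_exact_joint(self, planted_model):
        from cosegnet.synthetic import true_relative_risk

        single = true_relative_risk(planted_model, "BRCA1", ["NOTCH1"])
        double = true_relative_risk(planted_model, "BRCA1", ["NOTCH1", "MTOR"])
        triple = true_relative_risk(planted_model, "BRCA1", ["NOTCH1", "MTOR", "ARID1A"])
        assert single <= double <= triple


class TestEmpiricalRelativeRisk:
    def test_eight_patient_hand_count(self):
        values = np.array(
            [
                [1, 1],
                [1, 1],
                [0, 1],
                [1, 0],
                [0, 0],
                [0, 0],
                [0, 0],
                [1, 0],
            ]
        )
        matrix = MutationMatrix.from_arrays(
            [f"p{i}" for i in range(8)], ["A", "G"], values
        )
        estimate = empirical_relative_risk(matrix, "A", ["G"])
        # P(A|G=1) = 2/3, P(A|G=0) = 2/5
        assert estimate.rr == pytest.approx((2 / 3) / (2 / 5))
        assert not estimate.degenerate

    def test_empty_stratum_continuity_corrected(self):
        values = np.array([[1, 1], [0, 1], [1, 1]])
        matrix = MutationMatrix.from_arrays(["p1", "p2", "p3"], ["A", "G"], values)
        estimate = empirical_relative_risk(matrix, "A", ["G"])
        assert estimate.degenerate
        assert math.isfinite(estimate.rr)
        # (2 + 0.5)/(3 + 1) over (0 + 0.5)/(0 + 1)
        assert estimate.rr == pytest.approx((2.5 / 4) / 0.5)

    def test_agrees_with_model_on_large_sample(self, planted_cohort):
        model_based = relative_risk(
            make_dag({"BRCA1": (), "ERBB2": ("BRCA1",)}),
            fit_cpts(
                planted_cohort.matrix,
                make_dag({"BRCA1": (), "ERBB2": ("BRCA1",)}),
                pseudo_count=0.0,
            ),
            "BRCA1",
            ["ERBB2"],
        )
        empirical = empirical_relative_risk(planted_cohort.matrix, "BRCA1", ["ERBB2"])
        assert model_based.rr == pytest.approx(empirical.rr, rel=1e-9)
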