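"""CPDAG learner, d-separation oracle, equivalence-class utilities."""

import itertools

import networkx as nx
import numpy as np
import pytest

from bnsurvey.structure import (
    Cpdag,
    LearnConfig,
    _meek,
    dag_to_cpdag,
    dsep,
    learn_cpdag,
    learn_markov_blanket,
    oracle_ci,
    shd,
)
from bnsurvey.synthetic import reference_network, random_dag, simulate_stratum


def named_dag(edges, n_nodes=None):
    g = nx.DiGraph()
    if n_nodes:
        g.add_nodes_from(f"x{i}" for i in range(n_nodes))
    g.add_edges_from(edges)
    return g


class TestDsep:
    def test_chain_blocked_by_middle(self, chain_dag):
        assert dsep(chain_dag, "x", "z", ["y"])
        assert not dsep(chain_dag, "x", "z")

    def test_collider_opens_when_conditioned(self, collider_dag):
        assert dsep(collider_dag, "x", "y")
        assert not dsep(collider_dag, "x", "y", ["z"])

    def test_agrees_with_networkx_on_random_dags(self):
        rng = np.random.default_rng(17)
        for i in range(200):
            g = named_dag(random_dag(8, 10, np.random.default_rng(i)), n_nodes=8)
            nodes = sorted(g.nodes)
            x, y = rng.choice(nodes, size=2, replace=False)
            rest = [n for n in nodes if n not in (x, y)]
            z = set(rng.choice(rest, size=rng.integers(0, 4), replace=False))
            assert dsep(g, x, y, z) == nx.is_d_separator(g, {x}, {y}, z)

    def test_rejects_overlapping_arguments(self, chain_dag):
        with pytest.raises(ValueError):
            dsep(chain_dag, "x", "x")
        with pytest.raises(ValueError):
            dsep(chain_dag, "x", "y", ["y"])


def enumerate_3node_cpdag(dag):
    """Independent oracle: the union of orientations over the equivalence
    class of a 3-node DAG, classes defined by (skeleton, v-structures)."""

    def signature(g):
        skel = frozenset(frozenset(e) for e in g.edges)
        vstr = set()
        for z in g.nodes:
            for a, b in itertools.combinations(sorted(g.predecessors(z)), 2):
                if not (g.has_edge(a, b) or g.has_edge(b, a)):
                    vstr.add((a, b, z))
        return skel, frozenset(vstr)

    nodes = list(dag.nodes)
    all_dags = []
    pairs = list(itertools.combinations(nodes, 2))
    for choices in itertools.product((None, 0, 1), repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (a, b), c in zip(pairs, choices):
            if c == 0:
                g.add_edge(a, b)
            elif c == 1:
                g.add_edge(b, a)
        if nx.is_directed_acyclic_graph(g):
            all_dags.append(g)
    target = signature(dag)
    members = [g for g in all_dags if signature(g) == target]
    directed, undirected = set(), set()
    for a, b in dag.edges:
        if all(g.has_edge(a, b) for g in members):
            directed.add((a, b))
        else:
            undirected.add(tuple(sorted((a, b))))
    return Cpdag(nodes, undirected, directed)


class TestDagToCpdag:
    def test_chain_is_fully_reversible(self, chain_dag):
        g = dag_to_cpdag(chain_dag)
        assert g.undirected == {("x", "y"), ("y", "z")} and not g.directed

    def test_collider_is_fully_compelled(self, collider_dag):
        g = dag_to_cpdag(collider_dag)
        assert g.directed == {("x", "z"), ("y", "z")} and not g.undirected

    def test_single_edge_is_reversible(self):
        g = dag_to_cpdag(named_dag([("x", "y")]))
        assert g.undirected == {("x", "y")} and not g.directed

    def test_matches_equivalence_class_enumeration_on_all_3node_dags(self):
        nodes = ["a", "b", "c"]
        pairs = list(itertools.combinations(nodes, 2))
        seen = 0
        for choices in itertools.product((None, 0, 1), repeat=3):
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            for (a, b), c in zip(pairs, choices):
                if c == 0:
                    g.add_edge(a, b)
                elif c == 1:
                    g.add_edge(b, a)
            if not nx.is_directed_acyclic_graph(g):
                continue
            seen += 1
            assert shd(dag_to_cpdag(g), enumerate_3node_cpdag(g)) == 0
        assert seen == 25  # all acyclic orientations of 3 possible edges

    def test_rejects_cyclic_input(self):
        with pytest.raises(ValueError, match="acyclic"):
            dag_to_cpdag(nx.DiGraph([("a", "b"), ("b", "a")]))

    def test_meek_closure_is_idempotent(self):
        for i in range(25):
            g = named_dag(random_dag(6, 7, np.random.default_rng(i)), n_nodes=6)
            cp = dag_to_cpdag(g)
            status = {e: "und" for e in cp.undirected}
            status.update({tuple(sorted(e)): e for e in cp.directed})
            before = dict(status)
            _meek(status)
            assert status == before


class TestMarkovBlanket:
    def test_collider_blanket_contains_child_and_spouse(self, collider_dag):
        nodes = ["x", "y", "z"]
        mb = learn_markov_blanket(None, "x", ci=oracle_ci(collider_dag, nodes), nodes=nodes)
        assert mb == {"y", "z"}

    def test_chain_blanket_is_the_single_neighbour(self, chain_dag):
        nodes = ["x", "y", "z"]
        mb = learn_markov_blanket(None, "x", ci=oracle_ci(chain_dag, nodes), nodes=nodes)
        assert mb == {"y"}

    def test_independent_nodes_have_empty_blanket(self):
        g = named_dag([], n_nodes=3)
        nodes = sorted(g.nodes)
        mb = learn_markov_blanket(None, "x0", ci=oracle_ci(g, nodes), nodes=nodes)
        assert mb == set()

    def test_blanket_from_data_matches_graph(self):
        net = reference_network(1.5, seed=0)
        records, _ = simulate_stratum(net, 50_000, seed=13)
        g = net.graph()
        target = "ever_tested"
        truth = set(g.predecessors(target)) | set(g.successors(target))
        for child in g.successors(target):
            truth |= set(g.predecessors(child)) - {target}
        mb = learn_markov_blanket(records, list(net.nodes).index(target), nodes=list(net.nodes))
        assert mb == truth


class TestLearnCpdagOracle:
    def test_chain_and_collider(self, chain_dag, collider_dag):
        nodes = ["x", "y", "z"]
        learned = learn_cpdag(ci=oracle_ci(chain_dag, nodes), nodes=nodes)
        assert shd(learned, dag_to_cpdag(chain_dag, nodes)) == 0
        learned = learn_cpdag(ci=oracle_ci(collider_dag, nodes), nodes=nodes)
        assert shd(learned, dag_to_cpdag(collider_dag, nodes)) == 0

    def test_independent_nodes_give_empty_graph(self):
        g = named_dag([], n_nodes=4)
        nodes = sorted(g.nodes)
        learned = learn_cpdag(ci=oracle_ci(g, nodes), nodes=nodes)
        assert learned.n_edges == 0

    def test_equivalence_on_random_dags(self):
        for i in range(60):
            g = named_dag(random_dag(6, 8, np.random.default_rng(1000 + i)), n_nodes=6)
            nodes = sorted(g.nodes)
            learned = learn_cpdag(ci=oracle_ci(g, nodes), nodes=nodes)
            learned.validate()
            assert shd(learned, dag_to_cpdag(g, nodes)) == 0, i


class TestLearnCpdagData:
    def test_majority_exact_recovery_at_large_n(self):
        # single-run recovery is limited by the test's type-I error: a
        # spurious edge that survives every separation attempt does not
        # vanish with n, which is exactly why the bootstrap consensus
        # exists.  Majority exact recovery is the honest single-run claim.
        net = reference_network(1.5, seed=0)
        truth = dag_to_cpdag(net.graph(), net.nodes)
        shds = []
        for seed in range(8):
            records, _ = simulate_stratum(net, 50_000, seed=seed)
            learned = learn_cpdag(records, LearnConfig(), nodes=list(net.nodes))
            learned.validate()
            shds.append(shd(learned, truth))
        assert sum(s == 0 for s in shds) >= 5, shds

    def test_constant_column_stays_isolated(self):
        rng = np.random.default_rng(3)
        data = (rng.random((800, 4)) < 0.5).astype(np.uint8)
        data[:, 2] = 1
        g = learn_cpdag(data, LearnConfig())
        assert all("x2" not in e for e in g.skeleton())

    def test_dataframe_input_uses_column_names(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        a = (rng.random(4000) < 0.5).astype(np.uint8)
        b = ((rng.random(4000) < 0.15) ^ a).astype(np.uint8)
        g = learn_cpdag(pd.DataFrame({"a": a, "b": b}))
        assert g.skeleton() == {("a", "b")}


class TestShd:
    def base(self):
        return Cpdag("abc", [("a", "b")], [("b", "c")])

    def test_identical_graphs_have_distance_zero(self):
        assert shd(self.base(), self.base()) == 0

    def test_extra_edge_counts_one(self):
        other = Cpdag("abc", [("a", "b"), ("a", "c")], [("b", "c")])
        assert shd(self.base(), other) == 1

    def test_orientation_mismatch_counts_one(self):
        other = Cpdag("abc", [("a", "b"), ("b", "c")], [])
        assert shd(self.base(), other) == 1
        reversed_ = Cpdag("abc", [("a", "b")], [("c", "b")])
        assert shd(self.base(), reversed_) == 1

    def test_symmetry(self):
        other = Cpdag("abc", [], [("a", "b")])
        assert shd(self.base(), other) == shd(other, self.base())

    def test_rejects_different_node_sets(self):
        with pytest.raises(ValueError):
            shd(self.base(), Cpdag("abd", [], []))


class TestCpdagInvariants:
    def test_pair_cannot_be_both_directed_and_undirected(self):
        with pytest.raises(ValueError):
            Cpdag("ab", [("a", "b")], [("a", "b")])

    def test_directed_part_must_be_acyclic(self):
        with pytest.raises(ValueError, match="cycle"):
            Cpdag("abc", [], [("a", "b"), ("b", "c"), ("c", "a")])

    def test_learn_config_validation(self):
        with pytest.raises(ValueError):
            LearnConfig(alpha=0.0)
        with pytest.raises(ValueError):
            LearnConfig(test="mutual-information")

    def test_json_round_trip(self, tmp_path):
        g = Cpdag("abc", [("a", "b")], [("b", "c")])
        path = tmp_path / "g.json"
        g.to_json(path)
        assert Cpdag.from_json(path) == g
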