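"""Bayesian network stack: BDeu scoring against an independent
Dirichlet-multinomial oracle, likelihood equivalence, hill-climbing
optimality, bootstrap averaging, condition merging, and key drivers.

The oracle computes the marginal likelihood by sequential prediction:
P(data) = prod_rows P(x_row | counts so far) under Dirichlet priors,
never touching the gamma-function closed form the implementation uses.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import sncausal as sc
from sncausal.bayesnet import BootstrapStrength
from sncausal.containers import DiscretizedMatrix
from sncausal.exceptions import PipelineError


def make_discrete(values, n_levels, genes=None):
    values = np.asarray(values, dtype=np.int64)
    genes = pd.Index(
        genes if genes is not None else [f"g{i}" for i in range(values.shape[1])]
    )
    breaks = [np.arange(1, k) - 0.5 for k in n_levels]
    return DiscretizedMatrix(values, genes, breaks, max(n_levels))


def sequential_predictive_log_score(values, cards, dag_edges, iss=1.0):
    """Independent oracle: log prod_t P(x_t | x_1..x_{t-1}) with BDeu
    Dirichlet priors, accumulated row by row with plain dictionaries."""
    n, p = values.shape
    parents = {j: [] for j in range(p)}
    for a, b in dag_edges:
        parents[b].append(a)
    log_p = 0.0
    counts: dict = {}
    for t in range(n):
        for j in range(p):
            pa = tuple(values[t, k] for k in sorted(parents[j]))
            r = cards[j]
            q = int(np.prod([cards[k] for k in sorted(parents[j])])) or 1
            a_jk = iss / (r * q)
            node_counts = counts.setdefault(j, {})
            cfg = node_counts.setdefault(pa, [0] * r)
            total = sum(cfg)
            x = values[t, j]
            log_p += np.log((a_jk + cfg[x]) / (iss / q + total))
            cfg[x] += 1
    return log_p


def all_dags(nodes):
    """Every DAG over the given nodes (enumeration oracle)."""
    pairs = list(itertools.permutations(nodes, 2))
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        edges = [e for e, m in zip(pairs, mask) if m]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield g


class TestDiscretize:
    def test_worked_interval_example(self):
        vals = np.array([[0.0], [0.5], [1.0], [1.5], [3.0]])
        dm = sc.discretize_interval(vals, 3)
        np.testing.assert_array_equal(dm.values.ravel(), [0, 0, 1, 1, 2])

    def test_max_value_lands_in_closed_last_bin(self):
        dm = sc.discretize_interval(np.array([[0.0], [1.0], [2.0], [3.0]]), 3)
        assert dm.values.ravel()[-1] == 2

    def test_two_bins_split_at_midpoint(self):
        dm = sc.discretize_interval(np.array([[0.0], [0.49], [0.51], [1.0]]), 2)
        np.testing.assert_array_equal(dm.values.ravel(), [0, 0, 1, 1])

    def test_constant_gene_single_level_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            dm = sc.discretize_interval(np.ones((5, 1)), 3)
        assert dm.constant[0]
        assert dm.cardinalities[0] == 1
        assert (dm.values == 0).all()


class TestBdeScore:
    def test_hand_derived_single_node(self):
        """Binary node with data (0,0,1): marginal likelihood 1/16."""
        dm = make_discrete([[0], [0], [1]], [2])
        g = nx.DiGraph()
        g.add_node("g0")
        assert sc.bde_score(dm, g) == pytest.approx(np.log(1 / 16), abs=1e-12)

    def test_empty_data_scores_zero(self):
        dm = make_discrete(np.empty((0, 2), dtype=int), [2, 2])
        g = nx.DiGraph()
        g.add_nodes_from(["g0", "g1"])
        assert sc.bde_score(dm, g) == pytest.approx(0.0, abs=1e-12)

    def test_cyclic_graph_rejected(self):
        dm = make_discrete([[0, 1], [1, 0]], [2, 2])
        g = nx.DiGraph([("g0", "g1"), ("g1", "g0")])
        with pytest.raises(ValueError, match="cyclic"):
            sc.bde_score(dm, g)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sequential_predictive_oracle(self, seed):
        """BDeu equals the Dirichlet-multinomial predictive product on
        random 3-node datasets, to 1e-9."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        cards = [3, 3, 3]
        vals = np.column_stack([rng.integers(0, c, n) for c in cards])
        dm = make_discrete(vals, cards)
        edges_idx = [(0, 1), (0, 2), (1, 2)][: int(rng.integers(0, 4))]
        edges = [(f"g{a}", f"g{b}") for a, b in edges_idx]
        g = nx.DiGraph()
        g.add_nodes_from(dm.genes)
        g.add_edges_from(edges)
        oracle = sequential_predictive_log_score(vals, cards, edges_idx)
        assert sc.bde_score(dm, g) == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_likelihood_equivalence_all_3node_dags(self, seed):
        """All DAGs in a Markov equivalence class share one BDe score."""
        rng = np.random.default_rng(100 + seed)
        vals = rng.integers(0, 3, size=(40, 3))
        dm = make_discrete(vals, [3, 3, 3])
        scores = {}
        for g in all_dags(["g0", "g1", "g2"]):
            key = _equivalence_class_key(g)
            s = sc.bde_score(dm, g)
            scores.setdefault(key, []).append(s)
        assert len(list(all_dags(["g0", "g1", "g2"]))) == 25
        for klass, vals_ in scores.items():
            assert max(vals_) - min(vals_) < 1e-9, klass


def _equivalence_class_key(g):
    """Skeleton + v-structures characterize the Markov equivalence class."""
    skeleton = frozenset(frozenset(e) for e in g.edges)
    v_structs = frozenset(
        (a, c, b)
        for b in g.nodes
        for a, c in itertools.combinations(sorted(g.predecessors(b)), 2)
        if not g.has_edge(a, c) and not g.has_edge(c, a)
    )
    return skeleton, v_structs


class TestHillClimb:
    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, size=(500, 2))
        dm = make_discrete(vals, [2, 2])
        dag = sc.hill_climb(dm)
        assert dag.number_of_edges() == 0
        # exhaustive check: the empty graph beats both single-arc DAGs
        best = max(all_dags(["g0", "g1"]), key=lambda g: sc.bde_score(dm, g))
        assert best.number_of_edges() == 0

    def test_dependent_pair_recovered_up_to_equivalence(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 500)
        b = np.where(rng.random(500) < 0.95, a, 1 - a)
        dm = make_discrete(np.c_[a, b], [2, 2], genes=["A", "B"])
        dag = sc.hill_climb(dm)
        assert {tuple(sorted(e)) for e in dag.edges} == {("A", "B")}
        best = max(all_dags(["A", "B"]), key=lambda g: sc.bde_score(dm, g))
        assert best.number_of_edges() == 1

    def test_matches_exhaustive_search_on_3_nodes(self):
        """The greedy optimum equals the global optimum's score on easy
        3-node data (chain structure, strong dependence)."""
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 800)
        b = np.clip(a + rng.integers(-1, 2, 800), 0, 2)
        c = np.clip(b + rng.integers(-1, 2, 800), 0, 2)
        dm = make_discrete(np.c_[a, b, c], [3, 3, 3])
        learned = sc.hill_climb(dm)
        best = max(
            (sc.bde_score(dm, g) for g in all_dags(list(dm.genes)))
        )
        assert sc.bde_score(dm, learned) == pytest.approx(best, abs=1e-9)

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 3, size=(200, 4))
        dm = make_discrete(vals, [3] * 4)
        assert sorted(sc.hill_climb(dm).edges) == sorted(sc.hill_climb(dm).edges)

    def test_trajectory_strictly_increasing_and_local_optimum(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 400)
        b = np.clip(a + rng.integers(-1, 2, 400), 0, 2)
        c = rng.integers(0, 3, 400)
        dm = make_discrete(np.c_[a, b, c], [3, 3, 3])
        dag, traj = sc.hill_climb(dm, return_trajectory=True)
        assert all(t1 > t0 for t0, t1 in zip(traj, traj[1:]))
        # no single-arc move improves the final graph (checked exhaustively)
        final = sc.bde_score(dm, dag)
        for g in all_dags(list(dm.genes)):
            diff = set(g.edges) ^ set(dag.edges)
            if len(diff) == 1 or (
                len(diff) == 2 and {tuple(sorted(e)) for e in diff} and
                len({tuple(sorted(e)) for e in diff}) == 1
            ):
                assert sc.bde_score(dm, g) <= final + 1e-9

    def test_max_in_degree_respected(self):
        rng = np.random.default_rng(5)
        z = rng.integers(0, 3, 500)
        cols = [np.clip(z + rng.integers(-1, 2, 500), 0, 2) for _ in range(4)]
        dm = make_discrete(np.column_stack([z] + cols), [3] * 5)
        dag = sc.hill_climb(dm, max_in_degree=1)
        assert max(dict(dag.in_degree()).values()) <= 1


class TestBootstrapStrength:
    @pytest.fixture(scope="class")
    def chain_data(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 3, 400)
        b = np.clip(a + rng.integers(-1, 2, 400), 0, 2)
        return make_discrete(np.c_[a, b], [3, 3], genes=["A", "B"])

    def test_strong_arc_has_full_strength(self, chain_data):
        bs = sc.bootstrap_strength(chain_data, n_boot=25, seed=0)
        assert bs.strength("A", "B") == 1.0

    def test_direction_frequencies_sum_to_one(self, chain_data):
        bs = sc.bootstrap_strength(chain_data, n_boot=25, seed=0)
        assert bs.direction("A", "B") + bs.direction("B", "A") == pytest.approx(1.0)

    def test_absent_arc_has_zero_strength(self, chain_data):
        bs = sc.bootstrap_strength(chain_data, n_boot=10, seed=0)
        assert bs.strength("A", "nonexistent") == 0.0

    def test_seeded_reproducibility(self, chain_data):
        a = sc.bootstrap_strength(chain_data, n_boot=15, seed=3)
        b = sc.bootstrap_strength(chain_data, n_boot=15, seed=3)
        assert a.pair_counts == b.pair_counts and a.dir_counts == b.dir_counts

    def test_frequencies_bounded(self, chain_data):
        bs = sc.bootstrap_strength(chain_data, n_boot=20, seed=1)
        frame = bs.to_frame()
        assert ((frame.strength >= 0) & (frame.strength <= 1)).all()
        assert ((frame.direction_ab >= 0) & (frame.direction_ab <= 1)).all()


class TestAveragedNetwork:
    def _bs(self, pair_counts, dir_counts, n=100):
        bs = BootstrapStrength(nodes=["A", "B", "C"], n_replicates=n)
        bs.pair_counts.update(pair_counts)
        bs.dir_counts.update(dir_counts)
        return bs

    def test_strength_threshold(self):
        bs = self._bs({("A", "B"): 90, ("B", "C"): 80},
                      {("A", "B"): 90, ("B", "C"): 80})
        net = sc.averaged_network(bs)
        assert list(net.edges) == [("A", "B")]

    def test_orientation_by_majority(self):
        bs = self._bs({("A", "B"): 100}, {("A", "B"): 40, ("B", "A"): 60})
        net = sc.averaged_network(bs)
        assert list(net.edges) == [("B", "A")]
        assert net.edges["B", "A"]["direction"] == pytest.approx(0.6)

    def test_exact_tie_oriented_lexicographically_and_flagged(self):
        bs = self._bs({("A", "B"): 100}, {("A", "B"): 50, ("B", "A"): 50})
        with pytest.warns(UserWarning, match="tie"):
            net = sc.averaged_network(bs)
        assert list(net.edges) == [("A", "B")]
        assert net.edges["A", "B"]["tie"]

    def test_cycle_repair_drops_weakest(self):
        bs = self._bs(
            {("A", "B"): 100, ("B", "C"): 90, ("A", "C"): 95},
            {("A", "B"): 100, ("B", "C"): 90, ("C", "A"): 95},
        )
        with pytest.warns(UserWarning, match="cycle"):
            net = sc.averaged_network(bs)
        assert nx.is_directed_acyclic_graph(net)
        assert not net.has_edge("B", "C")  # weakest arc in the cycle


class TestMergeAndDrivers:
    def test_identical_networks_all_both(self):
        g = nx.DiGraph([("A", "B", {"strength": 0.9, "direction": 1.0})])
        merged = sc.merge_condition_networks(g, g.copy())
        assert all(d["provenance"] == "both" for _, d in merged.nodes(data=True))
        assert merged.edges["A", "B"]["provenance"] == "both"

    def test_ctrl_strength_preferred_when_both(self):
        ctrl = nx.DiGraph([("A", "B", {"strength": 0.9, "direction": 1.0})])
        case = nx.DiGraph([("A", "B", {"strength": 0.95, "direction": 1.0})])
        merged = sc.merge_condition_networks(ctrl, case)
        assert merged.edges["A", "B"]["weight"] == pytest.approx(0.9)

    def test_disjoint_edges_keep_condition_provenance(self):
        ctrl = nx.DiGraph([("A", "B", {"strength": 0.9, "direction": 1.0})])
        case = nx.DiGraph([("B", "C", {"strength": 0.88, "direction": 1.0})])
        merged = sc.merge_condition_networks(ctrl, case)
        assert merged.edges["A", "B"]["provenance"] == "NT"
        assert merged.edges["B", "C"]["provenance"] == "HD"
        assert merged.nodes["C"]["provenance"] == "HD"

    def test_regulation_flags_from_deg_table(self):
        ctrl = nx.DiGraph([("A", "B", {"strength": 0.9, "direction": 1.0})])
        deg = pd.DataFrame(
            {"gene": ["A"], "significant": [True], "direction": ["up"]}
        ).set_index("gene", drop=False)
        merged = sc.merge_condition_networks(ctrl, ctrl.copy(), deg)
        assert merged.nodes["A"]["regulation"] == "up"
        assert merged.nodes["B"]["regulation"] == "ns"

    def test_hub_definition_is_strict(self):
        g = nx.DiGraph()
        g.add_edges_from(("H", f"x{i}") for i in range(11))  # 11 out-edges
        g.add_edges_from(("J", f"y{i}") for i in range(10))  # exactly 10
        drivers = sc.find_key_drivers(g)
        roles = dict(zip(drivers.gene, drivers.role))
        assert roles.get("H") == "hub"
        assert "J" not in roles

    def test_connector_between_two_hubs(self):
        g = nx.DiGraph()
        g.add_edges_from(("H1", f"x{i}") for i in range(11))
        g.add_edges_from(("H2", f"y{i}") for i in range(11))
        g.add_edge("H1", "X")
        g.add_edge("X", "H2")
        drivers = sc.find_key_drivers(g)
        roles = dict(zip(drivers.gene, drivers.role))
        assert roles.get("X") == "connector"

    def test_self_loop_through_single_hub_not_connector(self):
        g = nx.DiGraph()
        g.add_edges_from(("H", f"x{i}") for i in range(11))
        g.add_edge("H", "X")
        g.add_edge("X", "H")  # same hub both sides
        drivers = sc.find_key_drivers(g)
        assert "X" not in set(drivers.gene)


class TestSelectFeatures:
    def test_sorted_union(self):
        assert sc.select_features({"c", "a", "b"}, {"d", "c"}) == \
            ["a", "b", "c", "d"]

    def test_empty_degs_returns_module_genes(self):
        assert sc.select_features(set(), {"x", "y"}) == ["x", "y"]

    def test_empty_union_is_pipeline_error(self):
        with pytest.raises(PipelineError):
            sc.select_features(set(), set())


class TestEstimators:
    def test_bde_hill_climb_estimator(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 2, 300)
        b = np.where(rng.random(300) < 0.9, a, 1 - a)
        est = sc.BDeHillClimb().fit(np.c_[a, b], feature_names=["A", "B"])
        assert {tuple(sorted(e)) for e in est.dag_.edges} == {("A", "B")}
        assert est.score_ == est.trajectory_[-1]

    def test_bootstrap_network_estimator(self):
        rng = np.random.default_rng(10)
        a = rng.integers(0, 3, 300)
        b = np.clip(a + rng.integers(-1, 2, 300), 0, 2)
        est = sc.BootstrapNetwork(n_boot=20, random_state=0).fit(
            np.c_[a, b].astype(float), feature_names=["A", "B"]
        )
        assert est.network_.number_of_edges() == 1
        assert est.strength_frame_.strength.iloc[0] >= 0.85
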