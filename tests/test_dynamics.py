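import itertools
import random

import networkx as nx
import pytest

import switchdyn as sd
from switchdyn.dynamics import build_annotated
from switchdyn.fixtures import brute_force_recurrent, printed_networks


def essential_param(name):
    net = sd.parse_network(printed_networks()[name])
    pg = sd.ParameterGraph.build(net, essential=True)
    assert pg.size == 1
    return net, pg.parameter_at(0)


def pipeline(net, param):
    D = sd.multilevel_map(net, param)
    stg = sd.async_stg(D)
    md = sd.morse_decomposition(stg)
    return D, stg, md, sd.morse_graph(md)


class TestMultiLevelMap:
    def test_toggle_is_double_negation(self):
        net, param = essential_param("toggle_essential")
        D = sd.multilevel_map(net, param)
        for s in sd.state_space(net).states():
            assert D(s) == (1 - s[1], 1 - s[0])
        assert D((0, 1)) == (0, 1)

    def test_negative_loop(self):
        net = sd.parse_network(printed_networks()["negative_loop"])
        pg = sd.ParameterGraph.build(net, essential=True)
        D = sd.multilevel_map(net, pg.parameter_at(0))
        for s in sd.state_space(net).states():
            assert D(s) == (1 - s[1], s[0])
        assert D((0, 0)) == (1, 0)

    def test_constant_logic_map_gives_constant_coordinate(self):
        net = sd.parse_network("X : Y\nY : X\n")
        pg = sd.ParameterGraph.build(net)
        for p in range(pg.size):
            param = pg.parameter_at(p)
            if len(set(param.logic_maps[0].table)) == 1:
                k = param.logic_maps[0].table[0]
                D = sd.multilevel_map(net, param)
                assert all(t[0] == k for _, t in D.items())


class TestAsyncSTG:
    def test_toggle_edges(self):
        net, param = essential_param("toggle_essential")
        _, stg, _, _ = pipeline(net, param)
        g = stg.graph
        assert set(g.successors((0, 0))) == {(1, 0), (0, 1)}
        assert set(g.successors((1, 0))) == {(1, 0)}
        assert set(g.successors((0, 1))) == {(0, 1)}
        assert set(g.successors((1, 1))) == {(0, 1), (1, 0)}

    def test_negative_loop_four_cycle(self):
        net = sd.parse_network(printed_networks()["negative_loop"])
        pg = sd.ParameterGraph.build(net, essential=True)
        _, stg, _, _ = pipeline(net, pg.parameter_at(0))
        cycle = [(0, 0), (1, 0), (1, 1), (0, 1)]
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            assert set(stg.graph.successors(a)) == {b}

    def test_out_degree_law(self):
        net = sd.parse_network("X : XY\nY : XY\n")
        pg = sd.ParameterGraph.build(net)
        rng = random.Random(0)
        for p in [rng.randrange(pg.size) for _ in range(20)]:
            D, stg, _, _ = pipeline(net, pg.parameter_at(p))
            for s, t in D.items():
                k = sum(a != b for a, b in zip(s, t))
                assert stg.graph.out_degree(s) == (k if k else 1)
                if k == 0:
                    assert stg.graph.has_edge(s, s)


class TestMorseDecomposition:
    def test_toggle_two_incomparable_fixed_points(self):
        net, param = essential_param("toggle_essential")
        _, _, md, _ = pipeline(net, param)
        assert md.components == [frozenset({(1, 0)}), frozenset({(0, 1)})]
        assert md.reaches == set()

    def test_negative_loop_single_cycle_component(self):
        net = sd.parse_network(printed_networks()["negative_loop"])
        pg = sd.ParameterGraph.build(net, essential=True)
        _, _, md, _ = pipeline(net, pg.parameter_at(0))
        assert md.components == [frozenset({(0, 0), (1, 0), (1, 1), (0, 1)})]

    def test_chain_keeps_only_recurrent_sink(self):
        net = sd.parse_network("X : X\n")
        pg = sd.ParameterGraph.build(net)
        # map (1,1): D(0)=1, D(1)=1 -> chain 0 -> 1 with self-loop at 1 only
        param = pg.parameter_at(2)
        _, _, md, _ = pipeline(net, param)
        assert md.components == [frozenset({(1,)})]

    def test_matches_brute_force_closure(self):
        net = sd.parse_network(printed_networks()["2D_Example_A"])
        pg = sd.ParameterGraph.build(net)
        rng = random.Random(1)
        for p in [rng.randrange(pg.size) for _ in range(25)]:
            _, stg, md, _ = pipeline(net, pg.parameter_at(p))
            bf = brute_force_recurrent(stg)
            assert md.components == bf.components
            assert md.reaches == bf.reaches


class TestAnnotation:
    def test_fixed_point_off_and_on(self):
        net = sd.parse_network("X : X\nY : Y\n")
        pg = sd.ParameterGraph.build(net)
        labels = set()
        for p in range(pg.size):
            _, _, _, mg = pipeline(net, pg.parameter_at(p))
            labels.update(mg.labels)
        assert "FP(0,0) OFF" in labels
        assert "FP(1,1) ON" in labels
        assert "FP(0,1)" in labels  # neither all-zero nor all-nonzero

    def test_full_cycle(self):
        net = sd.parse_network(printed_networks()["negative_loop"])
        pg = sd.ParameterGraph.build(net, essential=True)
        _, _, _, mg = pipeline(net, pg.parameter_at(0))
        assert mg.labels == ("FC",)
        assert mg.attractors == (0,)

    def test_partial_oscillation_lists_moving_variable(self):
        net = sd.parse_network("X : X\nY : ~Y\nZ : Z\n")
        pg = sd.ParameterGraph.build(net)
        # X, Z constant at 0; Y essential negative self-loop oscillates
        target = None
        for p in range(pg.size):
            param = pg.parameter_at(p)
            if (param.logic_maps[0].table == (0, 0)
                    and param.logic_maps[1].table == (0, 1)
                    and param.logic_maps[2].table == (0, 0)):
                target = param
        # one Y-flip 2-cycle per (x, z) slice; transients drain toward 0
        D, stg, md, mg = pipeline(net, target)
        assert set(mg.labels) == {"XC(Y)"}
        assert len(mg.attractors) == 1

    def test_non_recurrent_singleton_rejected(self):
        net = sd.parse_network("X : X\n")
        pg = sd.ParameterGraph.build(net)
        _, stg, _, _ = pipeline(net, pg.parameter_at(2))
        with pytest.raises(ValueError):
            sd.annotate(frozenset({(0,)}), stg, net)


class TestMorseGraph:
    def test_chain_with_recurrent_endpoints_has_one_hasse_edge(self):
        # hand-built STG 0 -> 1 -> 2 with self-loops at 0 and 2: two fixed
        # points, one reachability relation, exactly one attractor
        net = sd.parse_network("X : X\n")
        space = sd.StateSpace((3,))
        g = nx.DiGraph([((0,), (0,)), ((0,), (1,)), ((1,), (2,)), ((2,), (2,))])
        stg = sd.StateTransitionGraph(net, space, g, frozenset({(0,), (2,)}))
        mg = sd.morse_graph(sd.morse_decomposition(stg))
        assert mg.labels == ("FP(0) OFF", "FP(2) ON")
        assert mg.edges == frozenset({(0, 1)})
        assert mg.attractors == (1,)

    def test_every_graph_has_attractor_and_is_acyclic(self):
        net = sd.parse_network(printed_networks()["2D_Example_A"])
        pg = sd.ParameterGraph.build(net)
        rng = random.Random(5)
        for p in [rng.randrange(pg.size) for _ in range(30)]:
            _, _, _, mg = pipeline(net, pg.parameter_at(p))
            assert mg.attractors
            g = nx.DiGraph(list(mg.edges))
            g.add_nodes_from(range(mg.n_nodes))
            assert nx.is_directed_acyclic_graph(g)
            # FP labels exactly on singleton components
            for v, label in enumerate(mg.labels):
                assert label.startswith("FP") == (len(mg.components[v]) == 1)


def brute_force_isomorphic(g1, g2):
    labels1, edges1 = g1
    labels2, edges2 = g2
    if len(labels1) != len(labels2):
        return False
    k = len(labels1)
    for perm in itertools.permutations(range(k)):
        if all(labels1[v] == labels2[perm[v]] for v in range(k)) and \
                {(perm[a], perm[b]) for a, b in edges1} == set(edges2):
            return True
    return False


def random_labeled_dag(rng, max_nodes=6):
    k = rng.randint(1, max_nodes)
    labels = [rng.choice(["FP(0,0) OFF", "FP(1,1) ON", "FC", "XC(Y)"]) for _ in range(k)]
    order = list(range(k))
    rng.shuffle(order)
    edges = set()
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < 0.3:
                edges.add((order[i], order[j]))
    return labels, edges


class TestCanonicalForm:
    def test_relabeling_invariance_on_toggle(self):
        g1 = build_annotated(["FP(1,0)", "FP(0,1)"], set())
        g2 = build_annotated(["FP(0,1)", "FP(1,0)"], set())
        assert g1.canonical_string == g2.canonical_string

    def test_fp_vs_fc_differ(self):
        assert build_annotated(["FP(0,0) OFF"], set()).canonical_string != \
            build_annotated(["FC"], set()).canonical_string

    def test_matches_brute_force_isomorphism(self):
        rng = random.Random(11)
        graphs = [random_labeled_dag(rng) for _ in range(40)]
        # permuted copies must collide
        for labels, edges in graphs[:20]:
            k = len(labels)
            perm = list(range(k))
            rng.shuffle(perm)
            plabels = [None] * k
            for v in range(k):
                plabels[perm[v]] = labels[v]
            pedges = {(perm[a], perm[b]) for a, b in edges}
            assert build_annotated(labels, edges).canonical_string == \
                build_annotated(plabels, pedges).canonical_string
        # arbitrary pairs: string equality iff isomorphic
        for i in range(0, 30, 2):
            g1, g2 = graphs[i], graphs[i + 1]
            same = build_annotated(*g1).canonical_string == build_annotated(*g2).canonical_string
            assert same == brute_force_isomorphic(g1, g2)


class TestCompatibility:
    def test_essential_parameters_are_network_compatible(self):
        """Every essential parameter's D carries a sign-correct witness for
        every edge (positive: some upward step in the source raises the
        target's update; negative: lowers it)."""
        for name in ("toggle_essential", "2D_Example_A_essential"):
            net = sd.parse_network(printed_networks()[name])
            pg = sd.ParameterGraph.build(net)
            space = sd.state_space(net)
            for p in range(pg.size):
                D = sd.multilevel_map(net, pg.parameter_at(p))
                for src, tgt, sign in net.edges:
                    i, j = net.index(src), net.index(tgt)
                    witness = False
                    for s in space.states():
                        for hi in range(s[i] + 1, space.shape[i]):
                            u = s[:i] + (hi,) + s[i + 1:]
                            d = D(u)[j] - D(s)[j]
                            if (sign == "activation" and d > 0) or \
                                    (sign == "repression" and d < 0):
                                witness = True
                    assert witness, (name, p, src, tgt, sign)
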