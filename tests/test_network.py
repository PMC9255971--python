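"""Interaction-network construction and graph metrics vs exhaustive oracles."""

import itertools
import random

import networkx as nx
import numpy as np
import pytest

from polyrisk.atc import MEDICATION_LEVEL
from polyrisk.interactions import DetectedInteraction
from polyrisk.network import (
    InteractionNetwork,
    aggregate_pairs,
    build_network,
    chord_matrix,
    compute_metrics,
)


def det(pair, pid="P1", severity="C", kind="DDI"):
    return DetectedInteraction(pid, tuple(sorted(pair)), severity, kind)


def graph_network(g):
    return InteractionNetwork(level=MEDICATION_LEVEL, graph=g)


# -- independent combinatorial oracles --------------------------------------

def bfs_diameter(g):
    """All-pairs shortest paths by BFS on the largest component."""
    comp = max(nx.connected_components(g), key=len)
    best = 0
    for source in comp:
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        best = max(best, max(dist.values()))
    return best


def triple_transitivity(g):
    """Global transitivity by exhaustive enumeration of vertex triples."""
    closed = open_ = 0
    for u, v, w in itertools.permutations(g.nodes, 3):
        # ordered paths v-u-w centred at u; count each connected triple
        if g.has_edge(u, v) and g.has_edge(u, w):
            if g.has_edge(v, w):
                closed += 1
            else:
                open_ += 1
    total = closed + open_
    return closed / total if total else 0.0


# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_triangle_from_three_detections(self):
        ann = {"furosemide": "C03", "lisinopril": "C09", "warfarin": "B01"}
        dets = [
            det(("furosemide", "lisinopril")),
            det(("furosemide", "warfarin")),
            det(("lisinopril", "warfarin")),
        ]
        net = build_network(dets, 2, ann)
        assert net.n_nodes == 3 and net.n_edges == 3

    def test_empty_detections_empty_network(self):
        net = build_network([], 2, {})
        assert net.n_nodes == 0 and compute_metrics(net).n_components == 0

    def test_adjacency_equals_hand_aggregation(self):
        # 12 detections across 5 subgroups, weights hand-counted
        ann = {c: f"G{i//2}" for i, c in enumerate("abcdefghij")}
        pairs = [("a", "c")] * 3 + [("a", "e")] * 2 + [("c", "e")] * 1 \
            + [("g", "i")] * 4 + [("a", "i")] * 2
        net = build_network([det(p, pid=f"P{i}") for i, p in enumerate(pairs)], 2, ann)
        weights = {tuple(sorted(e)): w for *e, w in net.graph.edges.data("weight")}
        assert weights == {
            ("G0", "G1"): 3, ("G0", "G2"): 2, ("G1", "G2"): 1,
            ("G3", "G4"): 4, ("G0", "G4"): 2,
        }

    def test_same_subgroup_pairs_become_self_tally_not_edges(self):
        ann = {"atorvastatin": "C10", "simvastatin": "C10", "warfarin": "B01"}
        dets = [det(("atorvastatin", "simvastatin")), det(("simvastatin", "warfarin"))]
        net = build_network(dets, 2, ann)
        assert net.self_pair_count == 1 and net.n_edges == 1

    def test_unmapped_drug_routed_to_report(self):
        ann = {"warfarin": "B01"}
        net = build_network([det(("turmeric", "warfarin"))], 2, ann)
        assert net.unmapped_count == 1 and net.n_edges == 0

    def test_aggregation_conservation(self):
        rng = random.Random(5)
        drugs = [f"d{i}" for i in range(12)]
        ann = {d: f"G{rng.randrange(4)}" for d in drugs[:9]}  # 3 drugs unmapped
        dets = [
            det(rng.sample(drugs, 2), pid=f"P{i}") for i in range(60)
        ]
        net = build_network(dets, 2, ann)
        assert net.total_weight() + net.self_pair_count + net.unmapped_count == 60


class TestMetrics:
    def test_triangle(self):
        g = nx.complete_graph(3)
        m = compute_metrics(graph_network(g))
        assert (m.density, m.diameter, m.triadic_closure) == (1.0, 1, 1.0)

    def test_path(self):
        g = nx.path_graph(3)
        m = compute_metrics(graph_network(g))
        assert m.density == pytest.approx(2 / 3)
        assert m.diameter == 2 and m.triadic_closure == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_er_graphs_match_exhaustive_oracles(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        m = compute_metrics(graph_network(g))
        n, e = g.number_of_nodes(), g.number_of_edges()
        assert m.density == pytest.approx(2 * e / (n * (n - 1)))
        assert m.diameter == bfs_diameter(g)
        assert m.triadic_closure == pytest.approx(triple_transitivity(g))
        assert m.n_components == len(list(nx.connected_components(g)))

    def test_metrics_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(10, 0.35, seed=7)
        perm = dict(zip(g.nodes, np.random.default_rng(0).permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, {k: f"x{v}" for k, v in perm.items()})
        a, b = compute_metrics(graph_network(g)), compute_metrics(graph_network(h))
        assert (a.density, a.diameter, a.triadic_closure, a.n_components) == (
            b.density, b.diameter, b.triadic_closure, b.n_components
        )

    def test_disconnected_graph_diameter_on_largest_component(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        m = compute_metrics(graph_network(g))
        assert m.diameter == 2 and m.n_components == 2
        assert m.component_diameters == (2, 1)


class TestChordMatrix:
    ann = {c: c.upper() for c in "abcdefg"}

    def test_threshold_filter(self):
        dets = [det(("a", "b"), pid=f"P{i}") for i in range(25)] + [
            det(("a", "c"), pid=f"P{i}") for i in range(5)
        ]
        mat, labels = chord_matrix(dets, 2, self.ann, min_count=20)
        assert labels == ["A", "B"]
        assert mat[0, 1] == 25

    def test_min_count_one_conserves_counts(self):
        dets = [det(("a", "b"))] * 3 + [det(("c", "d"))] * 2
        mat, labels = chord_matrix(dets, 2, self.ann, min_count=1)
        assert mat.sum() == 2 * 5
        assert (mat == mat.T).all() and (np.diag(mat) == 0).all()

    def test_hand_filter_on_seven_pairs(self):
        counts = {("a", "b"): 5, ("a", "c"): 2, ("b", "c"): 3, ("a", "d"): 1,
                  ("c", "d"): 4, ("b", "d"): 2, ("a", "e"): 3}
        dets = [
            det(p, pid=f"P{i}{j}") for j, (p, k) in enumerate(counts.items())
            for i in range(k)
        ]
        mat, labels = chord_matrix(dets, 2, self.ann, min_count=3)
        kept = {
            (labels[i], labels[j]): mat[i, j]
            for i in range(len(labels)) for j in range(i + 1, len(labels))
            if mat[i, j]
        }
        assert kept == {("A", "B"): 5, ("B", "C"): 3, ("C", "D"): 4, ("A", "E"): 3}

    def test_min_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            chord_matrix([], 2, self.ann, min_count=0)


def test_aggregate_pairs_medication_level_keeps_distinct_drugs():
    ann = {"a": "a", "b": "b"}
    counts, self_pairs, unmapped = aggregate_pairs([det(("a", "b"))], MEDICATION_LEVEL, ann)
    assert counts == {("a", "b"): 1} and self_pairs == 0 and unmapped == 0
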