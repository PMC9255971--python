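"""Interaction networks at medication level or any ATC rollup level.

Each node is a medication (generic name) or an ATC class at level 1-3; an
edge joins two nodes whenever at least one detected interaction aggregates
to that pair, weighted by the number of patient-level detections. The three
reported metrics are

  * density      — realized edges over all possible edges, 2E / (N(N-1));
  * diameter     — longest shortest path within the largest connected
                   component (interaction networks are often disconnected);
  * triadic closure — global transitivity, 3 x triangles / connected triples.

At a rollup level, two interacting drugs may fall in the same class; such
detections become a self-pair tally reported alongside the graph rather than
self-loop edges. Detections involving an unclassified drug are likewise
routed to an unmapped tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .atc import MEDICATION_LEVEL


@dataclass
class InteractionNetwork:
    level: object  # MEDICATION_LEVEL or int 1-3
    graph: nx.Graph
    self_pair_count: int = 0
    unmapped_count: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges.data("weight"))


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    triadic_closure: float
    n_components: int
    mean_local_clustering: float
    component_diameters: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density outside [0, 1]")
        if not 0.0 <= self.triadic_closure <= 1.0:
            raise ValueError("triadic closure outside [0, 1]")


def aggregate_pairs(
    detections: Iterable, level, annotation: Mapping[str, str]
) -> tuple:
    """Roll detection pairs up to node labels at ``level``.

    Returns ``(pair_counts, self_pairs, unmapped)``: occurrence counts per
    unordered node pair, the count of detections collapsing onto one node,
    and the count involving a drug with no label. Conservation holds:
    the three sum to the number of input detections.
    """
    pair_counts: dict = {}
    self_pairs = 0
    unmapped = 0
    for det in detections:
        a, b = det.pair
        la, lb = annotation.get(a), annotation.get(b)
        if not la or not lb:
            unmapped += 1
            continue
        if la == lb and level != MEDICATION_LEVEL:
            self_pairs += 1
            continue
        key = tuple(sorted((la, lb)))
        pair_counts[key] = pair_counts.get(key, 0) + 1
    return pair_counts, self_pairs, unmapped


def build_network(
    detections: Iterable, level, annotation: Mapping[str, str]
) -> InteractionNetwork:
    """Aggregate detections into a simple weighted undirected graph.

    The node universe is the set of labels that actually interact, not the
    full formulary. ``annotation`` maps generic name -> node label (see
    :func:`polyrisk.atc.annotation_map`).
    """
    pair_counts, self_pairs, unmapped = aggregate_pairs(detections, level, annotation)
    g = nx.Graph()
    for (a, b), w in sorted(pair_counts.items()):
        g.add_edge(a, b, weight=w)
    return InteractionNetwork(
        level=level, graph=g, self_pair_count=self_pairs, unmapped_count=unmapped
    )


def compute_metrics(network: InteractionNetwork) -> NetworkMetrics:
    """Density, diameter (largest component), transitivity, component count.

    Degenerate conventions: an empty or single-node graph has density 0,
    diameter 0 and closure 0; these arise only on near-empty fixtures.
    """
    g = network.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    if n == 0:
        return NetworkMetrics(0, 0, 0.0, 0, 0.0, 0, 0.0, ())
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    comp_diams = tuple(
        nx.diameter(g.subgraph(c)) if len(c) > 1 else 0 for c in components
    )
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        density=density,
        diameter=comp_diams[0] if comp_diams else 0,
        triadic_closure=float(nx.transitivity(g)),
        n_components=len(components),
        mean_local_clustering=float(nx.average_clustering(g)),
        component_diameters=comp_diams,
    )


def chord_matrix(
    detections: Iterable,
    level,
    annotation: Mapping[str, str],
    min_count: int = 1,
) -> tuple:
    """Symmetric occurrence matrix for chord-diagram export.

    Cell (i, j) holds the detection count aggregating to pair (i, j) when it
    reaches ``min_count``, else 0; the diagonal is zero and labels are sorted.
    Returns ``(matrix, labels)``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    pair_counts, _, _ = aggregate_pairs(detections, level, annotation)
    kept = {p: w for p, w in pair_counts.items() if w >= min_count}
    labels = sorted({lab for pair in kept for lab in pair})
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for (a, b), w in kept.items():
        mat[idx[a], idx[b]] = w
        mat[idx[b], idx[a]] = w
    return mat, labels


def write_edge_list(network: InteractionNetwork, path) -> None:
    rows = [
        {"source": a, "target": b, "weight": w}
        for a, b, w in sorted(network.graph.edges.data("weight"))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


def write_chord_matrix(mat: np.ndarray, labels: Sequence[str], path) -> None:
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(path)
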