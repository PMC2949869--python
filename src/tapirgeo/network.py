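"""Haplotype networks: minimum spanning network and median joining.

The minimum spanning network (MSN) is the union of all minimum spanning
trees of the haplotypes under Hamming distance. Median joining (Bandelt,
Forster & Roehl 1999) augments the node set with median (Steiner) vectors —
majority-consensus sequences of triplets — whenever they shorten the
network, recomputes the MSN on the augmented set, and prunes unsampled
vectors that end up with degree <= 2, iterating to a fixed point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .seq_io import HaplotypeTable, InputError


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # nodes: sequence strings; edge attr "weight" = Hamming dist
    sampled: dict[str, str]  # sequence -> hap_id for sampled haplotypes
    epsilon: int = 0

    @property
    def median_vectors(self) -> list[str]:
        return [n for n in self.graph.nodes if n not in self.sampled]

    def total_length(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for node in self.graph.nodes:
            g.add_node(
                node,
                hap_id=self.sampled.get(node, ""),
                median="0" if node in self.sampled else "1",
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]))
        nx.write_graphml(g, path)

    def to_dot(self) -> str:
        lines = ["graph haplotypes {"]
        for node in sorted(self.graph.nodes):
            if node in self.sampled:
                lines.append(f'  "{node}" [label="{self.sampled[node]}"];')
            else:
                lines.append(f'  "{node}" [label="mv", shape=point];')
        for u, v, d in sorted(self.graph.edges(data=True)):
            lines.append(f'  "{u}" -- "{v}" [label={int(d["weight"])}];')
        lines.append("}")
        return "\n".join(lines)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_graph(seqs: list[str], epsilon: int = 0) -> nx.Graph:
    """Union of all minimum spanning trees, relaxed by ``epsilon``.

    Kruskal over distance classes: an edge of weight w is kept when its
    endpoints lie in different components of the graph built from all edges
    of weight < w - epsilon (epsilon=0 gives the exact union of MSTs at
    each weight class).
    """
    seqs = sorted(set(seqs))
    g = nx.Graph()
    g.add_nodes_from(seqs)
    if len(seqs) < 2:
        return g
    edges = sorted(
        (_hamming(a, b), a, b) for a, b in itertools.combinations(seqs, 2)
    )
    weights = sorted({w for w, _, _ in edges})
    for w in weights:
        # components induced by strictly closer edge classes (with relaxation)
        base = nx.Graph()
        base.add_nodes_from(seqs)
        base.add_edges_from((a, b) for ww, a, b in edges if ww < w - epsilon)
        comp = {n: i for i, c in enumerate(nx.connected_components(base)) for n in c}
        for ww, a, b in edges:
            if ww == w and comp[a] != comp[b]:
                g.add_edge(a, b, weight=w)
        if nx.is_connected(g) and w >= max(
            d["weight"] for _, _, d in g.edges(data=True)
        ):
            # all later classes connect already-connected nodes at higher cost
            if epsilon == 0:
                break
    return g


def minimum_spanning_network(haps: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    if len(haps.haplotypes) < 2:
        raise InputError("network needs at least 2 haplotypes")
    sampled = {seq: hap_id for hap_id, seq in haps.haplotypes}
    g = _msn_graph(list(sampled), epsilon=epsilon)
    return HaplotypeNetwork(g, sampled, epsilon)


def _medians(a: str, b: str, c: str) -> list[str]:
    """Majority-consensus vectors of a triplet; column ties branch."""
    options: list[list[str]] = []
    for x, y, z in zip(a, b, c):
        votes = {x, y, z}
        if len(votes) < 3:
            # a majority exists
            maj = max(votes, key=lambda ch: (x, y, z).count(ch))
            options.append([maj])
        else:
            options.append(sorted(votes))
    out = {"".join(combo) for combo in itertools.product(*options)}
    return sorted(out)


def median_joining(haps: HaplotypeTable, epsilon: int = 0, max_iter: int = 50) -> HaplotypeNetwork:
    """Bandelt-style median-joining network.

    Each round: build the (epsilon-relaxed) MSN over the current node set;
    for every connected triplet, propose its median vector(s); add those
    that strictly reduce the total MSN length; prune unsampled nodes of
    degree <= 2; stop at a fixed point.
    """
    if len(haps.haplotypes) < 2:
        raise InputError("network needs at least 2 haplotypes")
    sampled = {seq: hap_id for hap_id, seq in haps.haplotypes}
    nodes: set[str] = set(sampled)

    def msn_length(node_set: set[str]) -> float:
        g = _msn_graph(sorted(node_set), epsilon=epsilon)
        mst = nx.minimum_spanning_tree(g, weight="weight")
        return float(sum(d["weight"] for _, _, d in mst.edges(data=True)))

    for _ in range(max_iter):
        g = _msn_graph(sorted(nodes), epsilon=epsilon)
        base_len = msn_length(nodes)
        # connected triplets: u-v, v-w adjacent in the current network
        candidates: set[str] = set()
        for v in g.nodes:
            nbrs = sorted(g.neighbors(v))
            for u, w in itertools.combinations(nbrs, 2):
                for med in _medians(u, v, w):
                    if med not in nodes:
                        candidates.add(med)
        best_gain, best_med = 0.0, None
        for med in sorted(candidates):
            gain = base_len - msn_length(nodes | {med})
            if gain > best_gain + 1e-9:
                best_gain, best_med = gain, med
        changed = False
        if best_med is not None:
            nodes.add(best_med)
            changed = True
        # prune unsampled nodes with degree <= 2 in the current MSN
        g = _msn_graph(sorted(nodes), epsilon=epsilon)
        while True:
            doomed = [
                n
                for n in g.nodes
                if n not in sampled and g.degree(n) <= 2
            ]
            if not doomed:
                break
            nodes -= set(doomed)
            changed = True
            g = _msn_graph(sorted(nodes), epsilon=epsilon)
        if not changed:
            break
    g = _msn_graph(sorted(nodes), epsilon=epsilon)
    return HaplotypeNetwork(g, sampled, epsilon)
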