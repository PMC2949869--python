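"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration — and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from tapirgeo.trees import GeneTree, Node


# -- pairwise differences ----------------------------------------------------

def brute_mean_pairwise_difference(seqs: list[str]) -> float:
    n = len(seqs)
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
            pairs += 1
    return total / pairs


# -- AMOVA from the sums-of-squares definitions ------------------------------

def brute_amova_components(dist, partition):
    """Variance components computed directly from squared-distance sums.

    ``partition``: {group: {pop: [labels]}}. Returns (sigma_a, sigma_b,
    sigma_c) via the Excoffier mean-square identities, every sum written as
    an explicit loop over sample pairs.
    """
    labels = dist.labels
    pos = {lab: i for i, lab in enumerate(labels)}
    d2 = dist.matrix**2

    def ssd(samples):
        tot = 0.0
        for a in samples:
            for b in samples:
                tot += d2[pos[a], pos[b]]
        return tot / (2.0 * len(samples))

    pops = [(g, p, partition[g][p]) for g in partition for p in partition[g]]
    all_samples = [s for _, _, ss in pops for s in ss]
    N = len(all_samples)
    G = len(partition)
    P = len(pops)

    ssd_total = ssd(all_samples)
    ssd_wp = sum(ssd(ss) for _, _, ss in pops)
    ssd_wg = 0.0
    for g in partition:
        members = []
        for p in partition[g]:
            members.extend(partition[g][p])
        ssd_wg += ssd(members)

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = (ssd_wp / df_wp) if df_wp else 0.0

    sizes = {p: len(ss) for _, p, ss in pops}
    gsizes = {g: sum(len(partition[g][p]) for p in partition[g]) for g in partition}
    sum_npg = sum(
        sum(len(partition[g][p]) ** 2 for p in partition[g]) / gsizes[g]
        for g in partition
    )
    sigma_c = ms_wp
    sigma_b = sigma_a = None
    if df_ap:
        n1 = (N - sum_npg) / df_ap
        sigma_b = ((ssd_wg - ssd_wp) / df_ap - sigma_c) / n1
    if df_ag:
        n2 = (sum_npg - sum(v**2 for v in sizes.values()) / N) / df_ag
        n3 = (N - sum(v**2 for v in gsizes.values()) / N) / df_ag
        sb = sigma_b if sigma_b is not None else 0.0
        sigma_a = ((ssd_total - ssd_wg) / df_ag - sigma_c - n2 * sb) / n3
    return sigma_a, sigma_b, sigma_c


# -- parsimony by exhaustive internal-state assignment -----------------------

def brute_parsimony(tree: GeneTree, tip_states: dict[str, str]) -> int:
    """Minimum changes over all assignments of states to internal nodes."""
    states = sorted(set(tip_states.values()))
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        changes = 0

        def state_of(n):
            return tip_states[n.label] if n.is_leaf else assign[id(n)]

        for n in internals:
            for c in n.children:
                if state_of(c) != state_of(n):
                    changes += 1
        if best is None or changes < best:
            best = changes
    return best


def all_rooted_binary_trees(labels: list[str]):
    """Yield every rooted binary tree topology over the given tips."""
    if len(labels) == 1:
        yield Node(label=labels[0], length=1.0)
        return
    first, rest = labels[0], labels[1:]
    for sub in all_rooted_binary_trees(rest):
        # insert `first` on every edge (including above the root)
        for tree in _insertions(sub, first):
            yield tree


def _insertions(root: Node, label: str):
    import copy

    # above the root
    new = Node(length=1.0, children=[copy.deepcopy(root), Node(label=label, length=1.0)])
    yield new
    # on each edge below some node
    nodes = []

    def collect(n, path):
        nodes.append(path)
        for i, c in enumerate(n.children):
            collect(c, path + [i])

    collect(root, [])
    for path in nodes[1:]:  # skip the root itself (handled above)
        clone = copy.deepcopy(root)
        parent = clone
        for i in path[:-1]:
            parent = parent.children[i]
        child = parent.children[path[-1]]
        parent.children[path[-1]] = Node(
            length=1.0, children=[child, Node(label=label, length=1.0)]
        )
        yield clone


# -- minimum spanning trees by exhaustive enumeration ------------------------

def all_mst_edges(seqs: list[str]) -> set[frozenset]:
    """Union of edges over all spanning trees of minimum total weight."""
    import networkx as nx

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    nodes = sorted(set(seqs))
    edges = [(a, b, ham(a, b)) for a, b in itertools.combinations(nodes, 2)]
    best_w = None
    union: set[frozenset] = set()
    for combo in itertools.combinations(edges, len(nodes) - 1):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(combo)
        if not nx.is_connected(g):
            continue
        w = sum(e[2] for e in combo)
        if best_w is None or w < best_w:
            best_w = w
            union = {frozenset((a, b)) for a, b, _ in combo}
        elif w == best_w:
            union |= {frozenset((a, b)) for a, b, _ in combo}
    return union


# -- Stirling numbers by permutation cycle counting --------------------------

def stirling_by_cycle_count(n: int) -> dict[int, int]:
    """|S1(n,k)| = number of n-permutations with exactly k cycles."""
    counts: dict[int, int] = {}
    for perm in itertools.permutations(range(n)):
        seen = [False] * n
        cycles = 0
        for i in range(n):
            if not seen[i]:
                cycles += 1
                j = i
                while not seen[j]:
                    seen[j] = True
                    j = perm[j]
        counts[cycles] = counts.get(cycles, 0) + 1
    return counts
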