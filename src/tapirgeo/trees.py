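"""Gene trees: F84 pairwise distances, UPGMA, and newick round-tripping.

``GeneTree`` is a minimal rooted tree whose nodes carry a label, a branch
length to the parent, and an optional deme tag (used by the coalescent
simulator and the Slatkin-Maddison test). Newick parsing/serialisation is
delegated to dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .amova import DistanceMatrix
from .seq_io import InputError, SequenceAlignment


@dataclass
class Node:
    label: str | None = None
    length: float = 0.0  # branch length to parent
    deme: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """Rooted tree; branch-length unit recorded (substitutions/site or generations)."""

    def __init__(self, root: Node, unit: str = "substitutions/site"):
        self.root = root
        self.unit = unit

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def rec(n: Node) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def rec(n: Node) -> None:
            for c in n.children:
                rec(c)
            out.append(n)

        rec(self.root)
        return out

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths keyed by leaf label."""
        out: dict[str, float] = {}

        def rec(n: Node, d: float) -> None:
            if n.is_leaf:
                out[n.label] = d
            for c in n.children:
                rec(c, d + c.length)

        rec(self.root, 0.0)
        return out

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def resolve_polytomies(self, rng: np.random.Generator) -> "GeneTree":
        """Random binary resolution of polytomies (zero-length new branches)."""

        def rec(n: Node) -> Node:
            kids = [rec(c) for c in n.children]
            while len(kids) > 2:
                i, j = sorted(rng.choice(len(kids), size=2, replace=False))
                b = kids.pop(j)
                a = kids.pop(i)
                kids.append(Node(length=0.0, children=[a, b]))
            n.children = kids
            return n

        import copy

        return GeneTree(rec(copy.deepcopy(self.root)), unit=self.unit)

    # -- newick bridging ----------------------------------------------------

    def to_newick(self) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                return f"{n.label}:{n.length:g}"
            inner = ",".join(rec(c) for c in n.children)
            lab = n.label or ""
            return f"({inner}){lab}:{n.length:g}"

        return rec(self.root).rsplit(":", 1)[0] + ";"

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")


def read_newick(text_or_path: str, unit: str = "substitutions/site") -> GeneTree:
    """Parse newick text (or a path to a newick file) into a GeneTree."""
    text = text_or_path
    try:
        import os

        if os.path.exists(text_or_path):
            text = open(text_or_path).read()
    except (OSError, ValueError):
        pass
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"malformed newick: {exc}") from exc

    def rec(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        n = Node(
            label=label,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
        )
        n.children = [rec(c) for c in dnode.child_nodes()]
        return n

    return GeneTree(rec(dtree.seed_node), unit=unit)


def write_newick(tree: GeneTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# F84 distances
# ---------------------------------------------------------------------------

def f84_distance_pair(
    P: float, Q: float, freqs: dict[str, float]
) -> float:
    """Closed-form F84 maximum-likelihood distance.

    P and Q are the observed proportions of transition- and transversion-
    differing sites; freqs are the (empirical) base frequencies. Saturated
    pairs (non-positive log arguments) raise ``ValueError``.
    """
    pa, pc, pg, pt = (freqs[b] for b in "ACGT")
    pr, py = pa + pg, pc + pt
    A = pa * pg / pr + pc * pt / py
    B = pa * pg + pc * pt
    C = pr * py
    x = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    y = 1.0 - Q / (2.0 * C)
    if x <= 0.0 or y <= 0.0:
        raise ValueError("saturated pair: F84 distance undefined")
    return -2.0 * A * math.log(x) + 2.0 * (A - B - C) * math.log(y)


PURINES = set("AG")


def f84_distance(aln: SequenceAlignment) -> DistanceMatrix:
    """Pairwise F84 distances from pooled empirical base frequencies.

    Saturated pairs are flagged by substituting twice the largest finite
    distance in the matrix (documented fallback; NaN-free output so the
    matrix stays usable for clustering).
    """
    if aln.n < 2:
        raise InputError("need at least 2 sequences")
    cols = aln.retained_columns()
    mat = aln.matrix()[:, cols]
    total = mat.size
    freqs = {b: float((mat == b).sum()) / total for b in "ACGT"}
    n = aln.n
    out = np.zeros((n, n))
    saturated: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            diff = a != b
            both_pur = np.isin(a, ("A", "G")) & np.isin(b, ("A", "G"))
            both_pyr = np.isin(a, ("C", "T")) & np.isin(b, ("C", "T"))
            ti = int((diff & (both_pur | both_pyr)).sum())
            tv = int(diff.sum()) - ti
            P, Q = ti / len(cols), tv / len(cols)
            try:
                d = f84_distance_pair(P, Q, freqs)
            except ValueError:
                saturated.append((i, j))
                d = np.nan
            out[i, j] = out[j, i] = d
    if saturated:
        finite = out[np.isfinite(out)]
        stand_in = 2.0 * float(finite.max()) if finite.size else 1.0
        for i, j in saturated:
            out[i, j] = out[j, i] = stand_in
    return DistanceMatrix(aln.sample_ids, out)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dist: DistanceMatrix) -> GeneTree:
    """Average-linkage agglomeration into an ultrametric rooted tree.

    Ties in the minimum pair distance are broken by the lexicographically
    smallest (label_i, label_j) pair, making the output deterministic.
    """
    clusters: dict[str, tuple[Node, int, float]] = {}  # key -> (node, size, height)
    labels = list(dist.labels)
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        clusters[a] = (Node(label=a), 1, 0.0)
        for j in range(i + 1, len(labels)):
            b = labels[j]
            d[(a, b)] = d[(b, a)] = float(dist.matrix[i, j])

    active = sorted(labels)
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                key = (d[(a, b)], a, b)
                if best is None or key < best:
                    best = key
        dmin, a, b = best
        na, sa, ha = clusters[a]
        nb, sb, hb = clusters[b]
        h = dmin / 2.0
        na.length = h - ha
        nb.length = h - hb
        new_key = f"({a},{b})"
        merged = Node(children=[na, nb])
        clusters[new_key] = (merged, sa + sb, h)
        for c in active:
            if c in (a, b):
                continue
            d[(new_key, c)] = d[(c, new_key)] = (
                sa * d[(a, c)] + sb * d[(b, c)]
            ) / (sa + sb)
        active = sorted([c for c in active if c not in (a, b)] + [new_key])

    root = clusters[active[0]][0]
    root.length = 0.0
    return GeneTree(root, unit="substitutions/site")
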