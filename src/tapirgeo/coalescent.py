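"""Structured-coalescent gene-tree simulation on population trees.

The model is a haploid (mtDNA) coalescent without migration: within a
population of haploid effective size Ne, k lineages coalesce at rate
k(k-1)/(2 Ne) per generation; at a divergence time the lineage sets of the
daughter populations merge into the ancestral population. Branch lengths of
simulated gene trees are in generations and every tip carries the deme it
was sampled from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .seq_io import InputError
from .trees import GeneTree, Node


@dataclass
class PopNode:
    """One population (deme or ancestral) in a population tree.

    ``time`` is the generation (before present) at which this population
    comes into existence by the merger of its children; 0 for sampled tips.
    """

    name: str
    Ne: float
    time: float = 0.0
    n_samples: int = 0
    children: list["PopNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class PopulationTree:
    def __init__(self, root: PopNode):
        self.root = root
        self._validate(root)

    def _validate(self, node: PopNode) -> None:
        if node.Ne <= 0:
            raise InputError(f"population {node.name!r} has Ne <= 0")
        for c in node.children:
            if c.time >= node.time:
                raise InputError(
                    f"divergence times must increase root-ward: "
                    f"{c.name!r} at {c.time} under {node.name!r} at {node.time}"
                )
            self._validate(c)

    def tips(self) -> list[PopNode]:
        out: list[PopNode] = []

        def rec(n: PopNode) -> None:
            if n.is_tip:
                out.append(n)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    @property
    def total_samples(self) -> int:
        return sum(t.n_samples for t in self.tips())

    def with_sample_sizes(self, sizes: dict[str, int]) -> "PopulationTree":
        import copy

        root = copy.deepcopy(self.root)

        def rec(n: PopNode) -> None:
            if n.is_tip:
                n.n_samples = int(sizes.get(n.name, 0))
            for c in n.children:
                rec(c)

        rec(root)
        return PopulationTree(root)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def rec(n: PopNode) -> dict:
            d = {"name": n.name, "Ne": n.Ne, "time": n.time}
            if n.is_tip:
                d["n_samples"] = n.n_samples
            else:
                d["children"] = [rec(c) for c in n.children]
            return d

        return rec(self.root)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationTree":
        def rec(d: dict) -> PopNode:
            return PopNode(
                name=str(d["name"]),
                Ne=float(d["Ne"]),
                time=float(d.get("time", 0.0)),
                n_samples=int(d.get("n_samples", 0)),
                children=[rec(c) for c in d.get("children", [])],
            )

        return cls(rec(d))

    @classmethod
    def from_yaml(cls, text: str) -> "PopulationTree":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_newick(cls, text: str, default_ne: float = 1.0) -> "PopulationTree":
        """Parse an annotated newick where node comments carry ``[&Ne=...]``.

        Branch lengths are in generations; divergence times are recovered by
        assuming tips are at time 0 (ultrametric population history).
        """
        import dendropy

        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=False,
                extract_comment_metadata=False,
            )
        except Exception as exc:
            raise InputError(f"malformed newick: {exc}") from exc

        def ne_of(dnode) -> float:
            for comment in dnode.comments or []:
                token = comment.lstrip("&")
                for part in token.split(","):
                    if part.strip().lower().startswith("ne="):
                        return float(part.strip()[3:])
            return default_ne

        # compute node heights above the tips
        def height(dnode) -> float:
            if dnode.is_leaf():
                return 0.0
            c = dnode.child_nodes()[0]
            return height(c) + float(c.edge.length or 0.0)

        counter = [0]

        def rec(dnode) -> PopNode:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            else:
                counter[0] += 1
                name = f"anc{counter[0]}"
            return PopNode(
                name=name,
                Ne=ne_of(dnode),
                time=height(dnode),
                children=[rec(c) for c in dnode.child_nodes()],
            )

        return cls(rec(tree.seed_node))


def simultaneous_split_tree(
    demes: dict[str, int], tau: float, Ne: float, ancestral_ne: float | None = None
) -> PopulationTree:
    """K-way simultaneous split at ``tau`` generations before present.

    Models allopatric fragmentation: every sampled deme diverged from the
    common ancestral population at the same time, with no migration since.
    """
    tips = [
        PopNode(name=d, Ne=Ne, time=0.0, n_samples=n) for d, n in sorted(demes.items())
    ]
    root = PopNode(
        name="ancestral",
        Ne=ancestral_ne if ancestral_ne is not None else Ne,
        time=tau,
        children=tips,
    )
    return PopulationTree(root)


def _coalesce_within(
    lineages: list[tuple[Node, float]],
    Ne: float,
    t_start: float,
    t_end: float | None,
    rng: np.random.Generator,
) -> tuple[list[tuple[Node, float]], float]:
    """Coalesce lineages in one population from t_start until t_end (or MRCA).

    ``lineages`` holds (subtree root, height) pairs; returns survivors and
    the time reached.
    """
    t = t_start
    lin = list(lineages)
    while len(lin) > 1:
        k = len(lin)
        rate = k * (k - 1) / (2.0 * Ne)
        wait = rng.exponential(1.0 / rate)
        if t_end is not None and t + wait > t_end:
            return lin, t_end
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lin.pop(j)
        a = lin.pop(i)
        a[0].length = t - a[1]
        b[0].length = t - b[1]
        lin.append((Node(children=[a[0], b[0]]), t))
    return lin, t if t_end is None else t_end


def simulate_gene_tree(ptree: PopulationTree, seed=None) -> GeneTree:
    """One gene tree under the structured coalescent without migration."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = ptree.total_samples
    if total < 1:
        raise InputError("no samples to simulate")

    def rec(pop: PopNode) -> list[tuple[Node, float]]:
        if pop.is_tip:
            lin = [
                (Node(label=f"{pop.name}_{i+1}", deme=pop.name), 0.0)
                for i in range(pop.n_samples)
            ]
            start = 0.0
        else:
            lin = []
            for c in pop.children:
                lin.extend(rec(c))
            start = pop.time
        parent_time = _parent_time.get(id(pop))
        survivors, _ = _coalesce_within(lin, pop.Ne, start, parent_time, rng)
        return survivors

    _parent_time: dict[int, float | None] = {id(ptree.root): None}

    def note_parents(pop: PopNode) -> None:
        for c in pop.children:
            _parent_time[id(c)] = pop.time
            note_parents(c)

    note_parents(ptree.root)
    survivors = rec(ptree.root)
    assert len(survivors) == 1
    root = survivors[0][0]
    root.length = 0.0
    return GeneTree(root, unit="generations")
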