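"""Slatkin-Maddison s and coalescent hypothesis testing.

s is the minimum number of state changes of the (unordered) deme character
over a gene tree — a parsimony count of inter-deme transfer events. Under a
population-history null hypothesis, gene trees are simulated with the
structured coalescent and the observed s is compared against the simulated
null distribution: an observed s far below the null (fewer apparent
migration/sorting events than pure allopatric fragmentation predicts)
rejects the null in favour of a history whose groupings track the genealogy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coalescent import PopulationTree, simulate_gene_tree
from .seq_io import InputError
from .trees import GeneTree


@dataclass
class SMTestResult:
    s_observed: int | None
    null_s: list[int]
    mean_s: float
    ci99: tuple[int, int]
    p: float | None
    scenario: dict

    def summary_row(self) -> dict:
        row = dict(self.scenario)
        row.update(
            mean_s=self.mean_s,
            ci99_low=self.ci99[0],
            ci99_high=self.ci99[1],
            s_observed=self.s_observed,
            p=self.p,
        )
        return row


def fitch_changes(tree: GeneTree, tip_states: dict[str, str]) -> int:
    """Minimum state changes of an unordered character (Fitch bottom-up)."""
    count = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label in tip_states:
                state = tip_states[node.label]
            elif node.deme is not None and node.deme in tip_states:
                state = tip_states[node.deme]
            else:
                raise InputError(f"no state for tip {node.label!r}")
            sets[id(node)] = frozenset([state])
        else:
            acc = None
            for c in node.children:
                s = sets[id(c)]
                if acc is None:
                    acc = s
                else:
                    inter = acc & s
                    if inter:
                        acc = inter
                    else:
                        acc = acc | s
                        count += 1
            sets[id(node)] = acc
    return count


def slatkin_maddison_s(
    tree: GeneTree,
    tip_states: dict[str, str],
    seed: int | None = None,
    resolutions: int = 10,
) -> int:
    """Slatkin-Maddison s: Fitch change count of the deme character.

    Non-binary trees are resolved randomly ``resolutions`` times (seeded)
    and the minimum count over resolutions is reported, since a polytomy's
    parsimony length is the minimum over its binary refinements.
    """
    for leaf in tree.leaves():
        if leaf.label not in tip_states and (
            leaf.deme is None or leaf.deme not in tip_states
        ):
            raise InputError(f"unlabeled tip: {leaf.label!r}")
    if tree.is_binary():
        return fitch_changes(tree, tip_states)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(resolutions):
        resolved = tree.resolve_polytomies(rng)
        c = fitch_changes(resolved, tip_states)
        best = c if best is None else min(best, c)
    return best


def sm_hypothesis_test(
    null_ptree: PopulationTree,
    alt_grouping: dict[str, str],
    reps: int = 1000,
    seed: int | None = None,
    s_observed: int | None = None,
    scenario: dict | None = None,
) -> SMTestResult:
    """Null distribution of s under a population-tree hypothesis.

    ``alt_grouping`` maps each deme of ``null_ptree`` to the character state
    it carries under the alternative hypothesis (for the study design the
    states are the four geographic regions). ``s_observed``, if given, is
    tested against the lower tail: p = P(null s <= observed).
    """
    if reps < 100:
        warnings.warn("fewer than 100 replicates gives a coarse null", stacklevel=2)
    tip_demes = {t.name for t in null_ptree.tips() if t.n_samples > 0}
    missing = tip_demes - set(alt_grouping)
    if missing:
        raise InputError(f"alt grouping missing states for demes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    null_s: list[int] = []
    for _ in range(reps):
        gt = simulate_gene_tree(null_ptree, rng)
        states = {leaf.label: alt_grouping[leaf.deme] for leaf in gt.leaves()}
        null_s.append(fitch_changes(gt, states))
    arr = np.array(null_s)
    lo = int(np.percentile(arr, 0.5, method="lower"))
    hi = int(np.percentile(arr, 99.5, method="higher"))
    p = None
    if s_observed is not None:
        p = float((arr <= s_observed).sum() + 1) / (reps + 1)
    return SMTestResult(
        s_observed=s_observed,
        null_s=null_s,
        mean_s=float(arr.mean()),
        ci99=(lo, hi),
        p=p,
        scenario=scenario or {},
    )


def run_scenarios(
    grid: list[tuple[float, float]],
    make_null_ptree,
    alt_grouping: dict[str, str],
    reps: int = 1000,
    seed: int | None = None,
    s_observed: int | None = None,
) -> list[SMTestResult]:
    """Cross-product execution over (generations, Ne) scenarios.

    ``make_null_ptree(generations, Ne)`` builds the null population tree for
    one grid cell; rows come back in input order.
    """
    rng = np.random.default_rng(seed)
    results = []
    for generations, ne in grid:
        ptree = make_null_ptree(generations, ne)
        res = sm_hypothesis_test(
            ptree,
            alt_grouping,
            reps=reps,
            seed=int(rng.integers(2**31 - 1)),
            s_observed=s_observed,
            scenario={"generations": generations, "Ne": ne},
        )
        results.append(res)
    return results
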