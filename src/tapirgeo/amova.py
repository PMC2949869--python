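"""Analysis of molecular variance (AMOVA), pairwise Phi, and SAMOVA.

AMOVA partitions the total molecular variance of a set of haploid sequences
into among-group (sigma2_a), among-population-within-group (sigma2_b) and
within-population (sigma2_c) components, estimated by equating observed
mean squared deviations — computed from pairwise squared distances — to
their expectations (Excoffier, Smouse & Quattro 1992). The fixation indices

    Phi_CT = sigma2_a / sigma2_T
    Phi_SC = sigma2_b / (sigma2_b + sigma2_c)
    Phi_ST = (sigma2_a + sigma2_b) / sigma2_T

are tested by permutation, each with its own resampling scheme.

SAMOVA searches, by simulated annealing over geographically contiguous
partitions of sampling sites into K groups, for the partition maximising
Phi_CT (Dupanloup, Schneider & Excoffier 2002). Contiguity is enforced on a
Delaunay triangulation of the site coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .seq_io import HaplotypeTable, InputError


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise InputError("distance matrix not symmetric")
        if np.diag(m).any():
            raise InputError("distance matrix diagonal not zero")
        if (m < 0).any():
            raise InputError("negative distances")
        self.matrix = m

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class AmovaResult:
    sigma2_a: float | None  # among groups
    sigma2_b: float | None  # among populations within groups
    sigma2_c: float  # within populations
    phi_CT: float | None
    phi_SC: float | None
    phi_ST: float | None
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None
    df: dict = field(default_factory=dict)

    @property
    def sigma2_total(self) -> float:
        return (self.sigma2_a or 0.0) + (self.sigma2_b or 0.0) + self.sigma2_c

    @property
    def percent_variation(self) -> dict[str, float]:
        tot = self.sigma2_total
        return {
            "among_groups": 100.0 * (self.sigma2_a or 0.0) / tot,
            "among_pops_within_groups": 100.0 * (self.sigma2_b or 0.0) / tot,
            "within_pops": 100.0 * self.sigma2_c / tot,
        }


@dataclass
class SamovaResult:
    K: int
    partition: dict[str, int]  # site_id -> group index
    phi_CT: float
    p_value: float | None
    trace: list[float]  # best Phi_CT per restart


def pairwise_difference_matrix(haps: HaplotypeTable) -> DistanceMatrix:
    """Sample-by-sample Hamming distances, expanded from the haplotype table.

    Sample order follows the recorded haplotype membership lists when
    available, otherwise samples are synthesised as hapid.k replicates.
    """
    seqs = []
    labels = []
    arrs = {h: np.frombuffer(s.encode(), dtype="S1") for h, s in haps.haplotypes}
    for (hap_id, _), c in zip(haps.haplotypes, haps.total_counts):
        names = haps.members.get(hap_id) or [f"{hap_id}.{k}" for k in range(int(c))]
        for name in names:
            labels.append(name)
            seqs.append(arrs[hap_id])
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float((seqs[i] != seqs[j]).sum())
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def _components(
    d2: np.ndarray, groups: list[list[np.ndarray]]
) -> AmovaResult:
    """Excoffier variance components from squared distances.

    ``groups`` is a nested structure: per group, a list of per-population
    index arrays into ``d2``.
    """
    pops = [p for g in groups for p in g]
    N = sum(len(p) for p in pops)
    G = len(groups)
    P = len(pops)

    def ssd(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return float(sub.sum()) / (2.0 * len(idx))

    all_idx = np.concatenate(pops)
    ssd_total = ssd(all_idx)
    ssd_wp = sum(ssd(p) for p in pops)
    ssd_wg = sum(ssd(np.concatenate(g)) for g in groups)
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0

    n_sizes = np.array([len(p) for p in pops], dtype=float)
    g_sizes = np.array([sum(len(p) for p in g) for g in groups], dtype=float)
    sum_npg = sum(
        sum(len(p) ** 2 for p in g) / sum(len(p) for p in g) for g in groups
    )

    if df_ap > 0:
        n_prime = (N - sum_npg) / df_ap
        ms_ap = ssd_ap_wg / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime
    else:
        sigma_b = None

    if df_ag > 0:
        n2_prime = (sum_npg - float((n_sizes**2).sum()) / N) / df_ag
        n3_prime = (N - float((g_sizes**2).sum()) / N) / df_ag
        ms_ag = ssd_ag / df_ag
        sb = sigma_b if sigma_b is not None else 0.0
        sigma_a = (ms_ag - sigma_c - n2_prime * sb) / n3_prime
    else:
        sigma_a = None

    tot = (sigma_a or 0.0) + (sigma_b or 0.0) + sigma_c
    if tot == 0.0:
        raise InputError("total molecular variance is zero; Phi undefined")
    phi_ct = sigma_a / tot if sigma_a is not None else None
    phi_sc = (
        sigma_b / (sigma_b + sigma_c)
        if sigma_b is not None and (sigma_b + sigma_c) != 0
        else None
    )
    if sigma_a is not None and sigma_b is not None:
        phi_st = (sigma_a + sigma_b) / tot
    elif sigma_b is not None:  # single level: among populations
        phi_st = sigma_b / tot
    elif sigma_a is not None:
        phi_st = sigma_a / tot
    else:
        phi_st = None
    return AmovaResult(
        sigma_a,
        sigma_b,
        sigma_c,
        phi_ct,
        phi_sc,
        phi_st,
        df={"among_groups": df_ag, "among_pops": df_ap, "within_pops": df_wp},
    )


def _resolve_partition(
    dist: DistanceMatrix, partition: dict[str, dict[str, list[str]]]
) -> list[list[np.ndarray]]:
    index = {lab: i for i, lab in enumerate(dist.labels)}
    seen: set[str] = set()
    groups = []
    for gname in sorted(partition):
        g = []
        for pname in sorted(partition[gname]):
            samples = partition[gname][pname]
            for s in samples:
                if s in seen:
                    raise InputError(f"sample {s!r} assigned twice")
                if s not in index:
                    raise InputError(f"sample {s!r} not in distance matrix")
                seen.add(s)
            g.append(np.array([index[s] for s in samples], dtype=int))
        groups.append(g)
    return groups


def amova(
    dist: DistanceMatrix,
    partition: dict[str, dict[str, list[str]]],
    permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on a group -> population -> samples partition.

    Permutation schemes (each statistic has its own null):
      Phi_ST — permute samples among populations (ignoring groups);
      Phi_SC — permute samples among populations within their group;
      Phi_CT — permute whole populations among groups.
    p = (#{permuted >= observed} + 1) / (permutations + 1).
    """
    d2 = dist.matrix**2
    groups = _resolve_partition(dist, partition)
    obs = _components(d2, groups)
    if permutations <= 0:
        return obs

    rng = np.random.default_rng(seed)
    pops = [p for g in groups for p in g]
    pop_sizes = [len(p) for p in pops]
    pops_per_group = [len(g) for g in groups]
    all_idx = np.concatenate(pops)

    def split_pops(flat: np.ndarray) -> list[np.ndarray]:
        out, ofs = [], 0
        for s in pop_sizes:
            out.append(flat[ofs : ofs + s])
            ofs += s
        return out

    ge_st = ge_sc = ge_ct = 0
    n_st = n_sc = n_ct = 0
    for _ in range(permutations):
        # Phi_ST: samples among populations
        if obs.phi_ST is not None:
            perm = rng.permutation(all_idx)
            new_pops = split_pops(perm)
            newg, ofs = [], 0
            for npop in pops_per_group:
                newg.append(new_pops[ofs : ofs + npop])
                ofs += npop
            try:
                r = _components(d2, newg)
                if r.phi_ST is not None and r.phi_ST >= obs.phi_ST - 1e-12:
                    ge_st += 1
                n_st += 1
            except InputError:
                pass
        # Phi_SC: samples among populations within groups
        if obs.phi_SC is not None:
            newg = []
            for g in groups:
                flat = rng.permutation(np.concatenate(g))
                out, ofs = [], 0
                for p in g:
                    out.append(flat[ofs : ofs + len(p)])
                    ofs += len(p)
                newg.append(out)
            try:
                r = _components(d2, newg)
                if r.phi_SC is not None and r.phi_SC >= obs.phi_SC - 1e-12:
                    ge_sc += 1
                n_sc += 1
            except InputError:
                pass
        # Phi_CT: whole populations among groups
        if obs.phi_CT is not None:
            order = rng.permutation(len(pops))
            newg, ofs = [], 0
            for npop in pops_per_group:
                newg.append([pops[k] for k in order[ofs : ofs + npop]])
                ofs += npop
            try:
                r = _components(d2, newg)
                if r.phi_CT is not None and r.phi_CT >= obs.phi_CT - 1e-12:
                    ge_ct += 1
                n_ct += 1
            except InputError:
                pass
    obs.p_ST = (ge_st + 1) / (n_st + 1) if obs.phi_ST is not None else None
    obs.p_SC = (ge_sc + 1) / (n_sc + 1) if obs.phi_SC is not None else None
    obs.p_CT = (ge_ct + 1) / (n_ct + 1) if obs.phi_CT is not None else None
    return obs


def pairwise_phi(
    dist: DistanceMatrix,
    demes: dict[str, list[str]],
    permutations: int = 1000,
    seed: int | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Phi_ST and permutation p for every pair of demes.

    Returns (deme_names, phi_matrix, p_matrix); Phi may be negative and is
    reported unclamped.
    """
    names = sorted(demes)
    k = len(names)
    phi = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            part = {
                "all": {names[i]: demes[names[i]], names[j]: demes[names[j]]}
            }
            sub_seed = int(rng.integers(2**31 - 1))
            try:
                res = amova(dist, part, permutations=permutations, seed=sub_seed)
                phi[i, j] = phi[j, i] = res.phi_ST
                pval[i, j] = pval[j, i] = res.p_ST
            except InputError:
                phi[i, j] = phi[j, i] = np.nan
    return names, phi, pval


# ---------------------------------------------------------------------------
# SAMOVA
# ---------------------------------------------------------------------------

def delaunay_adjacency(coords: dict[str, tuple[float, float]]) -> dict[str, set[str]]:
    """Neighbour sets from a planar Delaunay triangulation of site coordinates.

    Degenerate inputs (fewer than 4 sites or collinear sites) fall back to a
    complete graph.
    """
    names = sorted(coords)
    pts = np.array([coords[s] for s in names], dtype=float)
    adj: dict[str, set[str]] = {s: set() for s in names}
    try:
        if len(names) < 4:
            raise ValueError("too few sites for triangulation")
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for a in simplex:
                for b in simplex:
                    if a != b:
                        adj[names[a]].add(names[b])
    except Exception:
        for a in names:
            adj[a] = set(names) - {a}
    return adj


def _connected(sites: list[str], adj: dict[str, set[str]]) -> bool:
    if not sites:
        return False
    todo, seen, pool = [sites[0]], {sites[0]}, set(sites)
    while todo:
        s = todo.pop()
        for t in adj[s] & pool:
            if t not in seen:
                seen.add(t)
                todo.append(t)
    return len(seen) == len(pool)


class _PhiCTEvaluator:
    """Fast Phi_CT over groupings of fixed demes, via precomputed pair sums.

    For a grouping, SSD terms reduce to sums over per-deme-pair totals of
    squared distances, so each candidate partition costs O(D^2) instead of
    O(N^2).
    """

    def __init__(self, dist: DistanceMatrix, demes: dict[str, list[str]]):
        self.names = sorted(demes)
        index = {lab: i for i, lab in enumerate(dist.labels)}
        d2 = dist.matrix**2
        idx = {s: np.array([index[x] for x in demes[s]], dtype=int) for s in self.names}
        D = len(self.names)
        self.sizes = np.array([len(idx[s]) for s in self.names], dtype=float)
        self.W = np.zeros((D, D))  # full double-sum of d^2 between deme pairs
        for a in range(D):
            for b in range(D):
                self.W[a, b] = d2[np.ix_(idx[self.names[a]], idx[self.names[b]])].sum()
        self.N = float(self.sizes.sum())
        self.ssd_total = self.W.sum() / (2.0 * self.N)
        self.ssd_wp = sum(self.W[a, a] / (2.0 * self.sizes[a]) for a in range(D))
        self.P = D

    def phi_ct(self, assignment: np.ndarray) -> float:
        """assignment: per-deme group index, 0..K-1 (all groups non-empty)."""
        K = int(assignment.max()) + 1
        ssd_wg = 0.0
        g_sizes = np.zeros(K)
        sum_npg = 0.0
        for g in range(K):
            sel = np.flatnonzero(assignment == g)
            ng = self.sizes[sel].sum()
            g_sizes[g] = ng
            ssd_wg += self.W[np.ix_(sel, sel)].sum() / (2.0 * ng)
            sum_npg += (self.sizes[sel] ** 2).sum() / ng
        ssd_ap = ssd_wg - self.ssd_wp
        ssd_ag = self.ssd_total - ssd_wg
        df_wp = self.N - self.P
        df_ap = self.P - K
        df_ag = K - 1
        sigma_c = self.ssd_wp / df_wp if df_wp > 0 else 0.0
        if df_ap > 0:
            n_prime = (self.N - sum_npg) / df_ap
            sigma_b = (ssd_ap / df_ap - sigma_c) / n_prime
        else:
            sigma_b = 0.0
        n2 = (sum_npg - (self.sizes**2).sum() / self.N) / df_ag
        n3 = (self.N - (g_sizes**2).sum() / self.N) / df_ag
        sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
        tot = sigma_a + sigma_b + sigma_c
        if tot == 0:
            return -np.inf
        return sigma_a / tot


def _random_contiguous_partition(
    names: list[str], adj: dict[str, set[str]], K: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow K connected groups from random seeds (region-growing)."""
    D = len(names)
    pos = {s: i for i, s in enumerate(names)}
    assignment = np.full(D, -1, dtype=int)
    seeds = rng.choice(D, size=K, replace=False)
    frontier: list[list[str]] = [[] for _ in range(K)]
    for g, s in enumerate(seeds):
        assignment[s] = g
        frontier[g] = [names[s]]
    unassigned = D - K
    while unassigned > 0:
        order = rng.permutation(K)
        progressed = False
        for g in order:
            cands = [
                t
                for s in frontier[g]
                for t in adj[s]
                if assignment[pos[t]] == -1
            ]
            if not cands:
                continue
            t = cands[int(rng.integers(len(cands)))]
            assignment[pos[t]] = g
            frontier[g].append(t)
            unassigned -= 1
            progressed = True
            if unassigned == 0:
                break
        if not progressed:
            # disconnected leftovers (shouldn't happen on a triangulation):
            # dump remaining sites into nearest group by adjacency-blind choice
            for i in range(D):
                if assignment[i] == -1:
                    assignment[i] = int(rng.integers(K))
                    unassigned -= 1
    return assignment


def samova(
    dist: DistanceMatrix,
    demes: dict[str, list[str]],
    coords: dict[str, tuple[float, float]],
    K: int,
    restarts: int = 100,
    seed: int | None = None,
    permutations: int = 1000,
    t0: float = 1.0,
    cooling: float = 0.9,
    moves_per_temp: int = 10,
    t_min: float = 1e-3,
) -> SamovaResult:
    """Simulated-annealing search for the contiguous K-partition maximising Phi_CT.

    ``restarts`` independent annealing chains are run (geometric cooling
    from ``t0`` by ``cooling`` with ``moves_per_temp`` proposals per
    temperature until ``t_min``); a proposal moves one site to a
    neighbouring group, accepted when it keeps both groups connected and
    non-empty, with Metropolis acceptance on -Phi_CT. The best final
    partition over all chains is returned, with a population-permutation p.
    """
    names = sorted(demes)
    D = len(names)
    if not (2 <= K <= D):
        raise InputError(f"K={K} must be between 2 and the number of demes ({D})")
    missing = set(names) - set(coords)
    if missing:
        raise InputError(f"no coordinates for sites: {sorted(missing)}")
    adj = delaunay_adjacency({s: coords[s] for s in names})
    ev = _PhiCTEvaluator(dist, demes)
    pos = {s: i for i, s in enumerate(names)}
    rng = np.random.default_rng(seed)

    best_assign: np.ndarray | None = None
    best_phi = -np.inf
    trace: list[float] = []

    for _ in range(restarts):
        assign = _random_contiguous_partition(names, adj, K, rng)
        phi = ev.phi_ct(assign)
        cur_best, cur_best_assign = phi, assign.copy()
        T = t0
        while T > t_min:
            for _ in range(moves_per_temp):
                i = int(rng.integers(D))
                g_from = assign[i]
                if (assign == g_from).sum() <= 1:
                    continue
                neigh_groups = {
                    assign[pos[t]] for t in adj[names[i]] if assign[pos[t]] != g_from
                }
                if not neigh_groups:
                    continue
                g_to = list(sorted(neigh_groups))[int(rng.integers(len(neigh_groups)))]
                new = assign.copy()
                new[i] = g_to
                donor = [names[j] for j in np.flatnonzero(new == g_from)]
                if not _connected(donor, adj):
                    continue
                new_phi = ev.phi_ct(new)
                if new_phi >= phi or rng.random() < math.exp((new_phi - phi) / T):
                    assign, phi = new, new_phi
                    if phi > cur_best:
                        cur_best, cur_best_assign = phi, assign.copy()
            T *= cooling
        trace.append(cur_best)
        if cur_best > best_phi:
            best_phi, best_assign = cur_best, cur_best_assign

    # canonicalise group numbering by first occurrence
    remap: dict[int, int] = {}
    canon = np.empty_like(best_assign)
    for i, g in enumerate(best_assign):
        if g not in remap:
            remap[g] = len(remap)
        canon[i] = remap[g]
    partition = {names[i]: int(canon[i]) for i in range(D)}

    p_value = None
    if permutations > 0:
        part_spec = {
            f"G{g}": {s: demes[s] for s in names if partition[s] == g}
            for g in range(K)
        }
        res = amova(
            dist,
            part_spec,
            permutations=permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        p_value = res.p_CT
    return SamovaResult(K, partition, float(best_phi), p_value, trace)
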