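"""Tajima's D and Fu's Fs with coalescent-simulated significance.

Both statistics test the standard neutral model of constant population size.
Tajima's D contrasts two estimators of theta (from pairwise differences and
from segregating sites); Fu's Fs asks whether the observed number of
distinct haplotypes is improbably large given theta, via the Ewens sampling
distribution. Significant negative values of either indicate an excess of
rare variants / haplotypes, the signature of recent population expansion.

Null distributions are obtained by simulating constant-size neutral
coalescent genealogies conditioned on theta = k_bar (the Arlequin
convention), dropping infinite-sites mutations on the branches, and
recomputing both statistics; p-values are the lower-tail fraction of
simulated values at or below the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seq_io import HaplotypeTable, InputError


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class NeutralityStats:
    group: str
    n: int
    S: int
    k_bar: float
    k_obs: int
    D: float | None
    Fs: float | None
    p_D: float | None
    p_Fs: float | None
    testable: bool
    reps: int = 0


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(S: int, k_bar: float, n: int) -> float:
    """Tajima's D from segregating sites S and mean pairwise difference k_bar."""
    if n < 4:
        raise InputError("Tajima's D requires n >= 4")
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k_bar - S / c["a1"]) / math.sqrt(var)


def log_stirling1_row(n: int) -> np.ndarray:
    """log |S1(n, k)| for k = 0..n (unsigned first-kind Stirling numbers).

    Recursion |S1(n,k)| = |S1(n-1,k-1)| + (n-1)|S1(n-1,k)| carried in
    log-space, stable to n of several hundred.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S1(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        if m > 1:
            new[1:] = np.logaddexp(row[:-1], math.log(m - 1) + row[1:])
        else:
            new[1:] = row[:-1]
        row = new
    return row


def ewens_k_tail(k_obs: int, theta: float, n: int) -> float:
    """S' = P(K >= k_obs) under the Ewens sampling distribution.

    P(K = k) = |S1(n,k)| theta^k / theta^(n) with rising factorial
    theta^(n) = theta (theta+1) ... (theta+n-1); evaluated in log-space.
    """
    if theta <= 0:
        raise UndefinedStatisticError("theta must be positive")
    ls1 = log_stirling1_row(n)
    log_theta = math.log(theta)
    log_rising = float(sum(math.log(theta + i) for i in range(n)))
    ks = np.arange(1, n + 1)
    logp = ls1[1:] + ks * log_theta - log_rising
    # normalise defensively against accumulated rounding
    logZ = float(np.logaddexp.reduce(logp))
    logp = logp - logZ
    tail = float(np.exp(np.logaddexp.reduce(logp[k_obs - 1 :])))
    return min(tail, 1.0)


def fus_fs(k_obs: int, theta: float, n: int) -> float:
    """Fu's Fs = ln(S' / (1 - S')) with S' = P(K >= k_obs | theta, n)."""
    if n < 2:
        raise InputError("Fu's Fs requires n >= 2")
    if k_obs < 2:
        raise UndefinedStatisticError("Fs undefined for monomorphic samples")
    sp = ewens_k_tail(k_obs, theta, n)
    if sp <= 0.0 or sp >= 1.0:
        raise UndefinedStatisticError("S' degenerate (0 or 1)")
    return math.log(sp / (1.0 - sp))


# ---------------------------------------------------------------------------
# neutral coalescent simulation of (S, k_bar, k_obs) given theta
# ---------------------------------------------------------------------------

def simulate_neutral_summaries(
    n: int, theta: float, reps: int, rng: np.random.Generator
) -> list[tuple[int, float, int]]:
    """Simulate (S, k_bar, K) under the constant-size neutral coalescent.

    Time is in coalescent units; mutations are infinite-sites with rate
    theta/2 per lineage per unit time. Haplotype identity is tracked as the
    mutation set carried by each tip.
    """
    out = []
    for _ in range(reps):
        # genealogy: standard n-coalescent
        active = list(range(n))
        sets = {i: {i} for i in range(n)}  # lineage -> tip descendants
        muts: dict[int, set[int]] = {i: set() for i in range(n)}  # tip -> mutations
        next_mut = 0
        k = n
        while k > 1:
            rate = k * (k - 1) / 2.0
            t = rng.exponential(1.0 / rate)
            # mutations on each of the k branches during t
            for lin in active:
                m = rng.poisson(theta / 2.0 * t)
                if m:
                    ids = range(next_mut, next_mut + m)
                    next_mut += m
                    for tip in sets[lin]:
                        muts[tip].update(ids)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            merged = sets[a] | sets[b]
            active = [x for x in active if x not in (a, b)]
            new_id = max(sets) + 1
            sets[new_id] = merged
            active.append(new_id)
            k -= 1
        all_muts = set().union(*muts.values()) if muts else set()
        S = len(all_muts)
        # pairwise differences via symmetric set difference
        kbar = 0.0
        tips = list(muts.values())
        for i in range(n):
            for j in range(i + 1, n):
                kbar += len(tips[i] ^ tips[j])
        kbar /= n * (n - 1) / 2.0
        K = len({frozenset(m) for m in tips})
        out.append((S, kbar, K))
    return out


def neutrality_test(
    haps: HaplotypeTable,
    S: int,
    group: str = "all",
    reps: int = 1000,
    seed: int | None = None,
) -> NeutralityStats:
    """Observed D and Fs with simulated lower-tail p-values.

    Returns a structured not-testable result (D, Fs, p both None) when the
    group is monomorphic or too small, mirroring how summary tables print
    "-" for such groups.
    """
    n = haps.n
    k_bar = 0.0
    if n >= 2:
        from .diversity import mean_pairwise_difference

        k_bar = mean_pairwise_difference(haps)
    k_obs = len(haps.haplotypes)
    if n < 4 or S < 1 or k_obs < 2:
        return NeutralityStats(group, n, S, k_bar, k_obs, None, None, None, None, False)
    D = tajimas_d(S, k_bar, n)
    Fs = fus_fs(k_obs, k_bar, n)
    rng = np.random.default_rng(seed)
    sims = simulate_neutral_summaries(n, k_bar, reps, rng)
    d_null, fs_null = [], []
    for Ssim, kbar_sim, Ksim in sims:
        if Ssim >= 1:
            d_null.append(tajimas_d(Ssim, kbar_sim, n))
        if Ksim >= 2:
            try:
                fs_null.append(fus_fs(Ksim, kbar_sim if kbar_sim > 0 else 1e-9, n))
            except UndefinedStatisticError:
                pass
    p_D = (sum(1 for d in d_null if d <= D) + 1) / (len(d_null) + 1) if d_null else None
    p_Fs = (
        (sum(1 for f in fs_null if f <= Fs) + 1) / (len(fs_null) + 1)
        if fs_null
        else None
    )
    return NeutralityStats(group, n, S, k_bar, k_obs, D, Fs, p_D, p_Fs, True, reps)
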