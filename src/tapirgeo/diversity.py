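"""Gene (haplotype) diversity and nucleotide diversity.

Gene diversity Hd is Nei's unbiased estimator

    Hd = n/(n-1) * (1 - sum_i p_i^2)

the probability that two sequences drawn without replacement carry different
haplotypes. Nucleotide diversity pi is the mean per-site Hamming distance
over all sample pairs (no multiple-hit correction), computed on the columns
retained after complete deletion. Standard deviations follow Nei (1987):
eq. 8.12 for Hd and eq. 10.7 (total variance, including the stochastic
coalescent term) for pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seq_io import HaplotypeTable, InputError, PopulationMap, SequenceAlignment


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given sample."""


@dataclass
class DiversityStats:
    group: str
    n: int
    L: int
    H_d: float | None  # None when undefined (n < 2)
    H_d_sd: float | None
    pi: float
    pi_sd: float
    k_bar: float

    @property
    def k_bar_pct(self) -> float:
        return 100.0 * self.k_bar / self.L if self.L else 0.0


def gene_diversity(counts) -> tuple[float, float]:
    """Nei's unbiased gene diversity and its standard deviation.

    ``counts`` is the haplotype frequency spectrum (one count per haplotype).
    """
    counts = np.asarray(list(counts), dtype=float)
    if (counts < 0).any():
        raise InputError("negative haplotype count")
    n = counts.sum()
    if n < 2:
        raise UndefinedStatisticError("gene diversity requires n >= 2")
    p = counts / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    h = n / (n - 1.0) * (1.0 - sum2)
    # Nei 1987, eq. 8.12
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return h, math.sqrt(max(var, 0.0))


def mean_pairwise_difference(haps: HaplotypeTable) -> float:
    """k_bar: mean Hamming distance over all C(n,2) sample pairs."""
    n = haps.n
    if n < 2:
        raise UndefinedStatisticError("pairwise difference requires n >= 2")
    counts = haps.total_counts
    seqs = [np.frombuffer(s.encode(), dtype="S1") for _, s in haps.haplotypes]
    total = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = int((seqs[i] != seqs[j]).sum())
            total += counts[i] * counts[j] * d
    return total / (n * (n - 1) / 2.0)


def nucleotide_diversity(haps: HaplotypeTable, L: int | None = None) -> tuple[float, float, float]:
    """(pi, sd, k_bar) for a haplotype table.

    ``L`` defaults to the retained-column count of the haplotype sequences.
    """
    if L is None:
        L = haps.length
    if L <= 0:
        raise InputError("alignment has no retained sites")
    n = haps.n
    k_bar = mean_pairwise_difference(haps)
    pi = k_bar / L
    # Nei 1987, eq. 10.7: total variance of pi
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0)), k_bar


def diversity_stats(haps: HaplotypeTable, group: str = "all", L: int | None = None) -> DiversityStats:
    """Full DiversityStats for one pooled sample; handles n=1 degeneracy."""
    if L is None:
        L = haps.length
    n = haps.n
    if n < 2:
        return DiversityStats(group, n, L, None, None, 0.0, 0.0, 0.0)
    hd, hd_sd = gene_diversity(haps.total_counts)
    pi, pi_sd, k_bar = nucleotide_diversity(haps, L)
    return DiversityStats(group, n, L, hd, hd_sd, pi, pi_sd, k_bar)


def diversity_by_grouping(
    aln: SequenceAlignment,
    popmap: PopulationMap,
    scheme: str,
) -> list[DiversityStats]:
    """Per-group diversity under a metadata grouping scheme.

    ``scheme`` names a population-map column (e.g. ``group`` for geography,
    ``ecoregion``, or any custom column such as a clade label). Haplotypes
    are collapsed on the pooled alignment so shared haplotypes keep one
    identity across groups, then statistics are computed within each group.
    """
    assign = popmap.assignment(scheme)
    groups = sorted(set(assign[s] for s in aln.sample_ids))
    cols = aln.retained_columns()
    L = len(cols)
    out = []
    for g in groups:
        ids = [s for s in aln.sample_ids if assign[s] == g]
        sub = aln.subset(ids)
        # distances are on the pooled retained columns, not per-group ones
        seq_of = dict(sub.records)
        key_counts: dict[str, int] = {}
        for s in ids:
            key = "".join(seq_of[s][c] for c in cols)
            key_counts[key] = key_counts.get(key, 0) + 1
        haps = HaplotypeTable(
            [(f"H{i+1}", k) for i, k in enumerate(key_counts)],
            ["all"],
            np.array([[c] for c in key_counts.values()], dtype=int),
        )
        out.append(diversity_stats(haps, group=g, L=L))
    return out
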