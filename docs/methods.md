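# Methods

This note records the models behind each component, the defaults and why,
the numerical choices, and the limits of what the synthetic-data tests can
show.

## Sequence handling

All statistics operate on *retained columns*: alignment positions where
every sequence carries a plain A/C/G/T. Columns containing gaps, Ns or
IUPAC ambiguity codes in any record are excluded before anything else is
computed (complete deletion), and haplotype identity is decided on the
retained columns only. This makes every count reproducible from the same
column set — segregating sites, transition/transversion classification,
base composition, pairwise distances and haplotype collapsing all see
identical data. Transition/transversion classification is per biallelic
column ({A,G} or {C,T} = transition, other two-base columns =
transversion); columns with three or more observed bases are tallied
separately as multiallelic rather than force-classified.

## Diversity estimators

Gene (haplotype) diversity is Nei's unbiased estimator
`Hd = n/(n−1)(1 − Σp_i²)` with the Nei (1987) eq. 8.12 sampling variance.
Nucleotide diversity is the uncorrected mean per-site pairwise difference
`π = k̄/L` (no multiple-hit correction — at the within-species divergences
this package targets, ~1%, the correction is far below the reporting
precision), with the Nei (1987) eq. 10.7 total variance, which includes
the coalescent ("stochastic") term; this matches the conventions of the
standard desktop tools for mtDNA surveys. Groups of one sample report
`Hd = undefined, π = 0` rather than raising, since survey tables routinely
contain singleton demes.

## AMOVA, pairwise Φ and SAMOVA

Variance components follow Excoffier, Smouse & Quattro (1992): sums of
squared pairwise distances (raw nucleotide differences, the conventional
default — no model correction) yield mean squares at the three levels,
which are equated to their expectations with the usual unequal-sample-size
coefficients. Φ_CT, Φ_SC and Φ_ST are ratios of those components; negative
estimates are reported unclamped, as is standard. Permutation nulls are
scheme-specific — samples among populations (Φ_ST), samples among
populations within groups (Φ_SC), whole populations among groups (Φ_CT) —
with the +1 pseudo-count correction `p = (b+1)/(m+1)`.

SAMOVA (Dupanloup et al. 2002) searches contiguous partitions of sampling
sites into K groups. Contiguity is defined on a Delaunay triangulation of
the site coordinates treated as planar x/y (an approximation at
continental extents; adequate for adjacency, and degenerate inputs fall
back to a complete graph). Each annealing chain starts from a random
region-grown contiguous partition; proposals move one site to an adjacent
group, are rejected if they disconnect the donor group, and are accepted
by Metropolis on −Φ_CT with geometric cooling (T₀ = 1, ratio 0.9, 10 moves
per temperature, stop below 1e-3). The default of 100 independent restarts
follows the original tool's convention; the best final partition wins,
ties by first occurrence under the seeded RNG. A per-candidate evaluator
precomputes deme-pair distance sums so each Φ_CT costs O(D²) in the number
of sites rather than O(N²) in samples.

## Neutrality tests

Tajima's D uses the standard a₁…e₂ constants. Fu's Fs is computed from the
exact Ewens sampling distribution: `S′ = P(K ≥ k_obs | θ, n)` with
unsigned Stirling numbers of the first kind and the rising factorial, all
in log-space (logaddexp recursion), stable to n of several hundred;
`Fs = ln(S′/(1−S′))`. θ is estimated as k̄ (θ_π). Significance comes from
neutral constant-size coalescent simulations conditioned on θ = k̄ — the
"simulate given theta" convention of the tool lineage mtDNA surveys use —
with infinite-sites mutations at rate θ/2 per lineage per coalescent-unit
time; p-values are lower-tail (expansion pushes both statistics negative).
Note D's null expectation is slightly negative (≈ −0.07 at n = 20, θ = 5)
because the denominator is itself estimated from S; this is a property of
the statistic, not a simulator bias.

## Haplotype networks

The minimum spanning network is the union of all minimum spanning trees
under Hamming distance (Kruskal by weight class, keeping every edge that
joins components separated by strictly cheaper classes; ε relaxes the
threshold). Median joining iterates: build the MSN over the current node
set, propose majority-consensus median vectors of connected triplets
(column ties branch into all tied medians), greedily add the median that
most reduces the total MSN length, prune unsampled nodes of degree ≤ 2,
repeat to a fixed point. ε defaults to 0 and characters are equally
weighted. One consequence worth stating: once a Steiner median is added,
direct sample–sample links it supersedes drop out of the final network, so
the network contains a minimum spanning tree *of its own node set* (and
its Steiner cost never exceeds the sampled MST cost) but not necessarily
an MST over sampled nodes alone.

## Distances and trees

F84 distances use the standard closed form from empirical (pooled) base
frequencies and per-pair transition/transversion proportions; with equal
frequencies and collapsed ti/tv structure the formula reduces exactly to
Jukes–Cantor, which the tests exploit. Saturated pairs (non-positive log
argument) are flagged and, in matrix output, replaced by twice the largest
finite distance so clustering remains possible; the fallback is
documented, deliberate and visible. UPGMA uses average linkage with ties
broken by lexicographically smallest label pair, making output
deterministic. The genealogy used for the migration-count test follows the
original protocol: one tip per (haplotype, site-of-occurrence) — a shared
haplotype contributes one tip per site where it occurs — on the UPGMA/F84
tree.

## Structured coalescent

Haploid (mtDNA) coalescent without migration: k lineages in a population
of haploid effective size Ne coalesce at rate k(k−1)/(2Ne) per generation;
at a divergence time the daughters' surviving lineages merge into the
ancestor. The published effective sizes (10⁴, 10⁶) are read as haploid
sizes. The allopatric-fragmentation null is a simultaneous K-way split at
the stated time with ancestral Ne equal to the per-deme Ne (the null's
internal topology is unspecified, so the maximally agnostic simultaneous
split is used). The scenario grid's generation counts (1,250 and 375,000)
are used verbatim even though they are inconsistent with a 10-year
generation time applied to the stated calendar depths; because the
original tool's time scaling is ambiguous, `null_population_tree` also
exposes `time_units="coalescent"` (depth × Ne) as the alternative reading.

## Slatkin–Maddison test

s is the Fitch parsimony count of the unordered deme character on a binary
gene tree (minimum state changes, equal to the brute-force minimum over
internal assignments); polytomies are resolved randomly (seeded) and the
minimum over resolutions reported. The null distribution is s over
simulated gene trees from the null population tree, the character states
being each hypothesis's regional grouping; rejection is lower-tail
(observed s below the null means less apparent migration than simultaneous
fragmentation predicts) with the empirical 0.5–99.5 percentile range as
the 99% interval. With the published design (sizes 19/13/7/6),
fragmentation at 1,250 generations with Ne = 10⁴ gives a null s
distribution entirely above the observed s = 4 at reps = 1,000; the
quasi-panmictic cell (Ne = 10⁶) reproduces the published null mean within
simulation error, while shallower-structure cells differ from the
published ones — attributable to the unquantified null-tree internals of
the original analysis, and documented rather than tuned away.

## Synthetic-data generator

The generator emulates the study design: per-site sample sizes
(6,2,2,6,2,13,3,3,2,1,1,4 over 12 sites summing to 45, mapped onto the
four regions as 19/13/7/6), L = 1,068 sites, HKY mutation with κ = 20 and
stationary frequencies A 0.298 / C 0.286 / G 0.130 / T 0.286 (the
published composition), and μ = 2.5×10⁻⁷ substitutions/site/generation
(the internally calibrated 2.5×10⁻² /site/My at 10 years/generation).
Default history: the four-region fragmentation null at 1,250 generations,
Ne = 10⁴. Sequences evolve by the exact per-branch transition matrix
expm(Q·μ·t) with Q normalised to unit mean rate — realised substitution
counts per branch are Poisson around μ·t·L, and stationarity is preserved
on long branches (a uniform event-placement scheme would not preserve the
base composition). A region's samples are assigned to its sampling sites
in exchangeable tip-label order so site labels carry no genealogical
signal beyond the region's. The truth record (gene tree newick, population
tree, parameters, true partition) suffices to recompute every downstream
expectation without re-simulation.

What the generator does not emulate: rate heterogeneity across sites (no
Γ/invariant-sites mixture, though the real data support one), indels,
sequencing error, heteroplasmy, migration after divergence, or the deep
four-clade structure of the real genealogy (the default null history is
shallow, so realised π ≈ 0.004–0.009 across seeds sits at or below the
observed 0.009). Tests passing on synthetic data therefore demonstrate
correctness of the estimators and simulators under a known truth, not that
the real data would yield any particular value.

## Problem sizes and determinism

Stochastic checks use fixed seeds (project default 20100914) and
Monte-Carlo sizes chosen to make their standard errors small relative to
the asserted tolerances: 10,000 replicates for TMRCA means, 2,000 for the
Tajima's D null mean, 1,000 gene trees per Slatkin–Maddison scenario, 100
annealing restarts for full SAMOVA runs (fewer in unit tests where the
planted signal is strong). Permutation p-values use the +1 correction and
are exactly reproducible given a seed.
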