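# tapirgeo

Population-genetic and phylogeographic analysis of mitochondrial sequence
surveys, built around a continent-wide cytochrome-*b* study of the lowland
tapir (*Tapirus terrestris*): 45 haploid sequences of 1,068 bp from 12
sampling sites grouped into 4 geographic regions (Andean foothills, western,
northern and southern Amazonia).

The package implements the full analysis chain such a survey needs:

- **Haplotypes and diversity** — haplotype collapsing, segregating-site
  classification (transitions/transversions), Nei's unbiased gene diversity
  `Hd = n/(n−1)·(1 − Σp_i²)` and nucleotide diversity `π = k̄/L`, per any
  grouping of samples.
- **Population structure** — hierarchical AMOVA variance components
  (σ²_a, σ²_b, σ²_c) and fixation indices Φ_CT, Φ_SC, Φ_ST with
  scheme-specific permutation tests; pairwise Φ_ST; and SAMOVA, a
  simulated-annealing search for the geographically contiguous K-partition
  of sampling sites maximising Φ_CT (contiguity from a Delaunay
  triangulation of site coordinates).
- **Demographic history** — Tajima's D and Fu's Fs (exact Ewens sampling
  tail via log-space Stirling numbers), with p-values from neutral
  coalescent simulation conditioned on θ = k̄.
- **Genealogies** — median-joining haplotype networks (minimum spanning
  network plus Steiner median vectors), F84 maximum-likelihood pairwise
  distances, UPGMA trees, newick I/O.
- **Hypothesis testing** — a structured-coalescent simulator (haploid, no
  migration) on arbitrary population trees, and the Slatkin–Maddison *s*
  statistic (Fitch parsimony count of the deme character on a gene tree)
  with simulated null distributions: an observed *s* far below the
  allopatric-fragmentation null rejects simultaneous-isolation history.
- **Synthetic data** — a generator reproducing the study's sampling design
  (45 × 1,068 bp, 12 sites, 4 regions) under any population-tree
  hypothesis with HKY mutations (κ = 20, base frequencies biased against G),
  emitting FASTA + population map + a truth record.

## Worked example

Simulate a study-shaped dataset and summarise its variation:

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_sequence_variation.py
```

which prints (seed 1):

```
45 sequences, 1068 unambiguous sites
S=27 (25 transitions, 2 transversions, 0 multiallelic)
base composition: A: 29.08%, C: 29.29%, G: 11.78%, T: 29.85%
22 haplotypes; Hd = 0.938 +/- 0.019; pi = 0.003891 +/- 0.002189; mean pairwise difference 0.389%
```

— a single coalescent realisation of the four-region null history
(fragmentation 1,250 generations ago, Ne = 10,000 per region): the strong
transition bias and G-poor composition mirror the real data, while S and π
fall below the observed values because one realisation of so shallow a
history carries less variation than the deeply structured real genealogy.
The same run reproduces the published gene diversities exactly from the
printed haplotype table:

```
gene diversity from the published haplotype table:
  all: n=45 Hd=0.988 +/- 0.007
  Andean Foothill: n=19 Hd=0.977 +/- 0.023
  North Amazon: n=13 Hd=0.923 +/- 0.057
```

The remaining drivers (`03` AMOVA, `04` neutrality tests, `05` network +
UPGMA/F84 tree, `06` SAMOVA scan, `07` Slatkin–Maddison scenario grid) each
read the simulated dataset from `results/synthetic/` and write their tables
under `results/`. For instance `07` compares an observed *s* against 1,000
simulated gene trees per (generations, Ne) scenario and reports the null
mean, its empirical 99% interval and the lower-tail p-value, scenario by
scenario.

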