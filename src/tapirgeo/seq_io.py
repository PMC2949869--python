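"""Aligned-sequence input, haplotype collapsing and site classification.

Sequences are mtDNA (haploid) alignments; all downstream statistics use
complete deletion: any column containing a base other than A/C/G/T in any
record is dropped before counting polymorphisms or collapsing haplotypes,
so every reported quantity refers to unambiguously aligned positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
VALID_CHARS = frozenset("ACGTUNRYSWKMBDHV-?.")


class AlignmentError(ValueError):
    """Raised when input sequences violate alignment invariants."""


class InputError(ValueError):
    """Raised for malformed or inconsistent user input."""


@dataclass
class SequenceAlignment:
    """An ordered, equal-length set of named nucleotide sequences."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment has no records")
        normalized = []
        length = len(self.records[0][1])
        seen: set[str] = set()
        for name, seq in self.records:
            seq = seq.upper().replace("U", "T")
            if name in seen:
                raise InputError(f"duplicate sample id: {name!r}")
            seen.add(name)
            if len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: {name!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            for pos, ch in enumerate(seq):
                if ch not in VALID_CHARS:
                    raise InputError(
                        f"illegal character {ch!r} in record {name!r} "
                        f"at position {pos + 1}"
                    )
            normalized.append((name, seq))
        self.records = normalized

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [name for name, _ in self.records]

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single characters."""
        return np.array([list(seq) for _, seq in self.records], dtype="U1")

    def retained_columns(self) -> np.ndarray:
        """Indices of columns containing only A/C/G/T (complete deletion)."""
        mat = self.matrix()
        ok = np.isin(mat, list("ACGT")).all(axis=0)
        return np.flatnonzero(ok)

    def subset(self, sample_ids: list[str]) -> "SequenceAlignment":
        wanted = dict(self.records)
        missing = [s for s in sample_ids if s not in wanted]
        if missing:
            raise InputError(f"samples not in alignment: {missing}")
        return SequenceAlignment([(s, wanted[s]) for s in sample_ids])


@dataclass
class PopulationMap:
    """Per-sample metadata: sampling site, geographic group, ecoregion."""

    table: pd.DataFrame  # columns: sample_id site_id group ecoregion lat lon species

    REQUIRED = ("sample_id", "site_id", "group", "ecoregion")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise InputError(f"population map missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise InputError(f"duplicate sample ids in map: {sorted(dups)}")
        self.table = self.table.reset_index(drop=True)

    def check_covers(self, aln: SequenceAlignment) -> None:
        missing = set(aln.sample_ids) - set(self.table["sample_id"])
        if missing:
            raise InputError(f"samples missing from population map: {sorted(missing)}")

    def assignment(self, level: str) -> dict[str, str]:
        """sample_id -> label at a metadata level (site_id/group/ecoregion/...)."""
        if level not in self.table.columns:
            raise InputError(f"unknown grouping level {level!r}")
        return dict(zip(self.table["sample_id"], self.table[level].astype(str)))

    def samples_of_species(self, species: str) -> list[str]:
        if "species" not in self.table.columns:
            raise InputError("population map has no species column")
        sel = self.table["species"] == species
        return list(self.table.loc[sel, "sample_id"])


@dataclass
class HaplotypeTable:
    """Unique sequences with per-deme sample counts."""

    haplotypes: list[tuple[str, str]]  # (hap_id, sequence on retained columns)
    demes: list[str]
    counts: np.ndarray  # (n_hap, n_deme) non-negative ints
    members: dict[str, list[str]] = field(default_factory=dict)  # hap_id -> samples

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.haplotypes), len(self.demes)):
            raise InputError("counts shape does not match haplotypes × demes")
        if (self.counts < 0).any():
            raise InputError("negative haplotype count")
        seqs = [s for _, s in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise InputError("haplotype sequences are not unique")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        return self.total_counts / self.n

    @property
    def length(self) -> int:
        return len(self.haplotypes[0][1]) if self.haplotypes else 0

    def expand(self) -> list[str]:
        """Multiset of sequences, one per sample (pooled over demes)."""
        out: list[str] = []
        for (_, seq), c in zip(self.haplotypes, self.total_counts):
            out.extend([seq] * int(c))
        return out


@dataclass
class SiteSummary:
    """Column-wise polymorphism classification of an alignment."""

    S: int
    transitions: int
    transversions: int
    multiallelic: int
    base_composition: dict[str, float]
    retained_sites: int

    def __post_init__(self) -> None:
        assert self.S == self.transitions + self.transversions + self.multiallelic


def read_fasta(path: str | Path) -> SequenceAlignment:
    """Read a multi-FASTA alignment, preserving record order."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return SequenceAlignment(records)


def write_fasta(aln: SequenceAlignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a TSV with header sample_id site_id group ecoregion [lat lon species]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("lat", "lon"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return PopulationMap(df)


def collapse_haplotypes(
    aln: SequenceAlignment,
    popmap: PopulationMap | None = None,
    deme_level: str = "site_id",
    species_filter: str | None = None,
) -> HaplotypeTable:
    """Collapse identical sequences (on retained columns) into haplotypes.

    Haplotype ids are H1, H2, ... in order of first appearance in the
    alignment. When a population map is given, counts are tabulated per deme
    at ``deme_level``; otherwise a single pooled deme is used.
    """
    if popmap is not None:
        popmap.check_covers(aln)
        if species_filter is not None:
            keep = set(popmap.samples_of_species(species_filter))
            aln = aln.subset([s for s in aln.sample_ids if s in keep])
        deme_of = popmap.assignment(deme_level)
        demes = sorted({deme_of[s] for s in aln.sample_ids})
    else:
        deme_of = {s: "all" for s in aln.sample_ids}
        demes = ["all"]

    cols = aln.retained_columns()
    deme_index = {d: j for j, d in enumerate(demes)}

    hap_index: dict[str, int] = {}
    haplotypes: list[tuple[str, str]] = []
    members: dict[str, list[str]] = {}
    rows: list[list[int]] = []
    for name, seq in aln.records:
        key = "".join(seq[c] for c in cols)
        if key not in hap_index:
            hap_id = f"H{len(haplotypes) + 1}"
            hap_index[key] = len(haplotypes)
            haplotypes.append((hap_id, key))
            members[hap_id] = []
            rows.append([0] * len(demes))
        i = hap_index[key]
        rows[i][deme_index[deme_of[name]]] += 1
        members[haplotypes[i][0]].append(name)

    return HaplotypeTable(haplotypes, demes, np.array(rows, dtype=int), members)


def classify_sites(aln: SequenceAlignment) -> SiteSummary:
    """Classify polymorphic columns and tabulate base composition.

    Columns with non-ACGT characters are excluded. A biallelic column whose
    two bases are both purines or both pyrimidines is a transition site;
    other biallelic columns are transversion sites; columns with three or
    more bases are counted separately as multiallelic.
    """
    mat = aln.matrix()
    cols = aln.retained_columns()
    ti = tv = multi = 0
    for c in cols:
        alleles = set(mat[:, c])
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            multi += 1
        elif alleles <= PURINES or alleles <= PYRIMIDINES:
            ti += 1
        else:
            tv += 1
    retained = mat[:, cols]
    total = retained.size
    comp = {b: float((retained == b).sum()) / total for b in "ACGT"} if total else {}
    return SiteSummary(
        S=ti + tv + multi,
        transitions=ti,
        transversions=tv,
        multiallelic=multi,
        base_composition=comp,
        retained_sites=len(cols),
    )
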