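"""Study design constants for the lowland-tapir cytb survey.

The sampling design is reproduced programmatically from the published
sample table: 45 lowland tapirs (*Tapirus terrestris*) from 12 sampling
sites in 4 geographic regions plus 3 mountain tapirs (*T. pinchaque*),
each sample mapped to its sampling site, geographic group, ecogeographic
unit, and mtDNA haplotype. Site coordinates are approximate map positions
(synthetic stand-ins read off the published sampling map, adequate for
adjacency/contiguity computations, not for georeferencing).
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .coalescent import PopNode, PopulationTree, simultaneous_split_tree
from .seq_io import PopulationMap

# sample_id, site_id, geographic group, ecogeographic unit, haplotype
SAMPLE_TABLE: list[tuple[str, str, str, str, str]] = [
    ("TG01", "1", "North Amazon", "North-East Amazon rainforest", "Hte 1"),
    ("TG06", "1", "North Amazon", "North-East Amazon rainforest", "Hte 1"),
    ("TG29", "1", "North Amazon", "North-East Amazon rainforest", "Hte 1"),
    ("TG28", "1", "North Amazon", "North-East Amazon rainforest", "Hte 2"),
    ("TG5", "1", "North Amazon", "North-East Amazon rainforest", "Hte 3"),
    ("TG24", "1", "North Amazon", "North-East Amazon rainforest", "Hte 7"),
    ("TC54", "2", "North Amazon", "North-East Amazon rainforest", "Hte 11"),
    ("TC186", "2", "North Amazon", "North-East Amazon rainforest", "Hte 19"),
    ("TB01", "3", "North Amazon", "North-East Amazon rainforest", "Hte 14"),
    ("TB02", "3", "North Amazon", "North-East Amazon rainforest", "Hte 15"),
    ("TE17", "4", "Andean Foothill", "Upper Amazon rainforest", "Hte 4"),
    ("TE22", "4", "Andean Foothill", "Upper Amazon rainforest", "Hte 4"),
    ("TE14", "4", "Andean Foothill", "Upper Amazon rainforest", "Hte 5"),
    ("TE19", "4", "Andean Foothill", "Upper Amazon rainforest", "Hte 6"),
    ("TE20", "4", "Andean Foothill", "Upper Amazon rainforest", "Hte 8"),
    ("TE16", "4", "Andean Foothill", "Upper Amazon rainforest", "Hte 9"),
    ("TP104", "5", "West Amazon", "Upper Amazon rainforest", "Hte 12"),
    ("TP94", "5", "West Amazon", "Upper Amazon rainforest", "Hte 16"),
    ("TP14", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 13"),
    ("TP4", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 23"),
    ("TP12", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 24"),
    ("TP13", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 24"),
    ("TP11", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 25"),
    ("TP9", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 26"),
    ("TP6", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 27"),
    ("TP7", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 27"),
    ("TP5", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 28"),
    ("TP2", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 28"),
    ("TP3", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 29"),
    ("TP1", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 30"),
    ("TP10", "6", "Andean Foothill", "Upper Amazon rainforest", "Hte 31"),
    ("TC88", "7", "West Amazon", "Upper Amazon rainforest", "Hte 18"),
    ("TC68", "7", "West Amazon", "Upper Amazon rainforest", "Hte 20"),
    ("TB69", "7", "West Amazon", "Upper Amazon rainforest", "Hte 13"),
    ("TV95", "8", "North Amazon", "Llanos", "Hte 10"),
    ("TV48", "8", "North Amazon", "Llanos", "Hte 10"),
    ("TV46", "8", "North Amazon", "Llanos", "Hte 10"),
    ("TBo183", "9", "South Amazon", '"Pastizal" herbaceous habitat', "Hte 2"),
    ("TBo85", "9", "South Amazon", '"Pastizal" herbaceous habitat', "Hte 22"),
    ("TC100", "10", "West Amazon", "Choco Darien rainforest", "Hte 17"),
    ("TB29", "11", "South Amazon", "South East Amazon rainforest", "Hte 21"),
    ("TA10", "12", "South Amazon", "Dry tropical forest", "Hte 32"),
    ("TA11", "12", "South Amazon", "Dry tropical forest", "Hte 33"),
    ("TA12", "12", "South Amazon", "Dry tropical forest", "Hte 34"),
    ("TA13", "12", "South Amazon", "Dry tropical forest", "Hte 35"),
]

MOUNTAIN_TAPIR_ROWS: list[tuple[str, str]] = [
    ("TPI1", "Hpi 1"),
    ("TPI2", "Hpi 1"),
    ("TPI4", "Hpi 2"),
]

# site -> (approximate latitude, longitude); synthetic map positions
SITE_COORDS: dict[str, tuple[float, float]] = {
    "1": (4.0, -53.0),    # French Guiana
    "2": (4.0, -70.0),    # east Colombia
    "3": (-1.0, -62.0),   # north Brazil (Rio Negro)
    "4": (-1.5, -77.5),   # Ecuadorian Amazon
    "5": (-12.0, -70.5),  # south-east Peru
    "6": (-7.0, -75.0),   # east Peru
    "7": (-4.0, -70.0),   # Colombia/Brazil frontier
    "8": (7.5, -67.0),    # Venezuelan llanos
    "9": (-15.0, -63.0),  # Bolivia
    "10": (5.5, -77.0),   # west Colombia (Choco)
    "11": (-2.0, -49.0),  # Brazil, south of the Amazon mouth
    "12": (-26.0, -54.5), # Argentina
}

SITE_GROUP: dict[str, str] = {
    "1": "North Amazon", "2": "North Amazon", "3": "North Amazon",
    "4": "Andean Foothill", "5": "West Amazon", "6": "Andean Foothill",
    "7": "West Amazon", "8": "North Amazon", "9": "South Amazon",
    "10": "West Amazon", "11": "South Amazon", "12": "South Amazon",
}

GROUPS = ("Andean Foothill", "North Amazon", "South Amazon", "West Amazon")

# Slatkin-Maddison scenario grid: (generations to fragmentation, Ne)
SCENARIO_GRID: list[tuple[float, float]] = [
    (1_250, 10_000),
    (1_250, 1_000_000),
    (375_000, 10_000),
    (375_000, 1_000_000),
]

OBSERVED_S = 4  # reconstructed gene genealogy vs the four geographic regions


def population_map() -> PopulationMap:
    df = pd.DataFrame(
        SAMPLE_TABLE, columns=["sample_id", "site_id", "group", "ecoregion", "haplotype"]
    )
    df["lat"] = df["site_id"].map(lambda s: SITE_COORDS[s][0])
    df["lon"] = df["site_id"].map(lambda s: SITE_COORDS[s][1])
    df["species"] = "Tapirus terrestris"
    return PopulationMap(df.drop(columns=["haplotype"]))


def haplotype_counts(level: str | None = None) -> dict[str, Counter]:
    """Haplotype frequency spectra from the sample table.

    ``level=None`` pools all 45 lowland samples under key ``"all"``;
    otherwise one Counter per value of the column (``group``/``ecoregion``/
    ``site_id``), each counting haplotype occurrences within that group.
    """
    out: dict[str, Counter] = {}
    idx = {"site_id": 1, "group": 2, "ecoregion": 3}
    for row in SAMPLE_TABLE:
        key = "all" if level is None else row[idx[level]]
        out.setdefault(key, Counter())[row[4]] += 1
    return out


def site_sample_sizes() -> dict[str, int]:
    c = Counter(row[1] for row in SAMPLE_TABLE)
    return dict(sorted(c.items(), key=lambda kv: int(kv[0])))


def region_sample_sizes() -> dict[str, int]:
    c = Counter(row[2] for row in SAMPLE_TABLE)
    return {g: c[g] for g in GROUPS}


def null_population_tree(
    generations: float, Ne: float, time_units: str = "generations"
) -> PopulationTree:
    """Allopatric-fragmentation null: simultaneous split of the four regions.

    Sample sizes are the study's per-region counts (Andean 19, North 13,
    South 7, West 6); the ancestral Ne equals the per-region Ne. With
    ``time_units="coalescent"`` the divergence time is ``generations * Ne``
    — the alternative reading of how the original tooling scaled the
    fragmentation depth, exposed because the published scaling is ambiguous.
    """
    tau = generations * Ne if time_units == "coalescent" else generations
    return simultaneous_split_tree(region_sample_sizes(), tau, Ne)


def hypothesis_tree(
    hypothesis: str, tmrca: float, Ne: float, sizes: dict[str, int] | None = None
) -> PopulationTree:
    """Population trees for the competing biogeographic hypotheses.

    ``null``: simultaneous four-way fragmentation at ``tmrca``.
    ``ii``: Andean foothills split first from the lowland-west lineage,
        which later sends separate lineages north and south of the Amazon.
    ``iii``: the north/south colonisation happens first; the western
        lowland and Andean foothill populations separate later.
    Internal divergence times, which the hypotheses leave unquantified, are
    spaced evenly between 0 and ``tmrca``.
    """
    sizes = sizes or region_sample_sizes()
    A, N, S, W = (
        sizes["Andean Foothill"],
        sizes["North Amazon"],
        sizes["South Amazon"],
        sizes["West Amazon"],
    )
    if hypothesis == "null":
        return null_population_tree(tmrca, Ne)

    def tip(name: str, n: int) -> PopNode:
        return PopNode(name=name, Ne=Ne, time=0.0, n_samples=n)

    if hypothesis == "ii":
        ns = PopNode(
            name="north+south", Ne=Ne, time=tmrca / 3.0,
            children=[tip("North Amazon", N), tip("South Amazon", S)],
        )
        west = PopNode(
            name="lowland-west", Ne=Ne, time=2.0 * tmrca / 3.0,
            children=[tip("West Amazon", W), ns],
        )
        root = PopNode(
            name="ancestral", Ne=Ne, time=tmrca,
            children=[tip("Andean Foothill", A), west],
        )
    elif hypothesis == "iii":
        ns = PopNode(
            name="north+south", Ne=Ne, time=tmrca / 2.0,
            children=[tip("North Amazon", N), tip("South Amazon", S)],
        )
        wa = PopNode(
            name="west+andes", Ne=Ne, time=tmrca / 3.0,
            children=[tip("West Amazon", W), tip("Andean Foothill", A)],
        )
        root = PopNode(name="ancestral", Ne=Ne, time=tmrca, children=[ns, wa])
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    return PopulationTree(root)


def region_identity_grouping() -> dict[str, str]:
    """Deme -> character state map: each region is its own state."""
    return {g: g for g in GROUPS}
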