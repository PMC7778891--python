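"""Published summary statistics of the reference resource releases.

These are the printed release-level numbers for the protein-family
knowledgebase the toolkit models: genome counts per taxonomic group in the
reference trees, family/gene counts for the 2018 (14.1) and 2020 (16.0)
releases, and protein-class coverage.  They are packaged as data so that
consistency arithmetic (group counts summing to the stated total, the
named-family and class-assignment percentages) is computable offline.
"""

from __future__ import annotations

#: genomes per kingdom/phylum represented in the 16.0 reference trees
GENOME_COUNTS_BY_GROUP: dict[str, int] = {
    "Bacteria": 35,
    "Archaea": 8,
    "Fungi": 14,
    "Plants": 40,
    "Protista and alveolata": 8,
    "Amoebozoa": 3,
    "Invertebrates": 15,
    "Vertebrates": 19,
}

#: stated total number of genomes in the 16.0 reference trees
GENOME_TOTAL: int = 142

#: per-release family statistics
RELEASE_STATS: dict[str, dict[str, int]] = {
    "14.1": {
        "year": 2018,
        "genomes": 132,
        "genes_in_families": 1_750_742,
        "families": 15_524,
        "named_families": 4_905,
    },
    "16.0": {
        "year": 2020,
        "genomes": 142,
        "genes_in_families": 2_065_831,
        "families": 15_702,
        "named_families": 14_849,
    },
}

#: protein-class ontology shape in release 16.0
PC_CLASS_COUNT: int = 210
PC_TOP_LEVEL_CLASSES: int = 24
PC_MAX_DEPTH: int = 4
#: families with a protein-class assignment in 16.0
PC_ASSIGNED_FAMILIES: int = 6_101
#: human protein-coding genes in class-assigned families (58% of the genome)
HUMAN_GENES_WITH_PC: int = 12_043


def genome_total_from_groups() -> int:
    """Sum of the per-group genome counts (consistency: equals GENOME_TOTAL)."""
    return sum(GENOME_COUNTS_BY_GROUP.values())


def named_family_percentage(release: str) -> float:
    """Percent of families carrying a meaningful name in a release."""
    stats = RELEASE_STATS[release]
    return 100.0 * stats["named_families"] / stats["families"]


def pc_assignment_percentage() -> float:
    """Percent of 16.0 families associated with a protein class."""
    return 100.0 * PC_ASSIGNED_FAMILIES / RELEASE_STATS["16.0"]["families"]
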