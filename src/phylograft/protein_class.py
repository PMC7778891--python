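"""Strict-hierarchy protein class ontology: loading, validation, summaries.

A protein class ontology is a forest of functional classes under three hard
constraints: every class has at most one parent, the graph is acyclic, and
the hierarchy is shallow (at most four levels by default).  Protein families
-- not individual genes -- are assigned to classes, each family to exactly
one class unless it is flagged multidomain (two distinct modular functions in
one gene product).  Because the hierarchy is strict, rolling gene counts up
to any level never double-counts a gene through multiple parentage; the only
multiple counting comes from multidomain families, and the summary reports it
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import obonet

__all__ = [
    "ProteinClass",
    "ProteinClassOntology",
    "PCValidationError",
    "GenomeSummary",
    "load_pc",
    "load_family_assignments",
    "summarize_genome",
]


class PCValidationError(ValueError):
    """Raised when an ontology violates the strict-hierarchy constraints;
    ``problems`` lists every violation found."""

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = list(problems)


@dataclass
class ProteinClass:
    id: str
    name: str
    parent: Optional[str]  # None for top-level classes


@dataclass
class ProteinClassOntology:
    classes: dict[str, ProteinClass]
    #: family_id -> (class ids, is_multidomain)
    family_assignments: dict[str, tuple[list[str], bool]] = field(default_factory=dict)

    def depth(self, class_id: str) -> int:
        """1-based depth: top-level classes are at level 1."""
        d = 1
        cur = self.classes[class_id]
        while cur.parent is not None:
            d += 1
            cur = self.classes[cur.parent]
        return d

    def ancestor_at_level(self, class_id: str, level: int) -> str:
        """Ancestor-or-self at the requested level; a class shallower than
        ``level`` rolls up to itself (its most specific available class)."""
        lineage = [class_id]
        cur = self.classes[class_id]
        while cur.parent is not None:
            lineage.append(cur.parent)
            cur = self.classes[cur.parent]
        lineage.reverse()  # top-level first
        return lineage[min(level, len(lineage)) - 1]

    def max_observed_depth(self) -> int:
        return max((self.depth(c) for c in self.classes), default=0)


def _validate(raw: dict[str, tuple[str, list[str]]], max_depth: int) -> list[str]:
    """Check raw (id -> (name, parents)) rows against the hierarchy rules."""
    problems: list[str] = []
    for cid, (_, parents) in raw.items():
        if len(parents) > 1:
            problems.append(f"class {cid} has multiple parents: {sorted(parents)}")
        for p in parents:
            if p not in raw:
                problems.append(f"class {cid} references unknown parent {p}")
    g = nx.DiGraph()
    g.add_nodes_from(raw)
    for cid, (_, parents) in raw.items():
        for p in parents:
            if p in raw:
                g.add_edge(p, cid)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        problems.append("cycle detected: " + " -> ".join(u for u, _ in cycle))
        return problems  # depth undefined under a cycle
    # depth = longest root-to-node chain (unique chain once single-parent holds)
    for cid in nx.topological_sort(g):
        depth = 1
        parents = raw[cid][1]
        if parents and parents[0] in raw:
            depth = _depth_of(raw, parents[0]) + 1
        if depth > max_depth:
            problems.append(f"class {cid} at depth {depth} exceeds max depth {max_depth}")
    return problems


def _depth_of(raw: dict[str, tuple[str, list[str]]], cid: str) -> int:
    d = 1
    seen = set()
    while True:
        parents = raw[cid][1]
        if not parents or parents[0] not in raw or cid in seen:
            return d
        seen.add(cid)
        cid = parents[0]
        d += 1


def _read_tsv_classes(path) -> dict[str, tuple[str, list[str]]]:
    raw: dict[str, tuple[str, list[str]]] = {}
    dupes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["class_id", "parent_id"]:
            raise PCValidationError([f"bad class TSV header: {header}"])
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            cid, parent = parts[0], parts[1]
            name = parts[2] if len(parts) > 2 else cid
            if cid in raw:
                dupes.append(f"duplicate class id {cid}")
                continue
            raw[cid] = (name, [parent] if parent else [])
    if dupes:
        raise PCValidationError(dupes)
    return raw


def _read_obo_classes(path) -> dict[str, tuple[str, list[str]]]:
    graph = obonet.read_obo(path, ignore_obsolete=True)
    raw: dict[str, tuple[str, list[str]]] = {}
    for cid, data in graph.nodes(data=True):
        parents = list(data.get("is_a", []))
        raw[cid] = (data.get("name", cid), parents)
    return raw


def load_pc(path, max_depth: int = 4) -> ProteinClassOntology:
    """Load a protein class ontology from OBO or TSV and enforce the strict
    hierarchy: single parent, acyclic, depth <= ``max_depth``.

    Raises :class:`PCValidationError` listing every violation.  OBO terms
    with more than one ``is_a`` parent are violations, never silently pruned.
    """
    p = Path(path)
    if p.suffix.lower() == ".obo":
        raw = _read_obo_classes(path)
    else:
        raw = _read_tsv_classes(path)
    problems = _validate(raw, max_depth)
    if problems:
        raise PCValidationError(problems)
    classes = {
        cid: ProteinClass(cid, name, parents[0] if parents else None)
        for cid, (name, parents) in raw.items()
    }
    return ProteinClassOntology(classes)


def load_family_assignments(path, ontology: ProteinClassOntology) -> None:
    """Attach family -> class assignments from TSV
    (``family_id<TAB>class_ids comma-separated<TAB>is_multidomain 0/1``).

    An empty class field records a family with no class assignment.  A family
    with several classes must carry the multidomain flag.
    """
    problems = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["family_id"]:
            raise PCValidationError([f"bad assignment header: {header}"])
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            fam = parts[0]
            class_ids = [c for c in parts[1].split(",") if c] if len(parts) > 1 else []
            multidomain = len(parts) > 2 and parts[2] in ("1", "true", "True")
            for cid in class_ids:
                if cid not in ontology.classes:
                    problems.append(f"family {fam} assigned to unknown class {cid}")
            if len(class_ids) > 1 and not multidomain:
                problems.append(
                    f"family {fam} has {len(class_ids)} classes but is not multidomain"
                )
            ontology.family_assignments[fam] = (class_ids, multidomain)
    if problems:
        raise PCValidationError(problems)


@dataclass
class GenomeSummary:
    """Gene counts per class at one hierarchy level.

    ``multi_counted`` is the number of genes contributing to more than one
    class (only possible through multidomain families); for single-class
    assignments ``sum(counts.values()) + unclassified == total_genes``.
    """

    level: int
    counts: dict[str, int]
    unclassified: int
    multi_counted: int
    total_genes: int


def summarize_genome(
    gene_to_family: dict[str, str], ontology: ProteinClassOntology, level: int
) -> GenomeSummary:
    """Roll gene counts up to the requested hierarchy level.

    Each gene contributes once per *distinct* rolled-up class of its family's
    assignments (a multidomain family whose classes merge at this level still
    counts the gene once there).  Genes in families with no class assignment
    are unclassified; a gene mapped to a family absent from the assignment
    table is an error.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    counts: dict[str, int] = {}
    unclassified = 0
    multi = 0
    for gene, family in gene_to_family.items():
        if family not in ontology.family_assignments:
            raise KeyError(f"gene {gene!r} mapped to unknown family {family!r}")
        class_ids, _ = ontology.family_assignments[family]
        if not class_ids:
            unclassified += 1
            continue
        rolled = {ontology.ancestor_at_level(c, level) for c in class_ids}
        for c in rolled:
            counts[c] = counts.get(c, 0) + 1
        if len(rolled) > 1:
            multi += 1
    return GenomeSummary(
        level=level,
        counts=dict(sorted(counts.items())),
        unclassified=unclassified,
        multi_counted=multi,
        total_genes=len(gene_to_family),
    )
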