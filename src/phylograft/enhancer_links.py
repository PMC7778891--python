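"""Map genetic variants into enhancer intervals and report linked genes.

Enhancer-gene links are experimentally supported associations (ChIA-PET,
eQTL, Hi-C) between a non-coding interval and a target protein-coding gene.
Intervals are stored BED-style (0-based, half-open); VCF positions are
1-based, so a variant at POS p falls inside [start, end) iff
start + 1 <= p <= end.  Indels and structural variants overlap by their
anchor POS only, and multi-allelic records are treated as one position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from cyvcf2 import VCF
from intervaltree import IntervalTree

__all__ = ["EnhancerLink", "LinkTable", "VariantHit", "load_links", "map_variants",
           "enhancers_for_gene"]


@dataclass(frozen=True)
class EnhancerLink:
    enhancer_id: str
    chrom: str  # normalized: no leading "chr"
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene_id: str
    tissue: str = ""
    assay: str = ""  # ChIA-PET / eQTL / Hi-C (free text accepted)


@dataclass
class VariantHit:
    """One (variant, enhancer, gene) overlap; tissue/assay evidence is
    aggregated over the supporting link rows.  A variant with no overlap
    yields a single row with enhancer_id and gene_id None."""

    variant_id: str
    chrom: str
    pos: int  # 1-based VCF position
    enhancer_id: Optional[str]
    gene_id: Optional[str]
    tissues: str = ""
    assays: str = ""


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class LinkTable:
    """Interval-indexed enhancer-gene link table (one tree per chromosome)."""

    def __init__(self, links: list[EnhancerLink]):
        seen = set()
        for link in links:
            key = (link.enhancer_id, link.gene_id, link.tissue, link.assay)
            if key in seen:
                raise ValueError(f"duplicate link row {key}")
            seen.add(key)
            if not 0 <= link.start < link.end:
                raise ValueError(
                    f"bad interval [{link.start}, {link.end}) for {link.enhancer_id}"
                )
        self.links = list(links)
        self._trees: dict[str, IntervalTree] = {}
        self._by_gene: dict[str, list[EnhancerLink]] = {}
        for link in links:
            self._trees.setdefault(link.chrom, IntervalTree()).addi(
                link.start, link.end, link
            )
            self._by_gene.setdefault(link.gene_id, []).append(link)

    def overlapping(self, chrom: str, pos: int) -> list[EnhancerLink]:
        """Links whose interval contains the 1-based position ``pos``."""
        tree = self._trees.get(_norm_chrom(chrom))
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.at(pos - 1)),
            key=lambda l: (l.enhancer_id, l.gene_id, l.tissue, l.assay),
        )

    def __len__(self) -> int:
        return len(self.links)


def load_links(path) -> LinkTable:
    """Load a BED-like TSV of links: chrom, start, end, enhancer_id, gene_id,
    tissue, assay.  Lines starting with '#' and a header line are skipped;
    chromosome names are normalized by stripping a leading "chr"."""
    links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] in ("chrom", "chr", "CHROM"):
                continue
            if len(parts) < 5:
                raise ValueError(f"line {lineno}: expected >= 5 columns, got {len(parts)}")
            chrom, start_s, end_s, enh, gene = parts[:5]
            tissue = parts[5] if len(parts) > 5 else ""
            assay = parts[6] if len(parts) > 6 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}")
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            links.append(EnhancerLink(enh, _norm_chrom(chrom), start, end, gene, tissue, assay))
    return LinkTable(links)


def map_variants(vcf_path, links: LinkTable) -> list[VariantHit]:
    """Map every VCF record to the enhancers containing its position and the
    genes those enhancers regulate.

    Output has one row per (variant, enhancer, gene), with the supporting
    tissues and assays comma-aggregated; variants outside every enhancer
    still emit one empty-hit row so no input is silently dropped.
    """
    out: list[VariantHit] = []
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise ValueError(f"unreadable VCF {vcf_path}: {exc}") from exc
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        hits = links.overlapping(rec.CHROM, rec.POS)
        if not hits:
            out.append(VariantHit(vid, _norm_chrom(rec.CHROM), rec.POS, None, None))
            continue
        grouped: dict[tuple[str, str], list[EnhancerLink]] = {}
        for link in hits:
            grouped.setdefault((link.enhancer_id, link.gene_id), []).append(link)
        for (enh, gene), rows in sorted(grouped.items()):
            tissues = sorted({r.tissue for r in rows if r.tissue})
            assays = sorted({r.assay for r in rows if r.assay})
            out.append(
                VariantHit(
                    vid, _norm_chrom(rec.CHROM), rec.POS, enh, gene,
                    ",".join(tissues), ",".join(assays),
                )
            )
    return out


def enhancers_for_gene(gene_id: str, links: LinkTable) -> list[EnhancerLink]:
    """All links targeting ``gene_id``, sorted by (chrom, start); empty for
    an unknown gene."""
    rows = links._by_gene.get(gene_id, [])
    return sorted(rows, key=lambda l: (l.chrom, l.start, l.end, l.enhancer_id))
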