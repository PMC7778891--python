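"""Map genetic variants to enhancers and the genes those enhancers regulate.

Builds a small enhancer-gene link table and a VCF, then reports for each
variant the enhancers containing it (VCF positions are 1-based; intervals
are BED-style half-open) and the linked target genes.
"""

import tempfile
from pathlib import Path

from phylograft.enhancer_links import EnhancerLink, LinkTable, map_variants

table = LinkTable(
    [
        EnhancerLink("E1", "1", 100, 200, "GENE_A", "liver", "eQTL"),
        EnhancerLink("E1", "1", 100, 200, "GENE_B", "brain", "Hi-C"),
        EnhancerLink("E2", "2", 500, 900, "GENE_A", "heart", "ChIA-PET"),
    ]
)

vcf_text = (
    "##fileformat=VCFv4.2\n##contig=<ID=1>\n##contig=<ID=2>\n##contig=<ID=chr2>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    "1\t150\trs1\tA\tT\t.\t.\t.\n"
    "1\t250\trs2\tG\tC\t.\t.\t.\n"
    "chr2\t600\trs3\tT\tG\t.\t.\t.\n"
)
with tempfile.TemporaryDirectory() as td:
    vcf = Path(td) / "variants.vcf"
    vcf.write_text(vcf_text)
    for hit in map_variants(vcf, table):
        enh = hit.enhancer_id or "(no enhancer)"
        gene = hit.gene_id or "-"
        print(f"{hit.variant_id}  {hit.chrom}:{hit.pos}  {enh:14s} {gene:8s} "
              f"{hit.tissues or '-'} / {hit.assays or '-'}")
# rs1 falls inside E1, which links to two genes -> two rows; rs2 overlaps
# nothing and still emits a row; 'chr2' and '2' chromosome names unify.
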