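"""Map an amino-acid position to its homologous positions across a family.

Given one sequence and a residue index, the family MSA column holding that
residue gives the corresponding (1-based, ungapped) positions in every other
family member -- or none where a member has a gap.
"""

from phylograft import map_homolog_positions
from phylograft.reference_library import FamilyMSA

msa = FamilyMSA(
    "demo",
    {
        "HUMAN": "MK-VLSQ",
        "MOUSE": "MKAVLSQ",
        "YEAST": "MKAV--Q",
    },
)

for pos in (2, 3, 5):
    hits = map_homolog_positions(msa, "HUMAN", pos)
    rendered = ", ".join(f"{sid}:{p if p else 'gap'}" for sid, p in hits)
    print(f"HUMAN residue {pos} -> {rendered}")
# Position 5 of HUMAN sits in an MSA column where YEAST is gapped, so only
# MOUSE reports a corresponding residue.
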