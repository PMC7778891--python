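"""Validate a strict-hierarchy protein class ontology and summarize a genome.

The ontology must be single-parent, acyclic and at most four levels deep.
Gene counts roll up the hierarchy without double-counting (the only multiple
counting comes from explicitly multidomain families, and is reported).
"""

import tempfile
from pathlib import Path

from phylograft import load_pc, summarize_genome
from phylograft.protein_class import PCValidationError
from phylograft import synthetic_data as synth

with tempfile.TemporaryDirectory() as td:
    good = Path(td) / "pc.obo"
    good.write_text(synth.simulate_pc_obo(12, max_depth=3, seed=1))
    onto = load_pc(good, max_depth=4)
    print(f"valid ontology: {len(onto.classes)} classes, "
          f"max depth {onto.max_observed_depth()}")

    bad = Path(td) / "bad.obo"
    bad.write_text(synth.simulate_pc_obo(8, max_depth=3, seed=1, planted="multi_parent"))
    try:
        load_pc(bad)
    except PCValidationError as e:
        print(f"rejected ontology: {e.problems[0]}")

# pick classes under two *different* top-level roots so the multidomain
# family genuinely double-counts at level 1
roots = sorted(c for c, pc in onto.classes.items() if pc.parent is None)
onto.family_assignments = {
    "FAM1": ([roots[0]], False),
    "FAM2": ([roots[1]], False),
    "FAM3": ([], False),                    # no class assigned
    "FAM4": ([roots[0], roots[1]], True),   # multidomain
}
genes = {f"g{i}": f"FAM{i % 4 + 1}" for i in range(20)}
summary = summarize_genome(genes, onto, level=1)
print(f"level-1 counts: {summary.counts}")
print(f"unclassified={summary.unclassified}  multi_counted={summary.multi_counted}")
# Counts partition the classified genes exactly, except the multidomain
# family's genes, which appear under both of its classes and are reported.
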