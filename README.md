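# phylograft

Classify protein sequences by **grafting** them onto annotated reference
phylogenetic trees, and analyze the gene lists that come out of such
classifications. The package is a self-contained reimplementation of the
computational core of a family-tree-based protein knowledgebase: placement
of new sequences into precomputed family trees, transfer of subfamily and
GO-style gain/loss annotations from the graft point, gene-list
over/under-representation statistics, strict-hierarchy protein-class
ontology validation and genome summaries, and mapping of genetic variants
through enhancer–gene links. It is aimed at computational biologists who
want these operations as an importable, fully deterministic library (plus a
thin CLI) rather than a web service.

## The core method

A reference **family bundle** is a rooted tree with stably labeled internal
nodes (`AN12`), the family MSA, gain/loss term annotations on internal
nodes, and subfamily root nodes. Classifying a query sequence proceeds in
three steps:

1. **Family selection** — each family MSA is condensed into a
   position-specific profile: match columns are those with gap fraction
   ≤ 0.5, and the emission for residue *a* in column *c* is the
   pseudocount-smoothed frequency (count_a + α·q_a)/(n_c + α) with uniform
   background *q* and α = 1. The query is scored against every profile by
   global affine-gap dynamic programming with log₂-odds match scores
   (gap open 4 bits, extend 0.5 bits); the highest bit score wins.
2. **Alignment into reference coordinates** — the same DP traceback maps
   each query residue to an MSA match column.
3. **Parsimony placement** — for every tree edge *e*, the cost of attaching
   the query as a new leaf on *e* is the Fitch (Hartigan) parsimony score of
   the augmented tree over the match columns, with gaps and ambiguity codes
   as missing data. Costs for all edges are computed incrementally from one
   downpass and one "outside" pass over bitmask state sets: the cost on the
   edge above node *v* is `down(v) + outside(v) + (3 − K)` per column, where
   *K* is the largest number of the sets {down(v), outside(v), query}
   sharing a state. This equals recomputing Fitch from scratch on each
   augmented tree, and the test suite enforces that equivalence exactly.
   The minimal-cost edge is split by a new `ANINDUCED` node and the query
   attached as `ANGRAFTED`; ties resolve toward the most rootward edge.

The graft point then determines the annotations: the query inherits the
subfamily whose root clade contains the induced node, and every term whose
most recent gain/loss event on the root→graft lineage is a gain.

The surrounding services use standard machinery: two-sided
minimum-likelihood Fisher exact / binomial tests with Benjamini–Hochberg or
Bonferroni correction for list enrichment, Mann–Whitney U for quantitative
value enrichment, interval trees for VCF→enhancer→gene mapping
(1-based VCF positions against half-open BED intervals), and single-parent /
acyclic / depth-≤ 4 validation for the protein-class ontology.

Everything is testable offline: the `synthetic_data` module simulates
families with known history (Yule trees, 20-state Jukes–Cantor-style
sequence evolution, planted gain/loss annotations), gene lists with planted
enrichment, enhancer tables, VCFs, and protein-class hierarchies with
planted violations.

## Worked example

`examples/01_graft_query.py` simulates a 16-leaf family and re-classifies
one member's sequence:

```text
query           : L5 (200 residues, held out)
bit score       : 696.0
graft edge      : L5 (cost 358, delta 0, ties ['L5'])
subfamily       : None
inherited terms : ['GO:0000003', 'GO:0000004', 'GO:0000005']
true leaf terms : ['GO:0000003', 'GO:0000004', 'GO:0000005']
```

The query lands uniquely on its own leaf's edge with `delta 0` (it adds no
substitutions beyond the reference tree's own 358) and inherits exactly the
terms its lineage implies. The other scripts in `examples/` demonstrate
homolog-position mapping, over-representation and value enrichment,
variant→enhancer→gene mapping, and protein-class validation/summaries, each
printing a short annotated result.

The same workflows are available from a shell:

```bash
phylograft simulate family --out-dir fam --seed 0
phylograft graft --family-dir fam --query queries.fasta --out-prefix out --jplace
phylograft enrich --list list.txt --reference ref.txt --terms terms.tsv
phylograft map-variants --vcf variants.vcf --links links.tsv
```

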