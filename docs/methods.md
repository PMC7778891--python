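# Methods

This note documents the models and procedures implemented in phylograft,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference bundles and formats

A family bundle couples a rooted reference tree (Newick; internal nodes
carry stable labels like `AN12`), the family MSA (FASTA, `-` gaps), gain/loss
term annotations on internal nodes (TSV), and subfamily roots (TSV).
Loading validates the whole bundle and reports *every* violation: MSA rows
vs. tree leaves must match exactly, annotation node ids must exist, and
subfamily root clades must be disjoint. Nesting of subfamily roots is
treated as a data error rather than resolved by precedence, because no
nesting semantics is defined for subfamily clades; annotating the same node
with both gain and loss of one term is likewise rejected at load since no
precedence rule exists.

The Newick dialect is deliberately narrow: unquoted labels over
`[A-Za-z0-9_.-]`, optional branch lengths, no quoted labels or comments.
Bundles are machine-generated, and a ~100-line recursive-descent parser is
fully auditable; round trips are cross-checked against dendropy in the test
suite. Missing branch lengths default to 1.0 — placement uses topology
only, and a positive default keeps serialization total. Unlabeled internal
nodes are auto-named `AN<k>` in pre-order, continuing past the largest
existing index. Serialization prints branch lengths to 6 decimals.

## Profile model

The family "HMM" of the classification pipeline is realized as a
position-specific profile with affine gaps, not a full plan7 HMM. The
simplification is intentional: the model is deterministic, admits an
exhaustive brute-force alignment oracle, and suffices for family selection
and column mapping at reference-bundle scale. No E-value calibration is
attempted; scores are plain bits.

Parameters (all configurable):

| parameter          | default | meaning |
|--------------------|---------|---------|
| `gap_fraction_max` | 0.5     | max gap fraction for a match column (inclusive) |
| `pseudocount_alpha`| 1.0     | background-weighted pseudocount mass |
| background         | 1/20    | uniform over the 20 amino acids |
| `gap_open_bits`    | 4.0     | affine gap open penalty |
| `gap_extend_bits`  | 0.5     | per-position gap extension penalty |

Emissions are `(count_a + α·q_a)/(n_c + α)`; ambiguity codes (X/B/Z/U/O) in
the MSA are excluded from counts, and in queries they score exactly 0 bits
rather than being rejected. Alignment is global (Gotoh three-state DP,
implemented as a numba kernel); a gap run of length *g* costs
`open + g·extend`, and a deletion run abutting an insertion run counts as
two runs. Traceback is deterministic: ties prefer match over delete over
insert, and the final cell prefers the same order. Family selection takes
the arg-max bit score with lexicographic family-id tie-break and an optional
`min_bits` floor (default 0).

## Parsimony placement

"Most parsimonious graft point" is realized as unweighted Fitch parsimony
over the profile match columns. Two modeling choices:

- **Gaps are missing data** (the full 20-state set), never a 21st state:
  indel-rich alignments would otherwise let alignment artifacts dominate
  integer costs.
- **Insert columns are ignored**: query residues that align between match
  columns carry no placement signal.

Costs for all edges come from a two-pass algorithm over bitmask state sets
(20 bits per column, vectorized with numpy): a postorder pass gives each
node the Hartigan set and cost of its subtree; a preorder pass gives each
node the set and cost of the rest of the tree seen from its parent edge
(the sibling combine at a suppressed degree-2 node adds no event). The
insertion cost on the edge above *v* is `down(v) + outside(v) + (3 − K)`
per column with *K* the maximal multiplicity over the three sets
{down(v), outside(v), query}; placement above the root costs
`down(root) + [query ∩ down(root) = ∅]`. Because parsimony score is
invariant to rooting and Hartigan's counting rule is exact for arbitrary
(including multifurcating) rooted trees, this equals brute-force
recomputation of the augmented tree on every edge — an equivalence the test
suite and acceptance script verify exhaustively on simulated families.

Ties resolve toward the most rootward edge (smallest depth of the edge's
tipward node, then smallest pre-order index; the ROOT pseudo-edge is most
rootward of all). The rationale is conservative annotation transfer: a more
ancestral graft point inherits fewer, more ancestral annotations. The full
tie set is always reported, and the jplace export emits one row per tied
edge. The induced node splits the chosen edge in half (each half gets half
the branch length; the grafted leaf gets length 0; grafting above the root
gives the old root length 0).

### Evaluating placement accuracy

Leaf-exclusion trials prune one leaf (suppressing its degree-2 parent),
rebuild the profile, re-align and re-graft the held-out sequence, and
measure the line-graph distance between the true edge (the pruned leaf's
sibling edge, or ROOT when the sibling became the root) and the reported
edge. The headline metric is the **tie-aware placement error**: 0 whenever
the cost-tie set contains the true edge, otherwise the distance. Raw
distance is deliberately not used: at low substitution rates many edges tie
at the minimal cost, the rootward tie-break then picks an ancestral edge by
*policy*, and raw distance would blame the tie-break for what is an
information deficit in the data. Under the tie-aware error, accuracy
degrades monotonically with substitution rate, as it should.

## Annotation transfer

The query inherits only from the ancestry of the induced node: the subfamily
whose root clade contains it (at most one, by the non-nesting invariant),
and every term whose last gain/loss event on the root→induced lineage is a
gain. A loss above a later gain does not cancel it; sibling-clade
annotations never transfer (the query is outside those clades by
construction); a query grafted above the root inherits nothing.

## Enrichment statistics

Over/under-representation uses a 2×2 comparison of a term's frequency in
the uploaded list versus a reference list. The p-value is two-sided by the
minimum-likelihood rule — sum the (hyper)geometric/binomial pmf over every
outcome no more likely than the observed one, with a 1 + 1e-7 relative
tolerance on pmf comparisons so ULP noise cannot decide whether an equally
likely outcome counts. Evaluation is in log space via scipy. One p-value
covers both directions; the direction (sign of k − expected, ties reported
as "over") is a separate column. Correction (BH step-up, Bonferroni, or
none) is applied across the terms actually tested (those with at least one
reference gene), not the full vocabulary.

Value enrichment — "are the values of in-term genes distributed
non-randomly?" — uses a two-sided Mann–Whitney U with tie correction and
continuity correction (scipy's asymptotic method). A rank test is chosen for
distribution-freeness; terms covering all or none of the valued genes are
skipped with a note.

A calibration caveat documented here because it is a property of exact
tests, not of this implementation: under heavy discreteness (e.g. lists of
100 from a reference of 2000) the attained level of an exact two-sided test
at α = 0.05 is strictly below nominal — exact enumeration puts it at
0.03–0.044 depending on term size. The null-calibration check therefore
runs at a near-continuous scale (reference 20 000, lists of 1000, terms of
1000–4000), where the attained level sits within 0.05 ± 0.01; at coarser
scales the package's tests assert validity (rejection rate at or below
nominal), which is the correct property there.

## Enhancer–gene links and variants

Link intervals are BED-style 0-based half-open; VCF positions are 1-based,
so POS *p* hits [start, end) iff start + 1 ≤ p ≤ end. Indels and structural
variants overlap by their anchor POS only, and multi-allelic records are one
position — the evidence tables define enhancers as intervals, and anchor
semantics is the only convention that needs no assumptions about REF/ALT
content. Lookup uses one interval tree per chromosome (chromosome names
normalized by stripping `chr`); a variant hitting nothing still emits a row
so inputs are never silently dropped. Tissue/assay evidence is aggregated
per (variant, enhancer, gene).

## Protein-class ontology

The strict hierarchy is enforced at load: exactly one parent per non-root
class, acyclic, depth ≤ 4 (top level = depth 1), unique ids. OBO terms with
multiple `is_a` parents are violations, never silently pruned. Families map
to exactly one class unless flagged multidomain. Genome summaries roll each
gene up to its class's ancestor at the requested level (a class shallower
than the level rolls to itself); a gene counts once per *distinct* rolled-up
class, so for single-class assignments the level counts partition the
classified genes exactly, and the summary reports how many genes were
multiply counted through multidomain families.

## Synthetic data: what it emulates, and what it does not

Trees are Yule (pure-birth) topologies with i.i.d. exponential branch
lengths (mean 0.1 substitutions/site). Sequences evolve site-independently
under a 20-state Jukes–Cantor-style model: along a branch of length *b*
each site substitutes with probability 1 − exp(−b·rate) to a uniformly
chosen different residue. The default is indel-free, so the true site
homology is the alignment; an optional deletion-only indel mode
(per-branch, never re-inserted) produces gap columns when gap handling
itself is under test. Annotations place each term's gain at one uniform
internal node with independent losses below it. Gene lists are drawn
without replacement with a planted odds ratio via exponential-key order
statistics (equivalent to successive weight-proportional draws).

This is deliberately idealized relative to real protein families: no rate
heterogeneity across sites or lineages, no substitution-matrix structure
(e.g. BLOSUM-like exchangeabilities), no insertions, no alignment error —
the reference MSA is the truth. Passing the placement-recovery tests
therefore demonstrates the correctness and internal consistency of the
machinery under the stated model, not field accuracy on curated families,
which depends on alignment and tree quality the generators do not model.
Conversely, the oracle-equivalence results (placement, propagation,
overlap, validation) are exact combinatorial statements and carry over
unchanged.

Problem sizes in the default suite and acceptance script — 200
leaf-exclusion trials on 64-leaf trees with 300 columns at rate 0.5, 50
trials per rate for the monotonicity curve, 50 families for the placement
oracle sweep, 2000 replicates for null calibration — were chosen as the
smallest sizes at which the Monte-Carlo properties are stable across seeds.

## Known limitations

- The profile model has no insert-state emissions and no local alignment
  mode; very partial queries (domains) pay global gap penalties.
- Placement cost is unweighted parsimony; branch lengths influence nothing
  but the split of the grafted edge.
- The taxon filtering of the original services is reduced to sequence-id
  include-lists; no taxonomy model is included.
- `summarize_genome` requires every family to appear in the assignment
  table (empty assignments mark unclassified families); absent families are
  an error rather than silently unclassified.
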