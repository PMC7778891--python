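"""Seeded generators for every fixture the toolkit needs.

Families are simulated with a known evolutionary history: a Yule (pure-birth)
topology with exponential branch lengths, sequences evolved site-wise under a
20-state Jukes-Cantor-style substitution model, term annotations placed as
gain events with downstream losses, and subfamilies as disjoint clades.
Because the true history is known, held-out-leaf experiments can score
placement and annotation transfer against ground truth.  Gene lists, term
maps, enhancer link tables, VCFs, and protein-class hierarchies (including
deliberately broken ones) are generated the same way.

Every generator is fully deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .placement import ROOT_EDGE, edge_topological_distance, graft
from .profile import AMINO_ACIDS, build_profile
from .profile import score_and_align
from .reference_library import (
    AnnotationRecord,
    FamilyBundle,
    FamilyMSA,
    ReferenceTree,
    TermAnnotationMap,
    TreeNode,
)

__all__ = [
    "simulate_tree",
    "evolve_sequences",
    "simulate_annotations",
    "simulate_subfamilies",
    "simulate_family",
    "LeafExclusionResult",
    "leaf_exclusion_trial",
    "simulate_term_map",
    "simulate_gene_list",
    "simulate_links",
    "write_links_tsv",
    "simulate_vcf",
    "simulate_pc_obo",
]


# ---------------------------------------------------------------------------
# Trees and sequences
# ---------------------------------------------------------------------------


def simulate_tree(n_leaves: int, seed: int, branch_mean: float = 0.1) -> ReferenceTree:
    """Yule (pure-birth) topology: repeatedly split a uniformly chosen tip.

    Branch lengths are i.i.d. exponential with mean ``branch_mean``
    (substitutions/site).  Leaves are named L1..Ln and internal nodes AN1..
    in pre-order.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = {0: TreeNode("0", None, [1, 2])}  # ids temporarily ints
    nodes[1] = TreeNode("1", 0, [])  # type: ignore[arg-type]
    nodes[2] = TreeNode("2", 0, [])  # type: ignore[arg-type]
    tips = [1, 2]
    next_id = 3
    while len(tips) < n_leaves:
        idx = int(rng.integers(len(tips)))
        tip = tips.pop(idx)
        a, b = next_id, next_id + 1
        next_id += 2
        nodes[tip].children = [a, b]
        nodes[a] = TreeNode(str(a), tip, [])  # type: ignore[arg-type]
        nodes[b] = TreeNode(str(b), tip, [])  # type: ignore[arg-type]
        tips.extend([a, b])

    # stable names in pre-order
    names: dict[int, str] = {}
    n_leaf = n_int = 0
    stack = [0]
    order = []
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(nodes[nid].children))  # type: ignore[arg-type]
    for nid in order:
        if nodes[nid].children:
            n_int += 1
            names[nid] = f"AN{n_int}"
        else:
            n_leaf += 1
            names[nid] = f"L{n_leaf}"
    out = {}
    for nid, node in nodes.items():
        bl = None if node.parent is None else float(rng.exponential(0.1) / 0.1 * branch_mean)
        out[names[nid]] = TreeNode(
            names[nid],
            None if node.parent is None else names[node.parent],  # type: ignore[index]
            [names[c] for c in node.children],  # type: ignore[index]
            bl,
        )
    return ReferenceTree(out, names[0])


def evolve_sequences(
    tree: ReferenceTree,
    seq_len: int,
    rate: float,
    seed: int,
    indel_rate: float = 0.0,
    family_id: str = "FAM",
) -> tuple[FamilyMSA, str]:
    """Evolve sequences down the tree; the alignment is the true homology.

    The root sequence is uniform over the 20 amino acids.  Along a branch of
    length b each site substitutes with probability 1 - exp(-b*rate), to a
    uniformly chosen *different* residue.  With ``indel_rate`` > 0, sites are
    additionally deleted (never re-inserted) with probability
    1 - exp(-b*indel_rate) per branch, producing gap columns; the default is
    indel-free.  Returns the leaf MSA and the true root sequence.
    """
    if seq_len < 1 or rate <= 0:
        raise ValueError("seq_len must be >= 1 and rate > 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 20, seq_len)
    seqs: dict[str, np.ndarray] = {tree.root_id: root_seq}
    present: dict[str, np.ndarray] = {tree.root_id: np.ones(seq_len, dtype=bool)}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            continue
        b = node.branch_length if node.branch_length is not None else 1.0
        p_sub = 1.0 - math.exp(-b * rate)
        parent_seq = seqs[node.parent]
        sub = rng.random(seq_len) < p_sub
        seq = parent_seq.copy()
        # uniform over the 19 other residues
        seq[sub] = (parent_seq[sub] + 1 + rng.integers(0, 19, int(sub.sum()))) % 20
        pres = present[node.parent].copy()
        if indel_rate > 0:
            p_del = 1.0 - math.exp(-b * indel_rate)
            pres &= ~(rng.random(seq_len) < p_del)
        seqs[nid] = seq
        present[nid] = pres
    rows = {}
    for leaf in tree.leaves():
        chars = [AMINO_ACIDS[a] if keep else "-" for a, keep in zip(seqs[leaf], present[leaf])]
        rows[leaf] = "".join(chars)
    root_str = "".join(AMINO_ACIDS[a] for a in root_seq)
    return FamilyMSA(family_id, rows), root_str


# ---------------------------------------------------------------------------
# Annotations and subfamilies
# ---------------------------------------------------------------------------


def simulate_annotations(
    tree: ReferenceTree,
    n_terms: int,
    loss_prob: float,
    seed: int,
    gain_prob: float = 1.0,
) -> tuple[TermAnnotationMap, dict[str, set[str]]]:
    """Place each term as one gain at a uniformly chosen internal node, with
    independent losses (probability ``loss_prob``) at internal nodes strictly
    below the gain.  ``gain_prob`` is the chance a term is annotated at all.

    Returns the annotation map and the true per-leaf term sets, computed by
    walking each leaf's root-to-parent lineage.
    """
    rng = np.random.default_rng(seed)
    internals = tree.internal_nodes()
    records: list[AnnotationRecord] = []
    for i in range(n_terms):
        term = f"GO:{i + 1:07d}"
        if rng.random() >= gain_prob:
            continue
        gain_node = internals[int(rng.integers(len(internals)))]
        records.append(AnnotationRecord(gain_node, term, "gain"))
        for nid in internals:
            if nid != gain_node and tree.is_ancestor_or_self(gain_node, nid):
                if rng.random() < loss_prob:
                    records.append(AnnotationRecord(nid, term, "loss"))
    annotations = TermAnnotationMap(records)
    truth: dict[str, set[str]] = {}
    for leaf in tree.leaves():
        active: set[str] = set()
        for nid in reversed(tree.path_to_root(leaf)[1:]):  # root -> parent(leaf)
            active |= annotations.gains.get(nid, set())
            active -= annotations.losses.get(nid, set())
        truth[leaf] = active
    return annotations, truth


def simulate_subfamilies(
    tree: ReferenceTree, n_subfamilies: int, seed: int
) -> dict[str, str]:
    """Pick up to ``n_subfamilies`` disjoint non-root internal clades as
    subfamily roots (greedy over a shuffled candidate list)."""
    rng = np.random.default_rng(seed)
    candidates = [n for n in tree.internal_nodes() if n != tree.root_id]
    rng.shuffle(candidates)
    chosen: list[str] = []
    for cand in candidates:
        if len(chosen) >= n_subfamilies:
            break
        if any(
            tree.is_ancestor_or_self(c, cand) or tree.is_ancestor_or_self(cand, c)
            for c in chosen
        ):
            continue
        chosen.append(cand)
    return {f"SF{i + 1}": nid for i, nid in enumerate(sorted(chosen))}


def simulate_family(
    n_leaves: int = 16,
    seq_len: int = 200,
    rate: float = 0.5,
    n_terms: int = 5,
    loss_prob: float = 0.2,
    n_subfamilies: int = 2,
    seed: int = 0,
    family_id: str = "FAM",
    indel_rate: float = 0.0,
) -> tuple[FamilyBundle, dict[str, set[str]], str]:
    """Simulate a complete, validation-clean family bundle.

    Returns (bundle, per-leaf true term sets, true root sequence).  Seeds for
    the tree, sequences, annotations and subfamilies are derived from
    ``seed`` so distinct components never share a random stream.
    """
    tree = simulate_tree(n_leaves, seed=seed * 4 + 0)
    msa, root_seq = evolve_sequences(
        tree, seq_len, rate, seed=seed * 4 + 1, indel_rate=indel_rate, family_id=family_id
    )
    annotations, truth = simulate_annotations(tree, n_terms, loss_prob, seed=seed * 4 + 2)
    subfamilies = simulate_subfamilies(tree, n_subfamilies, seed=seed * 4 + 3)
    bundle = FamilyBundle(tree, msa, annotations, subfamilies, family_name=family_id)
    problems = bundle.validate()
    if problems:  # pragma: no cover - generator guarantees validity
        raise AssertionError(f"generated bundle invalid: {problems}")
    return bundle, truth, root_seq


# ---------------------------------------------------------------------------
# Leaf-exclusion evaluation
# ---------------------------------------------------------------------------


@dataclass
class LeafExclusionResult:
    leaf_id: str
    true_edge: str
    inferred_edge: str
    topological_distance: int
    tie_contains_true: bool
    delta_cost: int

    @property
    def placement_error(self) -> int:
        """Topological distance to the true edge, counting a cost tie that
        contains the true edge as a perfect recovery (ties are resolved
        rootward by policy, not by evidence)."""
        return 0 if self.tie_contains_true else self.topological_distance


def leaf_exclusion_trial(bundle: FamilyBundle, leaf_id: str) -> LeafExclusionResult:
    """Hold one leaf out, re-place its sequence, and score edge recovery.

    The leaf is pruned (its degree-2 parent suppressed), the profile rebuilt
    from the reduced MSA, the held-out ungapped sequence re-aligned and
    grafted.  The true edge is the one whose split regenerates the original
    topology: the pruned leaf's sibling edge, or the ROOT pseudo-edge when
    the sibling became the root.  Deterministic given the bundle and leaf.
    """
    tree = bundle.tree
    parent = tree.nodes[leaf_id].parent
    if parent is None:
        raise ValueError("cannot hold out the only node")
    siblings = [c for c in tree.nodes[parent].children if c != leaf_id]
    reduced_tree = tree.remove_leaf(leaf_id)
    if len(siblings) == 1:
        sib = siblings[0]
        true_edge = ROOT_EDGE if reduced_tree.root_id == sib else sib
    else:
        # multifurcating parent survives pruning; re-attachment to it is via
        # its own edge
        true_edge = ROOT_EDGE if parent == reduced_tree.root_id else parent

    reduced_rows = {k: v for k, v in bundle.msa.rows.items() if k != leaf_id}
    reduced_msa = FamilyMSA(bundle.msa.family_id, reduced_rows)
    kept_nodes = set(reduced_tree.nodes)
    reduced_ann = TermAnnotationMap(
        [r for r in bundle.annotations.records if r.node_id in kept_nodes]
    )
    reduced_sf = {sf: n for sf, n in bundle.subfamily_roots.items() if n in kept_nodes}
    reduced = FamilyBundle(
        reduced_tree, reduced_msa, reduced_ann, reduced_sf, bundle.family_name
    )

    prof = build_profile(reduced_msa)
    query_seq = bundle.msa.ungapped(leaf_id)
    aligned = score_and_align(query_seq, prof, query_id=leaf_id)
    _, placement = graft(reduced, aligned, query_seq)
    dist = edge_topological_distance(reduced_tree, true_edge, placement.edge)
    return LeafExclusionResult(
        leaf_id=leaf_id,
        true_edge=true_edge,
        inferred_edge=placement.edge,
        topological_distance=dist,
        tie_contains_true=true_edge in placement.tie_edges,
        delta_cost=placement.delta_cost,
    )


# ---------------------------------------------------------------------------
# Gene lists and term maps
# ---------------------------------------------------------------------------


def simulate_term_map(
    genes: list[str], n_terms: int, genes_per_term: int, seed: int
) -> dict[str, set[str]]:
    """Assign each term a uniform random subset of ``genes_per_term`` genes."""
    rng = np.random.default_rng(seed)
    return {
        f"TERM{i + 1:04d}": set(rng.choice(genes, size=genes_per_term, replace=False))
        for i in range(n_terms)
    }


def simulate_gene_list(
    N: int,
    n: int,
    term_map: dict[str, set[str]],
    enriched_term: Optional[str],
    odds: float,
    seed: int,
    genes: Optional[list[str]] = None,
) -> tuple[list[str], list[str]]:
    """Draw a gene list of size n from a reference of N genes, without
    replacement, up-weighting carriers of ``enriched_term`` by ``odds``.

    odds = 1 (or enriched_term None) is the exact null.  Weighted sampling
    without replacement uses exponential-key order statistics, equivalent to
    successive weight-proportional draws.  Returns (list, reference).
    """
    if n > N:
        raise ValueError(f"cannot draw {n} genes from a universe of {N}")
    if genes is None:
        genes = [f"G{i + 1:05d}" for i in range(N)]
    if len(genes) != N:
        raise ValueError("gene universe size must equal N")
    rng = np.random.default_rng(seed)
    carriers = term_map.get(enriched_term, set()) if enriched_term else set()
    weights = np.array([odds if g in carriers else 1.0 for g in genes])
    keys = rng.exponential(1.0, N) / weights  # smallest keys win
    picked = np.argsort(keys, kind="stable")[:n]
    return sorted(genes[i] for i in picked), list(genes)


# ---------------------------------------------------------------------------
# Enhancers / variants
# ---------------------------------------------------------------------------


def simulate_links(
    n_links: int,
    n_genes: int,
    seed: int,
    chroms: tuple[str, ...] = ("1", "2"),
    chrom_len: int = 1_000_000,
):
    """Random enhancer-gene link rows; ~30% of enhancers link a second gene."""
    from .enhancer_links import EnhancerLink

    rng = np.random.default_rng(seed)
    tissues = ["liver", "brain", "heart", "lung"]
    assays = ["ChIA-PET", "eQTL", "Hi-C"]
    links = []
    seen = set()
    i = 0
    while len(links) < n_links:
        i += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - 2000))
        end = start + int(rng.integers(200, 2000))
        enh = f"E{i:05d}"
        n_targets = 2 if rng.random() < 0.3 else 1
        for _ in range(n_targets):
            if len(links) >= n_links:
                break
            gene = f"GENE{int(rng.integers(n_genes)) + 1:04d}"
            tissue = tissues[int(rng.integers(len(tissues)))]
            assay = assays[int(rng.integers(len(assays)))]
            key = (enh, gene, tissue, assay)
            if key in seen:
                continue
            seen.add(key)
            links.append(EnhancerLink(enh, chrom, start, end, gene, tissue, assay))
    return links


def write_links_tsv(links, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tenhancer_id\tgene_id\ttissue\tassay\n")
        for l in links:
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.enhancer_id}\t{l.gene_id}"
                f"\t{l.tissue}\t{l.assay}\n"
            )


def simulate_vcf(
    path,
    n_variants: int,
    seed: int,
    chroms: tuple[str, ...] = ("1", "2"),
    chrom_len: int = 1_000_000,
) -> None:
    """Write a minimal VCF 4.2 of random SNVs and short indels."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={chrom_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for i in range(n_variants):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, chrom_len))
            ref_len = 1 if rng.random() < 0.9 else int(rng.integers(2, 5))
            ref = "".join(bases[int(b)] for b in rng.integers(0, 4, ref_len))
            alt = bases[(bases.index(ref[0]) + 1 + int(rng.integers(3))) % 4]
            rows.append((chrom, pos, f"v{i + 1}", ref, alt))
        for chrom, pos, vid, ref, alt in sorted(rows, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Protein-class hierarchies
# ---------------------------------------------------------------------------


def simulate_pc_obo(
    n_classes: int,
    max_depth: int,
    seed: int,
    planted: Optional[str] = None,
) -> str:
    """OBO text for a random protein-class hierarchy.

    ``planted`` optionally injects a violation: ``multi_parent`` (one term
    with two is_a parents), ``cycle`` (a two-term is_a cycle), or
    ``too_deep`` (a chain one level past ``max_depth``).
    """
    rng = np.random.default_rng(seed)
    ids = [f"PC{i + 1:05d}" for i in range(n_classes)]
    depth: dict[str, int] = {}
    parent: dict[str, Optional[str]] = {}
    for cid in ids:
        shallow = [c for c in depth if depth[c] < max_depth]
        if not shallow or rng.random() < 0.2:
            parent[cid] = None
            depth[cid] = 1
        else:
            p = shallow[int(rng.integers(len(shallow)))]
            parent[cid] = p
            depth[cid] = depth[p] + 1
    extra_is_a: dict[str, list[str]] = {}
    if planted == "multi_parent" and n_classes >= 3:
        child = ids[-1]
        others = [c for c in ids if c != child and c != parent[child]]
        extra_is_a[child] = [others[int(rng.integers(len(others)))]]
    elif planted == "cycle" and n_classes >= 2:
        a, b = ids[-2], ids[-1]
        parent[a], parent[b] = b, a
    elif planted == "too_deep":
        chain = [f"PCD{i + 1:04d}" for i in range(max_depth + 1)]
        for i, cid in enumerate(chain):
            ids.append(cid)
            parent[cid] = chain[i - 1] if i else None
    elif planted is not None:
        raise ValueError(f"unknown planted violation {planted!r}")
    lines = ["format-version: 1.2", "ontology: pc-synthetic", ""]
    for cid in ids:
        lines += [f"[Term]", f"id: {cid}", f"name: class {cid}"]
        if parent[cid] is not None:
            lines.append(f"is_a: {parent[cid]} ! parent")
        for p in extra_is_a.get(cid, []):
            lines.append(f"is_a: {p} ! extra parent")
        lines.append("")
    return "\n".join(lines)
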