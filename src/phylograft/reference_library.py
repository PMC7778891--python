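"""Reference family bundles: trees, alignments, node annotations, subfamilies.

A *family bundle* packages everything the grafting pipeline needs for one
protein family: a rooted reference tree whose internal nodes carry stable
labels (``AN12`` style), the family multiple sequence alignment, a table of
gain/loss term annotations on internal nodes, and the subfamily root nodes.

Trees are read and written in a restricted Newick dialect: unquoted labels
over ``[A-Za-z0-9_.-]``, optional branch lengths, internal labels after the
closing parenthesis.  Quoted labels and comments are deliberately not
supported; reference bundles are machine-generated and the parser stays
auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio import SeqIO

__all__ = [
    "TreeNode",
    "ReferenceTree",
    "FamilyMSA",
    "TermAnnotationMap",
    "FamilyBundle",
    "NewickParseError",
    "ValidationError",
    "parse_newick",
    "serialize_newick",
    "load_family",
    "map_homolog_positions",
]

_LABEL_RE = re.compile(r"[A-Za-z0-9_.\-]+")
_AN_RE = re.compile(r"^AN(\d+)$")


class NewickParseError(ValueError):
    """Raised on malformed Newick input; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class ValidationError(ValueError):
    """Raised when a family bundle violates its invariants.

    ``problems`` lists every violation found, so a bad bundle is reported
    in full rather than failing on the first inconsistency.
    """

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = list(problems)


@dataclass
class TreeNode:
    id: str
    parent: Optional[str]
    children: list[str] = field(default_factory=list)
    #: substitutions/site on the branch above this node; None only at the root
    #: or for trees built without branch lengths.
    branch_length: Optional[float] = None


class ReferenceTree:
    """Rooted tree with uniquely labeled nodes and ordered children.

    Leaves carry sequence identifiers; internal nodes carry stable labels.
    The structure is deliberately minimal: a dict of nodes with parent links
    and ordered child lists, plus the traversals the placement machinery
    needs.
    """

    def __init__(self, nodes: dict[str, TreeNode], root_id: str):
        self.nodes = nodes
        self.root_id = root_id

    # -- queries ---------------------------------------------------------

    def is_leaf(self, node_id: str) -> bool:
        return not self.nodes[node_id].children

    def leaves(self) -> list[str]:
        return [n for n in self.preorder() if self.is_leaf(n)]

    def internal_nodes(self) -> list[str]:
        return [n for n in self.preorder() if not self.is_leaf(n)]

    def preorder(self) -> Iterator[str]:
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self.nodes[nid].children))

    def postorder(self) -> Iterator[str]:
        out: list[str] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        return iter(reversed(out))

    def depth(self, node_id: str) -> int:
        """Number of edges between ``node_id`` and the root."""
        d = 0
        cur = self.nodes[node_id]
        while cur.parent is not None:
            d += 1
            cur = self.nodes[cur.parent]
        return d

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to and including the root."""
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def is_ancestor_or_self(self, ancestor: str, node_id: str) -> bool:
        cur: Optional[str] = node_id
        while cur is not None:
            if cur == ancestor:
                return True
            cur = self.nodes[cur].parent
        return False

    def copy(self) -> "ReferenceTree":
        nodes = {
            nid: TreeNode(n.id, n.parent, list(n.children), n.branch_length)
            for nid, n in self.nodes.items()
        }
        return ReferenceTree(nodes, self.root_id)

    def remove_leaf(self, leaf_id: str) -> "ReferenceTree":
        """Return a copy with ``leaf_id`` removed and its degree-2 parent
        suppressed (branch lengths of the merged edges are summed)."""
        if not self.is_leaf(leaf_id):
            raise ValueError(f"{leaf_id!r} is not a leaf")
        t = self.copy()
        parent_id = t.nodes[leaf_id].parent
        if parent_id is None:
            raise ValueError("cannot remove the only node of the tree")
        parent = t.nodes[parent_id]
        parent.children.remove(leaf_id)
        del t.nodes[leaf_id]
        if len(parent.children) == 1:
            only = t.nodes[parent.children[0]]
            grand = parent.parent
            if grand is None:
                # parent was the root: the remaining child becomes the root
                only.parent = None
                only.branch_length = None
                t.root_id = only.id
            else:
                if only.branch_length is not None and parent.branch_length is not None:
                    only.branch_length += parent.branch_length
                g = t.nodes[grand]
                g.children[g.children.index(parent_id)] = only.id
                only.parent = grand
            del t.nodes[parent_id]
        return t


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> ReferenceTree:
    """Parse a single Newick statement into a :class:`ReferenceTree`.

    Missing branch lengths default to 1.0 (the root never carries one).
    Unlabeled internal nodes are auto-named ``AN<k>`` in pre-order, with the
    counter starting after the largest ``AN`` index already present.
    """
    s = text.strip()
    if not s:
        raise NewickParseError("empty input", 0)
    if not s.endswith(";"):
        raise NewickParseError("missing terminating ';'", len(text))
    s = s[:-1]

    nodes: dict[str, TreeNode] = {}
    anon_count = 0
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def read_label() -> str:
        nonlocal pos
        m = _LABEL_RE.match(s, pos)
        if not m:
            return ""
        pos = m.end()
        return m.group(0)

    def read_branch_length() -> Optional[float]:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[+-]?\d*\.?\d+([eE][+-]?\d+)?", s[pos:])
            if not m:
                raise error("expected branch length after ':'")
            pos += m.end()
            return float(m.group(0))
        return None

    def add_node(label: str, bl: Optional[float], children: list[str]) -> str:
        nonlocal anon_count
        if not label:
            anon_count += 1
            label = f"\x00{anon_count}"  # placeholder, renamed after parse
        if label in nodes:
            raise error(f"duplicate label {label!r}")
        nodes[label] = TreeNode(label, None, children, bl)
        for c in children:
            nodes[c].parent = label
        return label

    def parse_clade() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [parse_clade()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_clade())
            if pos >= len(s) or s[pos] != ")":
                raise error("unbalanced parentheses")
            pos += 1
            label = read_label()
            bl = read_branch_length()
            return add_node(label, bl, children)
        label = read_label()
        if not label:
            raise error("expected a leaf label")
        bl = read_branch_length()
        return add_node(label, bl, [])

    root_id = parse_clade()
    if pos != len(s):
        raise error("trailing characters after tree" if s[pos] != ")" else "unbalanced parentheses")

    tree = ReferenceTree(nodes, root_id)
    # default branch lengths; root carries none
    for nid, node in nodes.items():
        if nid == root_id:
            node.branch_length = None
        elif node.branch_length is None:
            node.branch_length = 1.0
    # rename anonymous internals AN<k> in pre-order, past any existing index
    max_an = 0
    for nid in nodes:
        m = _AN_RE.match(nid)
        if m:
            max_an = max(max_an, int(m.group(1)))
    renames = {}
    k = max_an
    for nid in tree.preorder():
        if nid.startswith("\x00"):
            k += 1
            renames[nid] = f"AN{k}"
    for old, new in renames.items():
        node = nodes.pop(old)
        node.id = new
        nodes[new] = node
        for c in node.children:
            nodes[c].parent = new
        if node.parent is not None:
            p = nodes[node.parent] if node.parent in nodes else nodes[renames[node.parent]]
            p.children[p.children.index(old)] = new
        if tree.root_id == old:
            tree.root_id = new
    return tree


def serialize_newick(tree: ReferenceTree) -> str:
    """Serialize with internal labels and branch lengths to 6 decimals."""

    def emit(nid: str) -> str:
        node = tree.nodes[nid]
        label = node.id
        bl = "" if node.branch_length is None else f":{node.branch_length:.6f}"
        if not node.children:
            return f"{label}{bl}"
        inner = ",".join(emit(c) for c in node.children)
        return f"({inner}){label}{bl}"

    return emit(tree.root_id) + ";"


# ---------------------------------------------------------------------------
# MSA / annotations / bundle
# ---------------------------------------------------------------------------


@dataclass
class FamilyMSA:
    """A family multiple sequence alignment: equal-length gapped rows."""

    family_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError(["MSA rows have unequal lengths"])

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @classmethod
    def from_fasta(cls, path, family_id: str = "") -> "FamilyMSA":
        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(family_id or "family", rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.rows.items():
                fh.write(f">{sid}\n{seq}\n")

    def ungapped(self, sequence_id: str) -> str:
        return self.rows[sequence_id].replace("-", "")


@dataclass(frozen=True)
class AnnotationRecord:
    node_id: str
    term_id: str
    direction: str  # "gain" | "loss"


class TermAnnotationMap:
    """Gain/loss term annotations on internal tree nodes.

    A term gained at a node is inherited by every descendant until a loss of
    the same term intervenes on the path.  A (node, term) pair annotated with
    both gain and loss is a data error and is rejected here, since no
    precedence rule is defined for it.
    """

    def __init__(self, records: list[AnnotationRecord]):
        seen: dict[tuple[str, str], str] = {}
        problems = []
        for r in records:
            if r.direction not in ("gain", "loss"):
                problems.append(f"bad direction {r.direction!r} for {r.node_id}/{r.term_id}")
            key = (r.node_id, r.term_id)
            if key in seen and seen[key] != r.direction:
                problems.append(f"node {r.node_id} has both gain and loss of {r.term_id}")
            seen[key] = r.direction
        if problems:
            raise ValidationError(problems)
        self.records = list(records)
        self.gains: dict[str, set[str]] = {}
        self.losses: dict[str, set[str]] = {}
        for r in records:
            target = self.gains if r.direction == "gain" else self.losses
            target.setdefault(r.node_id, set()).add(r.term_id)

    @classmethod
    def from_tsv(cls, path) -> "TermAnnotationMap":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["node_id", "term_id", "direction"]:
                raise ValidationError([f"bad annotation header: {header}"])
            for line in fh:
                if not line.strip():
                    continue
                node_id, term_id, direction = line.rstrip("\n").split("\t")[:3]
                records.append(AnnotationRecord(node_id, term_id, direction))
        return cls(records)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tterm_id\tdirection\n")
            for r in self.records:
                fh.write(f"{r.node_id}\t{r.term_id}\t{r.direction}\n")


@dataclass
class FamilyBundle:
    """One reference family: tree + MSA + annotations + subfamily roots."""

    tree: ReferenceTree
    msa: FamilyMSA
    annotations: TermAnnotationMap
    subfamily_roots: dict[str, str]  # subfamily_id -> internal node id
    family_name: str = ""

    def validate(self) -> list[str]:
        """Return every invariant violation (empty list = valid bundle)."""
        problems: list[str] = []
        leaf_set = set(self.tree.leaves())
        msa_set = set(self.msa.rows)
        for extra in sorted(msa_set - leaf_set):
            problems.append(f"MSA row {extra!r} absent from tree")
        for missing in sorted(leaf_set - msa_set):
            problems.append(f"tree leaf {missing!r} absent from MSA")
        node_ids = set(self.tree.nodes)
        for r in self.annotations.records:
            if r.node_id not in node_ids:
                problems.append(f"annotation references unknown node {r.node_id!r}")
        roots = list(self.subfamily_roots.items())
        for sf, nid in roots:
            if nid not in node_ids:
                problems.append(f"subfamily {sf!r} root {nid!r} not in tree")
        for i, (sf1, n1) in enumerate(roots):
            for sf2, n2 in roots[i + 1 :]:
                if n1 not in node_ids or n2 not in node_ids or n1 == n2:
                    continue
                if self.tree.is_ancestor_or_self(n1, n2) or self.tree.is_ancestor_or_self(n2, n1):
                    problems.append(f"subfamily roots {sf1!r} and {sf2!r} are nested")
        return problems


def load_family(tree_path, msa_path, annotations_path, subfamilies_path,
                family_name: str = "") -> FamilyBundle:
    """Load and validate a family bundle from its four on-disk pieces.

    Raises :class:`ValidationError` listing every violation; a partially
    valid bundle is never returned.
    """
    with open(tree_path) as fh:
        tree = parse_newick(fh.read())
    msa = FamilyMSA.from_fasta(msa_path, family_id=family_name or "family")
    annotations = TermAnnotationMap.from_tsv(annotations_path)
    subfamily_roots: dict[str, str] = {}
    with open(subfamilies_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["subfamily_id", "node_id"]:
            raise ValidationError([f"bad subfamily header: {header}"])
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            subfamily_roots[parts[0]] = parts[1]
    bundle = FamilyBundle(tree, msa, annotations, subfamily_roots, family_name)
    problems = bundle.validate()
    if problems:
        raise ValidationError(problems)
    return bundle


# ---------------------------------------------------------------------------
# Homolog position mapping
# ---------------------------------------------------------------------------


def map_homolog_positions(
    bundle_or_msa, sequence_id: str, position: int
) -> list[tuple[str, Optional[int]]]:
    """Map an ungapped residue position to all other rows of the alignment.

    ``position`` is the 1-based index of a residue in the *ungapped* sequence
    of ``sequence_id``.  The residue's alignment column is located, and for
    every other row the 1-based ungapped position of the residue in that
    column is returned, or None where that row has a gap.
    """
    msa = bundle_or_msa.msa if isinstance(bundle_or_msa, FamilyBundle) else bundle_or_msa
    if sequence_id not in msa.rows:
        raise KeyError(f"unknown sequence {sequence_id!r}")
    row = msa.rows[sequence_id]
    ungapped_len = len(row) - row.count("-")
    if not 1 <= position <= ungapped_len:
        raise ValueError(
            f"position {position} out of range; valid range is 1..{ungapped_len}"
        )
    seen = 0
    column = -1
    for i, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == position:
                column = i
                break
    out: list[tuple[str, Optional[int]]] = []
    for sid, other in msa.rows.items():
        if sid == sequence_id:
            continue
        if other[column] == "-":
            out.append((sid, None))
        else:
            out.append((sid, column + 1 - other[: column].count("-")))
    return out
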