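"""Transfer subfamily and functional-term annotations to a grafted query.

Both operations read only the ancestry of the induced node: the query sits
outside every clade below the graft edge, so sibling-clade annotations never
transfer.  A query grafted above the root has no ancestral nodes and receives
neither a subfamily nor any terms.
"""

from __future__ import annotations

from typing import Optional

from .placement import ROOT_EDGE, Placement
from .reference_library import FamilyBundle, ReferenceTree, TermAnnotationMap

__all__ = ["assign_subfamily", "propagate_terms"]


def _ancestral_path(tree: ReferenceTree, placement: Placement) -> list[str]:
    """Original-tree nodes on the root -> induced-node path, top-down.

    The induced node splits the edge above ``placement.edge``; its strict
    ancestors are the nodes from the edge's parent up to the root.  For the
    ROOT pseudo-edge the path is empty.
    """
    if placement.edge == ROOT_EDGE:
        return []
    parent = tree.nodes[placement.edge].parent
    if parent is None:
        return []
    return list(reversed(tree.path_to_root(parent)))


def assign_subfamily(placement: Placement, bundle: FamilyBundle) -> Optional[str]:
    """Subfamily whose root clade contains the induced node, or None.

    None means the graft point lies above every subfamily root and only a
    family-level assignment is possible.  More than one hit is impossible for
    a validated bundle (subfamily roots never nest) and raises.
    """
    path = set(_ancestral_path(bundle.tree, placement))
    hits = [sf for sf, root in bundle.subfamily_roots.items() if root in path]
    if len(hits) > 1:
        raise RuntimeError(
            f"internal consistency error: nested subfamilies {sorted(hits)} "
            "both contain the graft point"
        )
    return hits[0] if hits else None


def propagate_terms(
    placement: Placement, annotations: TermAnnotationMap, tree: ReferenceTree
) -> set[str]:
    """Terms inherited by the grafted query from its ancestral lineage.

    Walks the root -> induced-node path top-down, activating each gain and
    deactivating each loss as it is met: a term is inherited iff its most
    recent event on the lineage is a gain.  A loss above a later gain does
    not cancel it; the induced node itself carries no annotations.
    """
    active: set[str] = set()
    for node_id in _ancestral_path(tree, placement):
        active |= annotations.gains.get(node_id, set())
        active -= annotations.losses.get(node_id, set())
    return active
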