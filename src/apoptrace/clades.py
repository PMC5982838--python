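"""Tree interrogation for origin reasoning.

Given a gene tree and a taxonomy, these operations answer the questions the
reconstruction turns on: does a leafset form a monophyletic branch; what is
the sister group of a clade; does the minimal clade around the eukaryotic
members of a family contain eubacterial (but not archaeal) neighbors —
evidence for a mitochondrial/eubacterial origin; did two eukaryotic paralog
clades diverge before eukaryogenesis (each closer to eubacterial homologs
than to the other); and what is the relative chronology of splits, read as
a node-height ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .phylo import leaf_labels, patristic_distances, root_tree
from .seqio import TaxonomyMap

__all__ = [
    "OriginCall",
    "ChronologyEvent",
    "ChronologyReport",
    "bipartition_present",
    "sister_leaves",
    "classify_family_origin",
    "predates_eukaryogenesis",
    "chronology",
]


@dataclass
class OriginCall:
    """Origin classification of a protein family.

    call is one of 'eubacterial', 'archaeal', 'eukaryote_only', 'ambiguous'.
    evidence records the minimal enclosing clade's leaves and the
    non-eukaryotic neighbors found in it or its sister.
    """

    family: str
    call: str
    clade_leaves: frozenset
    noneuk_neighbors: dict = field(default_factory=dict)


def bipartition_present(tree: dendropy.Tree, leafset) -> bool:
    """True iff some edge splits the tree's leaves exactly into ``leafset``
    vs its complement (unrooted monophyly)."""
    leafset = frozenset(leafset)
    all_leaves = leaf_labels(tree)
    if not leafset or not leafset < all_leaves:
        raise ValueError("leafset must be a proper nonempty subset of the tree's leaves")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if below == leafset or below == all_leaves - leafset:
            return True
    return False


def _mrca(tree: dendropy.Tree, leafset: frozenset) -> dendropy.Node:
    """MRCA in the rooted sense: shallowest node whose leaves cover leafset."""
    node = tree.seed_node
    while True:
        nxt = None
        for ch in node.child_nodes():
            below = frozenset(lf.taxon.label for lf in ch.leaf_iter())
            if leafset <= below:
                nxt = ch
                break
        if nxt is None:
            return node
        node = nxt


def sister_leaves(tree: dendropy.Tree, clade_leafset) -> frozenset:
    """Leaves under the sibling of the clade's MRCA in a rooted tree; the
    clade must be monophyletic."""
    clade = frozenset(clade_leafset)
    all_leaves = leaf_labels(tree)
    if not clade <= all_leaves:
        raise ValueError("clade leafset contains labels not in the tree")
    mrca = _mrca(tree, clade)
    below = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
    if below != clade:
        raise ValueError(f"leafset is not monophyletic; MRCA also covers {sorted(below - clade)}")
    parent = mrca.parent_node
    if parent is None:
        raise ValueError("clade is the whole tree; no sister exists")
    sisters: set[str] = set()
    for ch in parent.child_nodes():
        if ch is not mrca:
            sisters.update(lf.taxon.label for lf in ch.leaf_iter())
    return frozenset(sisters)


def _rooted_for_origin(tree: dendropy.Tree, taxonomy: TaxonomyMap) -> dendropy.Tree:
    """Root at archaeal leaves when they are present and form a bipartition
    (archaea as the outside reference); otherwise midpoint."""
    archaea = {
        lab for lab in leaf_labels(tree) if lab in taxonomy and taxonomy.domain_of(lab) == "Archaea"
    }
    if archaea:
        try:
            return root_tree(tree, mode="outgroup", outgroup=archaea)
        except ValueError:
            pass
    return root_tree(tree, mode="midpoint")


def classify_family_origin(
    tree: dendropy.Tree,
    family_leaves,
    taxonomy: TaxonomyMap,
    family: str = "",
) -> OriginCall:
    """Classify a family's origin from the composition of the minimal clade
    containing its eukaryotic members, plus that clade's sister.

    eubacterial: eubacterial leaves present there and archaeal absent;
    archaeal: the reverse; eukaryote_only: no eubacterial or archaeal leaves
    at all; ambiguous: both present.
    """
    family_leaves = frozenset(family_leaves)
    for lab in family_leaves:
        if lab not in taxonomy:
            raise KeyError(f"leaf {lab!r} missing from taxonomy")
    euk = frozenset(lab for lab in family_leaves if taxonomy.is_eukaryote(lab))
    if not euk:
        raise ValueError("family has no eukaryotic leaves; origin call undefined")
    rooted = _rooted_for_origin(tree, taxonomy)
    mrca = _mrca(rooted, euk)
    clade = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
    if mrca.parent_node is not None:
        sis = sister_leaves(rooted, clade)
    else:
        sis = frozenset()
    neighborhood = (clade | sis) - euk
    for lab in neighborhood:
        if lab not in taxonomy:
            raise KeyError(f"leaf {lab!r} missing from taxonomy")
    domains = {lab: taxonomy.domain_of(lab) for lab in neighborhood}
    has_bact = any(d == "Eubacteria" for d in domains.values())
    has_arch = any(d == "Archaea" for d in domains.values())
    if has_bact and not has_arch:
        call = "eubacterial"
    elif has_arch and not has_bact:
        call = "archaeal"
    elif not has_bact and not has_arch:
        call = "eukaryote_only"
    else:
        call = "ambiguous"
    noneuk = {lab: d for lab, d in domains.items() if d != "Eukaryota"}
    return OriginCall(family=family, call=call, clade_leaves=clade, noneuk_neighbors=noneuk)


def predates_eukaryogenesis(
    tree: dendropy.Tree,
    clade_a,
    clade_b,
    taxonomy: TaxonomyMap,
    mode: str = "mean",
) -> bool:
    """True iff two disjoint eukaryotic paralog clades each lie closer to
    eubacterial homologs than to each other, and the pair does not form a
    bipartition excluding all eubacterial leaves.

    mode='mean' (default) compares mean patristic distances; mode='nearest'
    uses single nearest-leaf distances.
    """
    A = frozenset(clade_a)
    B = frozenset(clade_b)
    if A & B:
        raise ValueError("clades must be disjoint")
    labels, d = patristic_distances(tree)
    pos = {lab: k for k, lab in enumerate(labels)}
    for lab in A | B:
        if lab not in pos:
            raise ValueError(f"leaf {lab!r} not in tree")
        if not taxonomy.is_eukaryote(lab):
            raise ValueError(f"leaf {lab!r} is not eukaryotic")
    bact = [lab for lab in labels if lab in taxonomy and taxonomy.domain_of(lab) == "Eubacteria"]
    if not bact:
        raise ValueError("no eubacterial leaves in tree; divergence test undefined")

    ia = [pos[x] for x in A]
    ib = [pos[x] for x in B]
    cross = d[np.ix_(ia, ib)]
    if mode == "mean":
        d_ab = float(cross.mean())
        d_a_bact = min(float(d[np.ix_(ia, [pos[e]])].mean()) for e in bact)
        d_b_bact = min(float(d[np.ix_(ib, [pos[e]])].mean()) for e in bact)
    elif mode == "nearest":
        d_ab = float(cross.min())
        d_a_bact = min(float(d[i, pos[e]]) for i in ia for e in bact)
        d_b_bact = min(float(d[i, pos[e]]) for i in ib for e in bact)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    closer = d_a_bact < d_ab and d_b_bact < d_ab
    union = A | B
    forms_clade = union < leaf_labels(tree) and bipartition_present(tree, union)
    return closer and not forms_clade


@dataclass
class ChronologyEvent:
    height: float
    child_leafsets: list[frozenset]
    preorder_index: int


@dataclass
class ChronologyReport:
    """Internal splits ordered by decreasing node height (mean path length
    from node to its descendant leaves); ties broken by preorder."""

    events: list[ChronologyEvent]

    def first(self) -> ChronologyEvent:
        return self.events[0]


def chronology(tree: dendropy.Tree) -> ChronologyReport:
    if not tree.is_rooted:
        raise ValueError("chronology requires a rooted tree")
    events = []
    for k, nd in enumerate(tree.preorder_node_iter()):
        if nd.is_leaf():
            continue
        if nd.parent_node is not None and nd.edge.length is None:
            raise ValueError("chronology requires branch lengths on all edges")
        # mean path length to descendant leaves
        total = 0.0
        count = 0
        stack = [(nd, 0.0)]
        while stack:
            cur, dist = stack.pop()
            if cur.is_leaf():
                total += dist
                count += 1
                continue
            for ch in cur.child_nodes():
                if ch.edge.length is None:
                    raise ValueError("chronology requires branch lengths on all edges")
                stack.append((ch, dist + ch.edge.length))
        height = total / count
        child_sets = [
            frozenset(lf.taxon.label for lf in ch.leaf_iter()) for ch in nd.child_nodes()
        ]
        events.append(ChronologyEvent(height=height, child_leafsets=child_sets, preorder_index=k))
    events.sort(key=lambda e: (-e.height, e.preorder_index))
    return ChronologyReport(events=events)
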