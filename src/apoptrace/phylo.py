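"""Distance-based gene-tree inference with bootstrap support.

The pipeline builds trees by the classical chain: per-pair p-distances with
pairwise deletion of gap columns, Poisson correction d = -ln(1 - p), and
Saitou-Nei neighbor joining.  Bootstrap support for the reference tree's
internal edges is the percentage of column-resampled replicates whose NJ
tree contains the same bipartition.

Neighbor joining here is deterministic: Q-matrix ties are broken by the
smallest (row, column) index pair, and negative branch-length estimates are
clamped to zero with the deficit moved to the sister branch so patristic
orderings stay monotone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import MultipleAlignment

__all__ = [
    "DistanceMatrix",
    "BootstrapSpec",
    "p_distance_matrix",
    "poisson_distance",
    "poisson_correct",
    "neighbor_joining",
    "bootstrap_support",
    "root_tree",
    "leaf_labels",
    "edge_bipartitions",
    "nontrivial_bipartitions",
    "patristic_distances",
]

_GAP_BYTES = frozenset(b"-.")
POISSON_CLAMP = 10.0


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix has non-finite entries")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class BootstrapSpec:
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# distances


def _encode(aln: MultipleAlignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = aln.ids
    mat = np.array(
        [np.frombuffer(s.upper().encode(), dtype=np.uint8) for _, s in aln.rows]
    )
    is_gap = (mat == ord("-")) | (mat == ord("."))
    return labels, mat, is_gap


def p_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    """Per-pair fraction of mismatching residues, comparing only columns
    where both rows have residues (pairwise deletion)."""
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows for a distance matrix")
    labels, mat, is_gap = _encode(aln)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~is_gap[i] & ~is_gap[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(labels=labels, values=d)


def poisson_distance(p: float, clamp: float = POISSON_CLAMP) -> float:
    """Poisson-corrected protein distance -ln(1 - p); saturated values
    (p >= 1) are clamped with a warning."""
    if p < 0:
        raise ValueError(f"p-distance must be >= 0, got {p}")
    if p >= 1.0:
        warnings.warn(f"saturated p-distance {p}; clamping corrected distance to {clamp}")
        return clamp
    return min(-math.log1p(-p), clamp)


def poisson_correct(D: DistanceMatrix, clamp: float = POISSON_CLAMP) -> DistanceMatrix:
    vals = np.array(
        [[poisson_distance(p, clamp) if i != j else 0.0 for j, p in enumerate(row)]
         for i, row in enumerate(D.values)]
    )
    return DistanceMatrix(labels=list(D.labels), values=vals)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted tree (seed node is
    the final trifurcation)."""
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(list(D.labels))
    nodes: list[dendropy.Node] = []
    for lab in D.labels:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(lab)
        nodes.append(nd)
    d = D.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair among the minima, row-major
        i, j = map(int, np.unravel_index(np.argmin(q, axis=None), q.shape))
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negative estimates, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal three-cluster star
    a, b, c = range(3)
    center = dendropy.Node()
    lengths = (
        0.5 * (d[a, b] + d[a, c] - d[b, c]),
        0.5 * (d[a, b] + d[b, c] - d[a, c]),
        0.5 * (d[a, c] + d[b, c] - d[a, b]),
    )
    for node, ln in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = center
    tree.is_rooted = False
    for nd in tree.preorder_node_iter():
        nd.support = getattr(nd, "support", None)
    return tree


# ---------------------------------------------------------------------------
# tree utilities


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def edge_bipartitions(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map every edge of the tree (viewed unrooted) to its length, keyed by
    a canonical leafset: the side not containing the lexicographically first
    leaf.  The two edges meeting at a degree-2 root are merged."""
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    out: dict[frozenset, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if not below or below == all_leaves:
            continue
        key = below if ref not in below else all_leaves - below
        length = nd.edge.length or 0.0
        out[key] = out.get(key, 0.0) + length
    return out


def nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical internal bipartitions (both sides with >= 2 leaves)."""
    all_leaves = leaf_labels(tree)
    return {
        key
        for key in edge_bipartitions(tree)
        if 2 <= len(key) <= len(all_leaves) - 2
    }


def patristic_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix (sum of branch lengths)."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    labels = [lf.taxon.label for lf in leaves]
    # path to the seed node for each leaf, as dict node -> cumulative length
    paths: list[dict[int, float]] = []
    for lf in leaves:
        acc: dict[int, float] = {}
        total = 0.0
        nd = lf
        while nd is not None:
            acc[id(nd)] = total
            total += nd.edge.length or 0.0
            nd = nd.parent_node
        paths.append(acc)
    # depth from seed node
    depth: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # deepest common node of the two root-paths
            common = [k for k in paths[i] if k in paths[j]]
            mrca = max(common, key=lambda k: depth[k])
            d[i, j] = d[j, i] = paths[i][mrca] + paths[j][mrca]
    return labels, d


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(aln: MultipleAlignment, spec: BootstrapSpec) -> dendropy.Tree:
    """Annotate the full-alignment NJ tree with bootstrap supports.

    Columns are resampled with replacement (same alignment length) per
    replicate; each replicate tree is rebuilt by the same p-distance ->
    Poisson -> NJ chain.  Support of an internal edge is the percentage of
    successful replicates containing its bipartition.  Replicates whose
    distance matrix is undefined are skipped (counted and warned).
    """
    ref = neighbor_joining(poisson_correct(p_distance_matrix(aln)))
    ref_bips = nontrivial_bipartitions(ref)
    counts = {bip: 0 for bip in ref_bips}
    rng = np.random.default_rng(spec.seed)
    succeeded = 0
    skipped = 0
    ncol = aln.length
    for _ in range(spec.replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = aln.select_columns([int(k) for k in idx])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = neighbor_joining(poisson_correct(p_distance_matrix(rep)))
        except ValueError:
            skipped += 1
            continue
        succeeded += 1
        found = nontrivial_bipartitions(t)
        for bip in ref_bips & found:
            counts[bip] += 1
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicate(s) skipped (undefined distances)")
    all_leaves = leaf_labels(ref)
    refmin = min(all_leaves)
    for nd in ref.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            nd.support = None
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = below if refmin not in below else all_leaves - below
        if key in counts:
            nd.support = 100.0 * counts[key] / succeeded if succeeded else 0.0
        else:
            nd.support = None
    return ref


# ---------------------------------------------------------------------------
# rooting


def _reroot_at_midpoint(tree: dendropy.Tree) -> None:
    """Reroot in place at the midpoint of the longest leaf-to-leaf path.

    Done explicitly (walk the extreme path, split the straddling edge)
    so that symmetric and zero-length-edge cases stay exact.
    """
    labels, d = patristic_distances(tree)
    i, j = map(int, np.unravel_index(np.argmax(d), d.shape))
    half = d[i, j] / 2.0
    by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    a, b = by_label[labels[i]], by_label[labels[j]]

    chain_a = []
    nd = a
    while nd is not None:
        chain_a.append(nd)
        nd = nd.parent_node
    chain_b = []
    nd = b
    while nd is not None:
        chain_b.append(nd)
        nd = nd.parent_node
    in_a = {id(x): k for k, x in enumerate(chain_a)}
    mrca_k = next(k for k, x in enumerate(chain_b) if id(x) in in_a)
    mrca = chain_b[mrca_k]
    # ordered node path a -> mrca -> b
    path = chain_a[: in_a[id(mrca)] + 1] + list(reversed(chain_b[:mrca_k]))

    tol = 1e-9
    cum = 0.0
    for prev, nxt in zip(path, path[1:]):
        # the edge between prev and nxt belongs to whichever is the child
        child = nxt if nxt.parent_node is prev else prev
        length = child.edge.length or 0.0
        if abs(cum - half) <= tol:
            if prev is not tree.seed_node:
                tree.reroot_at_node(prev)
            return
        if cum < half < cum + length:
            cum_head = cum if child is prev else cum + length
            cum_tail = cum + length if child is prev else cum
            tree.reroot_at_edge(
                child.edge,
                length1=abs(half - cum_tail),
                length2=abs(half - cum_head),
            )
            return
        cum += length
    # midpoint at the far end of the path
    if path[-1] is not tree.seed_node:
        tree.reroot_at_node(path[-1])


def root_tree(
    tree: dendropy.Tree,
    mode: str = "midpoint",
    outgroup: set[str] | None = None,
) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of the longest leaf-to-leaf
    path, or on the edge subtending the given outgroup leafset (which must
    form a bipartition).  Leaf-to-leaf patristic distances are unchanged."""
    rooted = tree.clone(depth=1)
    if mode == "midpoint":
        _reroot_at_midpoint(rooted)
    elif mode == "outgroup":
        if not outgroup:
            raise ValueError("outgroup mode requires a nonempty outgroup leafset")
        all_leaves = leaf_labels(rooted)
        og = frozenset(outgroup)
        missing = og - all_leaves
        if missing:
            raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
        target = None
        for nd in rooted.preorder_node_iter():
            if nd.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if below == og or (all_leaves - below) == og:
                target = nd if below == og else nd
                break
        if target is None:
            raise ValueError("outgroup does not form a bipartition of the tree")
        ln = target.edge.length or 0.0
        rooted.reroot_at_edge(target.edge, length1=ln / 2.0, length2=ln / 2.0)
    else:
        raise ValueError(f"unknown rooting mode {mode!r}")
    rooted.is_rooted = True
    for nd in rooted.preorder_node_iter():
        if not hasattr(nd, "support"):
            nd.support = None
    return rooted
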