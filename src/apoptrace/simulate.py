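"""Synthetic-data generators with known ground truth.

Three generators cover the pipeline's stages:

* Dollo-style gene-content evolution on a rooted tree: the character
  starts at the root in a chosen state and is lost independently on each
  edge with a fixed probability; a lost character is never regained.

* Protein sequence evolution under the 20-state uniform-exchange model
  (the amino-acid analogue of Jukes-Cantor): sites are independent, and
  along a branch of length d the probability that a site ends in its
  starting state is 1/20 + (19/20) exp(-(20/19) d), so two tips separated
  by total path d have expected p-distance (19/20)(1 - exp(-(20/19) d)).
  The uniform model keeps those expectations in closed form, which the
  statistical tests exploit.

* Endosymbiosis scenarios: gene trees whose eukaryotic tips nest inside a
  eubacterial clade (optionally as two pre-eukaryotic paralog clades with
  distinct bacterial sisters, and optionally with an archaeal outgroup),
  together with a matching taxonomy and truth labels for the downstream
  origin, divergence and ancestral-presence calls.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import (
    AMINO_ACIDS,
    EUKARYOTIC_SUPERGROUPS,
    MultipleAlignment,
    TaxonomyMap,
    read_newick,
)

__all__ = [
    "ContentSimParams",
    "SeqSimParams",
    "EndosymbiosisScenario",
    "random_tree",
    "simulate_gene_content",
    "simulate_alignment",
    "simulate_endosymbiosis",
]


def random_tree(
    labels,
    seed: int = 0,
    min_branch: float = 0.1,
    max_branch: float = 1.0,
) -> dendropy.Tree:
    """Random rooted binary tree over the given leaf labels: topology by
    uniform sequential joins, branch lengths uniform in
    [min_branch, max_branch]."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(lab)
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(min_branch, max_branch))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        nd.support = None
    return tree


@dataclass
class ContentSimParams:
    tree: dendropy.Tree
    root_present: bool = True
    loss_prob_per_edge: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_prob_per_edge < 1.0:
            raise ValueError("loss_prob_per_edge must be in [0, 1)")


def simulate_gene_content(params: ContentSimParams):
    """Evolve a presence/absence character down the tree with independent
    per-edge loss and no regain.

    Returns (tip_presence, node_states): presence by leaf label, and true
    states keyed by each node's descendant leafset.
    """
    rng = np.random.default_rng(params.seed)
    state: dict[int, bool] = {}
    node_states: dict[frozenset, bool] = {}
    below: dict[int, frozenset] = {}
    for nd in params.tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
    tip_presence: dict[str, bool] = {}
    for nd in params.tree.preorder_node_iter():
        if nd.parent_node is None:
            s = params.root_present
        else:
            s = state[id(nd.parent_node)]
            if s and rng.random() < params.loss_prob_per_edge:
                s = False
        state[id(nd)] = s
        node_states[below[id(nd)]] = s
        if nd.is_leaf():
            tip_presence[nd.taxon.label] = s
    return tip_presence, node_states


@dataclass
class SeqSimParams:
    tree: dendropy.Tree
    length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")


def simulate_alignment(params: SeqSimParams) -> MultipleAlignment:
    """Simulate a gapless protein alignment along the tree under the
    20-state uniform-exchange substitution process."""
    rng = np.random.default_rng(params.seed)
    L = params.length
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    seqs: dict[int, np.ndarray] = {}
    rows: list[tuple[str, str]] = []
    for nd in params.tree.preorder_node_iter():
        if nd.parent_node is None:
            seq = rng.integers(0, 20, size=L)
        else:
            d = nd.edge.length or 0.0
            p_same = 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-(20.0 / 19.0) * d)
            parent = seqs[id(nd.parent_node)]
            seq = parent.copy()
            change = rng.random(L) >= p_same
            n_change = int(change.sum())
            if n_change:
                # draw uniformly among the 19 other states
                shift = rng.integers(1, 20, size=n_change)
                seq[change] = (seq[change] + shift) % 20
        seqs[id(nd)] = seq
        if nd.is_leaf():
            rows.append((nd.taxon.label, aa[seq].tobytes().decode()))
    return MultipleAlignment(rows=rows)


@dataclass
class EndosymbiosisScenario:
    n_bacterial: int = 6
    euk_groups: tuple = ("Opisthokonta", "SAR")
    pre_eukaryotic_duplication: bool = False
    include_archaea_outgroup: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bacterial < 2:
            raise ValueError("need at least 2 bacterial leaves")
        if not self.euk_groups:
            raise ValueError("euk_groups must be nonempty")
        bad = set(self.euk_groups) - set(EUKARYOTIC_SUPERGROUPS)
        if bad:
            raise ValueError(f"unknown supergroups {sorted(bad)}")


def _caterpillar(labels: list[str], tip_len, internal_len, jitter) -> str:
    """Newick fragment: a ladder over the given labels."""
    sub = f"{labels[0]}:{jitter(tip_len):.6f}"
    for lab in labels[1:]:
        sub = f"({sub},{lab}:{jitter(tip_len):.6f}):{jitter(internal_len):.6f}"
    return sub


def simulate_endosymbiosis(scn: EndosymbiosisScenario):
    """Build a gene tree in which the eukaryotic family members descend
    from a eubacterial donor clade.

    Returns (tree, taxonomy, truth).  truth carries the expected downstream
    calls: origin 'eubacterial', whether the two paralog clades predate
    eukaryogenesis, ancestral presence, and the leafsets of the paralog
    clades ('clade_a', 'clade_b' when duplicated).

    The origin truth refers to the family (each paralog clade nests among
    eubacteria).  With ``pre_eukaryotic_duplication`` the minimal clade
    spanning *all* eukaryotic members covers the whole duplicated core, so
    a whole-family origin call may legitimately see the archaeal outgroup
    as sister; classify each paralog clade separately to recover the
    eubacterial signal.
    """
    rng = np.random.default_rng(scn.seed)

    def jitter(x: float) -> float:
        return x * rng.uniform(0.8, 1.2)

    groups = list(scn.euk_groups)

    def euk_clade(suffix: str) -> tuple[str, list[str]]:
        labels = [f"{g}_{suffix}" for g in groups]
        if len(labels) == 1:
            return f"{labels[0]}:{jitter(0.15):.6f}", labels
        return _caterpillar(labels, 0.15, 0.08, jitter), labels

    n = scn.n_bacterial
    bact = [f"Bact{i + 1}" for i in range(n)]

    if scn.pre_eukaryotic_duplication:
        half = max(1, n // 2)
        b1, b2 = bact[:half], bact[half:]
        if not b2:
            b2 = [bact[-1]]
        eukA, labelsA = euk_clade("A")
        eukB, labelsB = euk_clade("B")
        sub1 = f"(({eukA},{ _caterpillar(b1, 0.12, 0.06, jitter)}):{jitter(0.10):.6f})"
        sub2 = f"(({eukB},{ _caterpillar(b2, 0.12, 0.06, jitter)}):{jitter(0.10):.6f})"
        core = f"({sub1}:{jitter(0.45):.6f},{sub2}:{jitter(0.45):.6f})"
        clade_a, clade_b = labelsA, labelsB
    else:
        half = max(1, n // 2)
        b_sister, b_outer = bact[:half], bact[half:]
        eukA, labelsA = euk_clade("A")
        inner = f"({eukA},{_caterpillar(b_sister, 0.12, 0.06, jitter)}):{jitter(0.15):.6f}"
        if b_outer:
            core = f"(({inner}),{_caterpillar(b_outer, 0.12, 0.06, jitter)}):{jitter(0.15):.6f}"
        else:
            core = f"({inner})"
        clade_a, clade_b = labelsA, []

    if scn.include_archaea_outgroup:
        newick = f"(({core}):{jitter(0.5):.6f},Arch1:{jitter(0.25):.6f},Arch2:{jitter(0.25):.6f});"
        arch = ["Arch1", "Arch2"]
    else:
        newick = f"({core});"
        arch = []

    tree = read_newick(newick)
    tree.is_rooted = False
    # prune degree-2 internal nodes introduced by string assembly
    tree.suppress_unifurcations()

    species_to_group: dict[str, str] = {}
    seq_to_species: dict[str, str] = {}
    for lab in clade_a + clade_b:
        seq_to_species[lab] = lab
        species_to_group[lab] = lab.rsplit("_", 1)[0]
    for lab in bact:
        seq_to_species[lab] = lab
        species_to_group[lab] = "Eubacteria"
    for lab in arch:
        seq_to_species[lab] = lab
        species_to_group[lab] = "Archaea"
    taxonomy = TaxonomyMap(seq_to_species, species_to_group)

    truth = {
        "origin": "eubacterial",
        "predates": scn.pre_eukaryotic_duplication,
        "ancestral": True,  # eubacterial presence always satisfies the rule here
        "clade_a": clade_a,
        "clade_b": clade_b,
        "euk_groups": groups,
    }
    return tree, taxonomy, truth
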