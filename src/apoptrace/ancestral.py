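"""Ancestral gene-content reconstruction at LECA.

Family membership is collapsed to a families x lineage-groups boolean
presence matrix (the five ancient eukaryotic supergroups — Opisthokonta,
Amoebozoa, SAR, Excavata, Archaeplastida — plus Eubacteria, Archaea and
Virus).  Two reconstructions are computed per family:

* the explicit parsimony rule: a family is ancestral if it is present in at
  least ``k`` (default 2) eukaryotic supergroups, or in Eubacteria, or in
  Archaea.  Viral presence alone never triggers the rule, since viral
  homologs are best explained by acquisition from hosts.

* Dollo parsimony on a rooted supergroup tree: the character is gained
  exactly once at the MRCA of the supergroups carrying it, and the minimal
  number of loss edges needed to explain the absences is counted.  The
  family is ancestrally present iff the gain node is the root (LECA).

On the default star-shaped supergroup tree the two criteria agree whenever
no prokaryotic evidence is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .clades import OriginCall
from .seqio import EUKARYOTIC_SUPERGROUPS, NONEUKARYOTIC_GROUPS, TaxonomyMap, read_newick

__all__ = [
    "PresenceMatrix",
    "DolloResult",
    "FamilyReconstruction",
    "AncestralReport",
    "default_supergroup_tree",
    "collapse_to_groups",
    "ancestral_by_rule",
    "dollo_reconstruct",
    "reconstruct_repertoire",
]


@dataclass
class PresenceMatrix:
    """Families x lineage groups boolean table (thin pandas wrapper)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate family tokens in presence matrix")
        if self.table.columns.has_duplicates:
            raise ValueError("duplicate group tokens in presence matrix")
        self.table = self.table.astype(bool)

    @property
    def families(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> list[str]:
        return list(self.table.columns)

    def row(self, family: str) -> pd.Series:
        return self.table.loc[family]

    @classmethod
    def from_dict(cls, rows: Mapping[str, Mapping[str, bool]], groups=None) -> "PresenceMatrix":
        groups = list(groups) if groups else list(EUKARYOTIC_SUPERGROUPS + NONEUKARYOTIC_GROUPS)
        df = pd.DataFrame(
            [[bool(r.get(g, False)) for g in groups] for r in rows.values()],
            index=list(rows.keys()),
            columns=groups,
        )
        return cls(df)

    @classmethod
    def from_tsv(cls, source) -> "PresenceMatrix":
        df = pd.read_csv(source, sep="\t", index_col=0, comment="#")
        return cls(df.astype(int).astype(bool))

    def to_tsv(self, path=None) -> str:
        text = self.table.astype(int).to_csv(sep="\t")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def default_supergroup_tree() -> dendropy.Tree:
    """Five-supergroup star rooted at LECA (used when no resolved eukaryote
    topology is supplied)."""
    newick = "(" + ",".join(f"{g}:1.0" for g in EUKARYOTIC_SUPERGROUPS) + "):0.0;"
    tree = read_newick(newick)
    tree.is_rooted = True
    return tree


def collapse_to_groups(
    family_members: Mapping[str, Iterable[str]],
    taxonomy: TaxonomyMap,
    groups=None,
) -> PresenceMatrix:
    """Presence matrix with cell (family, group) true iff at least one
    member id maps to that group."""
    groups = list(groups) if groups else list(taxonomy.eukaryotic_groups) + list(
        NONEUKARYOTIC_GROUPS
    )
    rows = {}
    for fam, members in family_members.items():
        row = {g: False for g in groups}
        for mid in members:
            if mid not in taxonomy:
                raise KeyError(f"family {fam!r}: member id {mid!r} not in taxonomy")
            g = taxonomy.group_of(mid)
            if g not in row:
                raise ValueError(f"group {g!r} of member {mid!r} not among matrix groups")
            row[g] = True
        rows[fam] = row
    return PresenceMatrix.from_dict(rows, groups=groups)


def ancestral_by_rule(
    row: Mapping[str, bool],
    k: int = 2,
    eukaryotic_groups=EUKARYOTIC_SUPERGROUPS,
) -> bool:
    """Parsimony rule for ancestral presence: >= k eukaryotic supergroups,
    or any eubacterial or archaeal presence.  Viral-only presence does not
    count."""
    n_euk = sum(1 for g in eukaryotic_groups if row.get(g, False))
    prok = bool(row.get("Eubacteria", False)) or bool(row.get("Archaea", False))
    return n_euk >= k or prok


@dataclass
class DolloResult:
    root_state: bool
    losses: int
    #: reconstructed presence per node, keyed by the node's descendant leafset
    node_states: dict = field(default_factory=dict)


def dollo_reconstruct(
    row: Mapping[str, bool],
    tree: dendropy.Tree,
) -> DolloResult:
    """Dollo parsimony on the supergroup tree: single gain at the MRCA of
    the present leaves, minimal losses covering the absences.

    Returns root state (true iff the gain sits at the root), the loss
    count, and per-node states keyed by descendant leafsets.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    present = {lab for lab in leaves if row.get(lab, False)}
    node_states: dict[frozenset, bool] = {}

    # subtree leafsets and present-leaf counts, bottom-up
    below: dict[int, frozenset] = {}
    npresent: dict[int, int] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
            npresent[id(nd)] = 1 if nd.taxon.label in present else 0
        else:
            kids = nd.child_nodes()
            below[id(nd)] = frozenset().union(*(below[id(c)] for c in kids))
            npresent[id(nd)] = sum(npresent[id(c)] for c in kids)

    if not present:
        for nd in tree.preorder_node_iter():
            node_states[below[id(nd)]] = False
        return DolloResult(root_state=False, losses=0, node_states=node_states)

    # gain node: MRCA of present leaves (walk down while a child covers all)
    gain = tree.seed_node
    while True:
        nxt = None
        for ch in gain.child_nodes():
            if npresent[id(ch)] == len(present):
                nxt = ch
                break
        if nxt is None:
            break
        gain = nxt

    # state: present iff within the gain subtree and own subtree has a
    # present leaf; losses = edges into maximal absent subtrees
    losses = 0
    in_gain: set[int] = set()
    stack = [gain]
    while stack:
        nd = stack.pop()
        in_gain.add(id(nd))
        stack.extend(nd.child_nodes())
    for nd in tree.preorder_node_iter():
        state = id(nd) in in_gain and npresent[id(nd)] > 0
        node_states[below[id(nd)]] = state
        if state:
            for ch in nd.child_nodes():
                if npresent[id(ch)] == 0:
                    losses += 1
    root_state = gain is tree.seed_node
    return DolloResult(root_state=root_state, losses=losses, node_states=node_states)


@dataclass
class FamilyReconstruction:
    family: str
    category: str | None
    groups_present: list[str]
    n_euk_groups: int
    prokaryote_evidence: bool
    ancestral: bool
    dollo_root: bool
    dollo_losses: int
    origin: OriginCall | None = None

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "category": self.category,
            "groups_present": self.groups_present,
            "n_euk_groups": self.n_euk_groups,
            "prokaryote_evidence": self.prokaryote_evidence,
            "ancestral": self.ancestral,
            "dollo_root": self.dollo_root,
            "dollo_losses": self.dollo_losses,
        }
        if self.origin is not None:
            d["origin"] = {
                "call": self.origin.call,
                "noneuk_neighbors": dict(sorted(self.origin.noneuk_neighbors.items())),
            }
        return d


@dataclass
class AncestralReport:
    """Per-family reconstruction plus category-level tallies."""

    families: list[FamilyReconstruction]

    def ancestral_families(self) -> list[str]:
        return [f.family for f in self.families if f.ancestral]

    def category_counts(self, ancestral_only: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.families:
            if ancestral_only and not f.ancestral:
                continue
            cat = f.category or "uncategorized"
            counts[cat] = counts.get(cat, 0) + 1
        return dict(sorted(counts.items()))

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([f.to_dict() for f in self.families]).set_index("family")

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "families": [f.to_dict() for f in self.families],
            "ancestral_families": self.ancestral_families(),
            "category_counts_ancestral": self.category_counts(),
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def reconstruct_repertoire(
    matrix: PresenceMatrix,
    tree: dendropy.Tree | None = None,
    origin_calls: Mapping[str, OriginCall] | None = None,
    k: int = 2,
    categories: Mapping[str, str] | None = None,
    eukaryotic_groups=EUKARYOTIC_SUPERGROUPS,
) -> AncestralReport:
    """Combine the parsimony rule, Dollo reconstruction and (optional)
    origin calls into a per-family ancestral report."""
    tree = tree if tree is not None else default_supergroup_tree()
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [g for g in eukaryotic_groups if g in matrix.groups and g not in tree_leaves]
    if missing:
        raise ValueError(f"supergroup tree lacks leaves for groups {missing}")
    out = []
    for fam in matrix.families:
        row = matrix.row(fam).to_dict()
        euk_present = [g for g in eukaryotic_groups if row.get(g, False)]
        prok = bool(row.get("Eubacteria", False)) or bool(row.get("Archaea", False))
        rule = ancestral_by_rule(row, k=k, eukaryotic_groups=eukaryotic_groups)
        dollo = dollo_reconstruct(row, tree)
        origin = origin_calls.get(fam) if origin_calls else None
        present_any = [g for g in matrix.groups if row.get(g, False)]
        out.append(
            FamilyReconstruction(
                family=fam,
                category=categories.get(fam) if categories else None,
                groups_present=present_any,
                n_euk_groups=len(euk_present),
                prokaryote_evidence=prok,
                ancestral=rule,
                dollo_root=dollo.root_state,
                dollo_losses=dollo.losses,
                origin=origin,
            )
        )
    return AncestralReport(families=out)
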