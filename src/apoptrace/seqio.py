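"""Readers and writers for the formats the pipeline consumes.

Four kinds of input are handled: unaligned protein FASTA, protein multiple
alignments (aligned FASTA or single-alignment Stockholm with HMM-style
match/insert column semantics), Newick trees with branch lengths and
numeric internal support labels, and a three-column taxonomy table mapping
sequence ids to species and to lineage groups (the five ancient eukaryotic
supergroups plus Eubacteria, Archaea and Virus).

Trees are represented as :class:`dendropy.Tree` objects throughout the
package; leaf labels live on ``node.taxon.label`` and bootstrap supports on
``node.support`` (mirrored to internal-node labels on output).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "AMINO_ACIDS",
    "EUKARYOTIC_SUPERGROUPS",
    "NONEUKARYOTIC_GROUPS",
    "MATCH",
    "INSERT",
    "FLANK",
    "SequenceRecord",
    "MultipleAlignment",
    "TaxonomyMap",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "read_alignment",
    "read_alignment_fasta",
    "read_newick",
    "write_newick",
    "load_taxonomy",
]

#: the 20 standard amino acids; anything else is coerced to X on ingestion
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
_GAP_CHARS = frozenset("-.")

#: default set of ancient eukaryotic lineage groups (supergroups)
EUKARYOTIC_SUPERGROUPS = ("Opisthokonta", "Amoebozoa", "SAR", "Excavata", "Archaeplastida")
NONEUKARYOTIC_GROUPS = ("Eubacteria", "Archaea", "Virus")

# column state labels (HMM profile semantics)
MATCH = "match"
INSERT = "insert"
FLANK = "flank"


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceRecord:
    """A protein sequence: unique id, gap-free residue string, optional species."""

    id: str
    residues: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has an empty residue string")
        self.residues = _sanitize_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)


def _sanitize_residues(residues: str, seq_id: str) -> str:
    residues = residues.upper()
    bad = set(residues) & _GAP_CHARS
    if bad:
        raise ValueError(f"sequence {seq_id!r} contains gap characters {sorted(bad)}")
    unknown = set(residues) - _VALID_RESIDUES
    if unknown:
        warnings.warn(
            f"sequence {seq_id!r}: non-standard residues {sorted(unknown)} replaced by X"
        )
        table = str.maketrans({c: "X" for c in unknown})
        residues = residues.translate(table)
    return residues


def read_fasta(source) -> list[SequenceRecord]:
    """Read unaligned FASTA into a list of :class:`SequenceRecord`.

    ``source`` may be a path, an open text handle, or a FASTA string.
    Wrapped lines are concatenated; residues are uppercased; duplicate ids
    and empty sequences raise ``ValueError``.
    """
    handle = _as_handle(source, sniff=">")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in FASTA input")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"sequence {rec.id!r} is empty")
        records.append(SequenceRecord(id=rec.id, residues=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], handle=None) -> str:
    """Serialize records as unwrapped FASTA; returns the text (and writes to
    ``handle`` if given)."""
    text = "".join(f">{r.id}\n{r.residues}\n" for r in records)
    if handle is not None:
        if hasattr(handle, "write"):
            handle.write(text)
        else:
            with open(handle, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# alignments


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows with per-column state labels.

    ``column_states[j]`` is one of :data:`MATCH`, :data:`INSERT`,
    :data:`FLANK`.  Gap characters are permitted ('-' in match columns,
    '.' in insert columns); residue case is preserved as read.
    """

    rows: list[tuple[str, str]]
    column_states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        n = lengths.pop() if lengths else 0
        if not self.column_states:
            self.column_states = [MATCH] * n
        if len(self.column_states) != n:
            raise ValueError(
                f"column_states length {len(self.column_states)} != alignment length {n}"
            )
        ids = [i for i, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.column_states)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for i, s in self.rows:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def select_columns(self, indices: Sequence[int]) -> "MultipleAlignment":
        """New alignment restricted to the given columns, order preserved."""
        rows = [(i, "".join(s[j] for j in indices)) for i, s in self.rows]
        states = [self.column_states[j] for j in indices]
        return MultipleAlignment(rows=rows, column_states=states)

    def to_records(self) -> list[SequenceRecord]:
        """Degapped rows as :class:`SequenceRecord` (uppercased)."""
        out = []
        for i, s in self.rows:
            residues = "".join(c for c in s if c not in _GAP_CHARS)
            out.append(SequenceRecord(id=i, residues=residues))
        return out

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in self.rows)


def _classify_columns(rows: list[tuple[str, str]]) -> list[str]:
    """Insert = any lowercase residue or '.' in the column; flank = maximal
    runs of insert columns touching either alignment end; match otherwise."""
    if not rows:
        return []
    n = len(rows[0][1])
    states = []
    for j in range(n):
        col = [s[j] for _, s in rows]
        if any(c == "." or c.islower() for c in col):
            states.append(INSERT)
        else:
            states.append(MATCH)
    # relabel terminal insert runs as flank (the profile's N/C states)
    j = 0
    while j < n and states[j] == INSERT:
        states[j] = FLANK
        j += 1
    j = n - 1
    while j >= 0 and states[j] == INSERT:
        states[j] = FLANK
        j -= 1
    return states


def read_stockholm(source) -> MultipleAlignment:
    """Read a single-alignment Stockholm file.

    Lowercase residues and '.' mark insert states; terminal insert runs are
    labelled flank.  A missing '//' terminator is tolerated with a warning.
    """
    handle = _as_handle(source, sniff="# STOCKHOLM")
    text = handle.read()
    if "//" not in text:
        warnings.warn("Stockholm input missing '//' terminator; assuming end of file")
        text = text.rstrip("\n") + "\n//\n"
    try:
        msa = AlignIO.read(io.StringIO(text), "stockholm")
    except ValueError as exc:
        raise ValueError(f"malformed Stockholm alignment: {exc}") from exc
    rows = [(rec.id, str(rec.seq)) for rec in msa]
    return MultipleAlignment(rows=rows, column_states=_classify_columns(rows))


def read_alignment_fasta(source) -> MultipleAlignment:
    """Read an aligned FASTA file; column states classified as for Stockholm."""
    handle = _as_handle(source, sniff=">")
    rows = []
    seen = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in alignment")
        seen.add(rec.id)
        rows.append((rec.id, str(rec.seq)))
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise ValueError(f"aligned FASTA rows have unequal lengths: {sorted(lengths)}")
    return MultipleAlignment(rows=rows, column_states=_classify_columns(rows))


def read_alignment(source) -> MultipleAlignment:
    """Dispatch on content: Stockholm if the header marker is present,
    aligned FASTA otherwise."""
    handle = _as_handle(source)
    text = handle.read()
    if text.lstrip().startswith("# STOCKHOLM"):
        return read_stockholm(text)
    return read_alignment_fasta(text)


# ---------------------------------------------------------------------------
# trees


def read_newick(source) -> dendropy.Tree:
    """Parse Newick into a :class:`dendropy.Tree`.

    Numeric internal-node labels are interpreted as bootstrap supports (in
    [0,100]; values in [0,1] are rescaled x100 with a warning) and stored on
    ``node.support``.
    """
    handle = _as_handle(source, sniff="(")
    text = handle.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    for nd in tree.preorder_node_iter():
        nd.support = None
        if nd.is_leaf():
            continue
        if nd.label is not None:
            try:
                val = float(nd.label)
            except ValueError:
                continue
            if 0.0 <= val <= 1.0 and val != 0:
                warnings.warn(
                    f"internal support {val} looks like a fraction; rescaling to {val * 100}"
                )
                val *= 100.0
            nd.support = val
            nd.label = None
    return tree


def write_newick(tree: dendropy.Tree, handle=None) -> str:
    """Serialize a tree to Newick, branch lengths to 6 decimals, supports as
    internal-node labels."""
    clone = tree.clone(depth=1)
    for nd in clone.preorder_node_iter():
        sup = getattr(nd, "support", None)
        if sup is not None and not nd.is_leaf():
            nd.label = format(sup, "g")
    text = clone.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    if handle is not None:
        if hasattr(handle, "write"):
            handle.write(text)
        else:
            with open(handle, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# taxonomy


class TaxonomyMap:
    """Sequence id -> species -> lineage group -> domain lookups.

    Groups are the configured eukaryotic supergroups (mapping to domain
    Eukaryota) plus Eubacteria, Archaea and Virus (each its own domain).
    """

    def __init__(
        self,
        seq_to_species: Mapping[str, str],
        species_to_group: Mapping[str, str],
        eukaryotic_groups: Sequence[str] = EUKARYOTIC_SUPERGROUPS,
    ) -> None:
        self.eukaryotic_groups = tuple(eukaryotic_groups)
        self.group_to_domain: dict[str, str] = {g: "Eukaryota" for g in self.eukaryotic_groups}
        self.group_to_domain.update(
            {"Eubacteria": "Eubacteria", "Archaea": "Archaea", "Virus": "Virus"}
        )
        for sp, grp in species_to_group.items():
            if grp not in self.group_to_domain:
                raise ValueError(
                    f"unknown group {grp!r} for species {sp!r}; "
                    f"valid groups: {sorted(self.group_to_domain)}"
                )
        self.seq_to_species = dict(seq_to_species)
        self.species_to_group = dict(species_to_group)

    def species_of(self, seq_id: str) -> str:
        try:
            return self.seq_to_species[seq_id]
        except KeyError:
            raise KeyError(f"sequence id {seq_id!r} not in taxonomy") from None

    def group_of(self, seq_id: str) -> str:
        sp = self.species_of(seq_id)
        try:
            return self.species_to_group[sp]
        except KeyError:
            raise KeyError(f"species {sp!r} (of {seq_id!r}) has no group") from None

    def domain_of(self, seq_id: str) -> str:
        return self.group_to_domain[self.group_of(seq_id)]

    def is_eukaryote(self, seq_id: str) -> bool:
        return self.domain_of(seq_id) == "Eukaryota"

    def ids(self) -> list[str]:
        return list(self.seq_to_species)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.seq_to_species

    def __len__(self) -> int:
        return len(self.seq_to_species)


def load_taxonomy(
    source, eukaryotic_groups: Sequence[str] = EUKARYOTIC_SUPERGROUPS
) -> TaxonomyMap:
    """Load a 3-column TSV (id, species, group; '#' comments) into a
    :class:`TaxonomyMap`."""
    handle = _as_handle(source, sniff="\t")
    try:
        df = pd.read_csv(
            handle,
            sep="\t",
            comment="#",
            header=None,
            names=["id", "species", "group"],
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return TaxonomyMap({}, {}, eukaryotic_groups)
    if df.empty:
        return TaxonomyMap({}, {}, eukaryotic_groups)
    if df.isna().any().any():
        raise ValueError("taxonomy table has missing fields (expect 3 tab-separated columns)")
    seq_to_species: dict[str, str] = {}
    species_to_group: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.id in seq_to_species and seq_to_species[row.id] != row.species:
            raise ValueError(
                f"sequence id {row.id!r} mapped to both "
                f"{seq_to_species[row.id]!r} and {row.species!r}"
            )
        seq_to_species[row.id] = row.species
        if row.species in species_to_group and species_to_group[row.species] != row.group:
            raise ValueError(
                f"species {row.species!r} mapped to both "
                f"{species_to_group[row.species]!r} and {row.group!r}"
            )
        species_to_group[row.species] = row.group
    return TaxonomyMap(seq_to_species, species_to_group, eukaryotic_groups)


# ---------------------------------------------------------------------------
# helpers


def _as_handle(source, sniff: str | None = None):
    """Accept a path, open handle, or raw string and return a text handle."""
    if hasattr(source, "read"):
        return source
    if isinstance(source, str):
        looks_like_data = (
            source == ""
            or "\n" in source
            or (sniff is not None and source.lstrip().startswith(sniff))
        )
        if looks_like_data:
            return io.StringIO(source)
        return open(source)
    return open(source)
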