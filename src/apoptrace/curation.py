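"""Family curation: alignment quality control and membership filters.

The historical pipeline this package re-creates relied on BLAST for
identity/coverage screening and on HMM match-state annotation for column
filtering.  Here the search step is replaced by exact global pairwise
alignment (Needleman-Wunsch; match +1, mismatch 0, linear gap -1), which is
deterministic and dependency-free while preserving the semantics of the
thresholds: a candidate is *novel* when its best-hit identity is below 90%
with at least 50% (query-side) coverage, and *redundant* when it is >= 90%
identical to a database sequence.

Novel members are folded into the master alignment by aligning them to a
position-specific profile (per-column residue frequencies with a 1/20
pseudocount, log-odds scored against a uniform background; affine gaps,
open -2, extend -1).  Residues that cannot be assigned to a match column
are treated as insertions and discarded, so merging never changes the
master's column count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqio import (
    AMINO_ACIDS,
    FLANK,
    INSERT,
    MATCH,
    MultipleAlignment,
    SequenceRecord,
)

__all__ = [
    "IdentityResult",
    "CurationConfig",
    "global_align",
    "pairwise_identity",
    "strip_nonmatch_columns",
    "strip_columns_with_any_gap_insertion",
    "remove_redundant",
    "find_novel",
    "merge_into_profile",
]

_GAPS = ("-", ".")


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of a pairwise comparison.

    identity
        Identical residue pairs over columns where both sequences place a
        residue (closest analogue of percent identity over the aligned
        region).
    coverage
        Fraction of the query's residues aligned opposite residues of the
        subject.
    aligned_columns
        Number of columns with residues on both sides.
    """

    identity: float
    coverage: float
    aligned_columns: int


@dataclass
class CurationConfig:
    identity_threshold: float = 0.90
    coverage_threshold: float = 0.50
    redundancy_threshold: float = 0.90

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage_threshold", "redundancy_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


# ---------------------------------------------------------------------------
# column filters


def strip_nonmatch_columns(aln: MultipleAlignment) -> MultipleAlignment:
    """Keep exactly the match columns (drops insert and flank states)."""
    keep = [j for j, st in enumerate(aln.column_states) if st == MATCH]
    out = aln.select_columns(keep)
    # residue case follows column state; match columns are uppercase
    out.rows = [(i, s.upper().replace(".", "-")) for i, s in out.rows]
    return out


def strip_columns_with_any_gap_insertion(aln: MultipleAlignment) -> MultipleAlignment:
    """Drop every column in which at least one row has a gap character."""
    keep = [
        j
        for j in range(aln.length)
        if all(s[j] not in _GAPS for _, s in aln.rows)
    ]
    return aln.select_columns(keep)


# ---------------------------------------------------------------------------
# pairwise alignment

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS + "X")}


def global_align(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch global alignment (match +1, mismatch 0, gap -1,
    linear).  Traceback ties prefer diagonal, then consuming ``a`` (up),
    then consuming ``b`` (left), for determinism."""
    m, n = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    S = np.empty((m + 1, n + 1), dtype=np.int32)
    S[0, :] = -np.arange(n + 1)
    S[:, 0] = -np.arange(m + 1)
    jj = np.arange(1, n + 1)
    for i in range(1, m + 1):
        eq = (av[i - 1] == bv).astype(np.int32)
        t = np.maximum(S[i - 1, :-1] + eq, S[i - 1, 1:] - 1)
        # x_j = max(t_j, x_{j-1} - 1) solved by a running-max offset trick
        x = np.maximum.accumulate(t + jj) - jj
        S[i, 1:] = np.maximum(x, S[i, 0] - jj)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        s = S[i, j]
        if i > 0 and j > 0 and s == S[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and s == S[i - 1, j] - 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> IdentityResult:
    """Globally align ``a`` (query) against ``b`` and score identity and
    query-side coverage."""
    ra, rb = global_align(a.residues, b.residues)
    both = sum(1 for x, y in zip(ra, rb) if x != "-" and y != "-")
    ident = sum(1 for x, y in zip(ra, rb) if x != "-" and x == y)
    identity = ident / both if both else 0.0
    coverage = both / len(a.residues)
    return IdentityResult(identity=identity, coverage=coverage, aligned_columns=both)


# ---------------------------------------------------------------------------
# membership filters


def remove_redundant(
    new_seqs: list[SequenceRecord],
    db_seqs: list[SequenceRecord],
    cfg: CurationConfig | None = None,
) -> list[SequenceRecord]:
    """Drop any new sequence with identity >= redundancy threshold to some
    database sequence; order preserved."""
    cfg = cfg or CurationConfig()
    kept = []
    for s in new_seqs:
        if any(
            pairwise_identity(s, d).identity >= cfg.redundancy_threshold for d in db_seqs
        ):
            continue
        kept.append(s)
    return kept


def find_novel(
    candidates: list[SequenceRecord],
    db_seqs: list[SequenceRecord],
    cfg: CurationConfig | None = None,
) -> list[SequenceRecord]:
    """Keep a candidate iff its maximal identity to the database is below the
    identity threshold and its coverage against the best-identity hit meets
    the coverage threshold.  With an empty database every candidate is
    trivially novel."""
    cfg = cfg or CurationConfig()
    kept = []
    for s in candidates:
        if not db_seqs:
            kept.append(s)
            continue
        results = [pairwise_identity(s, d) for d in db_seqs]
        best = max(results, key=lambda r: r.identity)
        if best.identity < cfg.identity_threshold and best.coverage >= cfg.coverage_threshold:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# profile merge

_PSEUDOCOUNT = 1.0 / 20.0
_BACKGROUND = 1.0 / 20.0
_GAP_OPEN = -2.0
_GAP_EXTEND = -1.0


def _column_scores(master: MultipleAlignment) -> np.ndarray:
    """Log-odds score of each residue against each master match column.

    Frequencies use a 1/20 pseudocount per amino acid; X scores 0
    everywhere (uninformative)."""
    cols = [j for j, st in enumerate(master.column_states) if st == MATCH]
    scores = np.zeros((len(cols), 21))  # 20 aa + X
    for k, j in enumerate(cols):
        counts = np.full(20, _PSEUDOCOUNT)
        n = 0
        for _, s in master.rows:
            c = s[j].upper()
            if c in _AA_INDEX and c != "X":
                counts[_AA_INDEX[c]] += 1.0
                n += 1
        freqs = counts / (n + 1.0)
        scores[k, :20] = np.log(freqs / _BACKGROUND)
        scores[k, 20] = 0.0
    return scores


def _align_to_profile(seq: str, scores: np.ndarray) -> tuple[str, int]:
    """Affine-gap global alignment of a sequence to a profile.

    Returns the emitted row (one character per profile column; '-' where a
    column is deleted) and the number of residues placed in match columns.
    Residues consumed between columns (insertions) are discarded.
    """
    ncol = scores.shape[0]
    m = len(seq)
    idx = [_AA_INDEX.get(c.upper(), 20) for c in seq]
    NEG = -1e30
    # DP over (residue i, column j); M = residue emitted in column,
    # X = residue inserted (consumed, no column), Y = column deleted.
    M = np.full((m + 1, ncol + 1), NEG)
    X = np.full((m + 1, ncol + 1), NEG)
    Y = np.full((m + 1, ncol + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = _GAP_OPEN + _GAP_EXTEND * (i - 1)
    for j in range(1, ncol + 1):
        Y[0, j] = _GAP_OPEN + _GAP_EXTEND * (j - 1)
    for i in range(m + 1):
        for j in range(ncol + 1):
            if i > 0 and j > 0:
                best = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
                M[i, j] = best + scores[j - 1, idx[i - 1]]
            if i > 0:
                X[i, j] = max(
                    M[i - 1, j] + _GAP_OPEN, X[i - 1, j] + _GAP_EXTEND, Y[i - 1, j] + _GAP_OPEN
                )
            if j > 0:
                Y[i, j] = max(
                    M[i, j - 1] + _GAP_OPEN, Y[i, j - 1] + _GAP_EXTEND, X[i, j - 1] + _GAP_OPEN
                )
    # traceback: prefer M, then X (insertion), then Y (deletion)
    i, j = m, ncol
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i, j])
    emitted: list[str] = []
    placed = 0
    while i > 0 or j > 0:
        if state == "M":
            emitted.append(seq[i - 1].upper())
            placed += 1
            prev = max(
                ("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i - 1, j - 1]
            )
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            # residue consumed as insertion; nothing emitted
            cands = [
                ("M", M[i - 1, j] + _GAP_OPEN),
                ("X", X[i - 1, j] + _GAP_EXTEND),
                ("Y", Y[i - 1, j] + _GAP_OPEN),
            ]
            state = max(cands, key=lambda t: t[1])[0]
            i -= 1
        else:
            emitted.append("-")
            cands = [
                ("M", M[i, j - 1] + _GAP_OPEN),
                ("Y", Y[i, j - 1] + _GAP_EXTEND),
                ("X", X[i, j - 1] + _GAP_OPEN),
            ]
            state = max(cands, key=lambda t: t[1])[0]
            j -= 1
    return "".join(reversed(emitted)), placed


def merge_into_profile(
    novel: list[SequenceRecord],
    master: MultipleAlignment,
    cfg: CurationConfig | None = None,
) -> MultipleAlignment:
    """Align each novel sequence to the master's position-specific profile
    and append it as a new row; the master's rows and column count are never
    changed.  Sequences placing fewer than the coverage threshold of their
    residues in match columns are skipped with a warning."""
    cfg = cfg or CurationConfig()
    match_cols = [j for j, st in enumerate(master.column_states) if st == MATCH]
    if not match_cols:
        raise ValueError("master alignment has no match columns")
    scores = _column_scores(master)
    rows = list(master.rows)
    existing = {i for i, _ in rows}
    for rec in novel:
        if rec.id in existing:
            raise ValueError(f"novel sequence id {rec.id!r} already present in master")
        emitted, placed = _align_to_profile(rec.residues, scores)
        if placed / len(rec.residues) < cfg.coverage_threshold:
            warnings.warn(
                f"sequence {rec.id!r} places only {placed}/{len(rec.residues)} residues "
                "in match columns; skipped"
            )
            continue
        # expand emitted (match columns only) back onto the master's frame
        full = []
        k = 0
        for j in range(master.length):
            if master.column_states[j] == MATCH:
                full.append(emitted[k])
                k += 1
            else:
                full.append("." if master.column_states[j] in (INSERT, FLANK) else "-")
        rows.append((rec.id, "".join(full)))
        existing.add(rec.id)
    return MultipleAlignment(rows=rows, column_states=list(master.column_states))
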