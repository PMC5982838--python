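# Methods

## Scope and model

`apoptrace` reconstructs the ancestral presence of apoptotic protein
families at two ancestral nodes: the last eukaryotic common ancestor
(LECA), and — via origin classification — the eubacterial endosymbiont
ancestor of mitochondria (the protomitochondrion).  The unit of analysis
is a protein family defined by a domain alignment; the evidence is which
of the five ancient eukaryotic supergroups (Opisthokonta, Amoebozoa, SAR,
Excavata, Archaeplastida) and which non-eukaryotic domains (Eubacteria,
Archaea, viruses) carry members of the family, plus the family's gene-tree
topology.

Two ancestral criteria are computed independently per family:

* **Parsimony rule.**  A family is ancestral if it is present in at least
  `k` eukaryotic supergroups (default `k = 2`) or in Eubacteria or
  Archaea.  The reading of "several groups" as ≥ 2 is the minimal one
  consistent with the treatment of every family in the source literature
  (each family called ancestral there is attested in at least two
  supergroups); `k` is exposed for sensitivity analyses.  Viral presence
  alone never triggers the rule: viral homologs are parsimoniously
  explained as host-derived (hijacked) rather than ancestral.
* **Dollo parsimony.**  On a rooted supergroup tree the character is
  gained exactly once, at the MRCA of the supergroups carrying it, and
  lost on a minimal set of edges covering the absences (a node is
  reconstructed present iff it lies in the gain subtree and its subtree
  retains at least one carrier; the loss count is the number of maximal
  absent subtrees).  Dollo rather than Fitch parsimony is used because
  none of the inferences involve convergent regain of a family.  The
  default supergroup tree is the five-leaf star rooted at LECA; any
  user-supplied rooted Newick over the same leaves is accepted.  On the
  star with no prokaryotic evidence, rule (`k = 2`) and Dollo root state
  coincide (tested exhaustively over all 32 rows).

## Origin classification

The endosymbiotic signature is read from the gene tree: the minimal
rooted clade containing all eukaryotic members of the family is located,
and the non-eukaryotic sequences inside that clade and in its sister are
collected.  Eubacterial-without-archaeal content yields the call
`eubacterial`, the converse `archaeal`; no prokaryotes at all yields
`eukaryote_only`; both yield `ambiguous`.  Rooting defaults to the
midpoint of the longest leaf-to-leaf path unless archaeal leaves are
present and form a bipartition, in which case they root the tree as the
outside reference.

Two eukaryotic paralog clades are said to have diverged before
eukaryogenesis when each lies closer to a eubacterial homolog than to the
other and the pair does not form a clade excluding all eubacteria.
"Closer" is operationalized as mean patristic distance by default
(robust to a single long branch); nearest-leaf distance is available via
`mode="nearest"` since the underlying notion of relatedness is not
uniquely defined by topology alone.

Relative chronology of splits is reported as a node-height ordering
(height = mean path length from a node to its descendant leaves, ties
broken by preorder).  This is a documented simplification of
relative-time methods: on clock-like trees the ordering coincides with
relative node ages, on strongly rate-heterogeneous trees it need not, and
the first event is the root split only in the clock-like regime.

## Curation

The historical search stack (BLAST/HMMER) is replaced by deterministic,
dependency-free equivalents that preserve the filtering semantics:

* Identity/coverage screening uses exact Needleman–Wunsch global
  alignment (match +1, mismatch 0, linear gap −1; traceback ties prefer
  diagonal, then the query-consuming move, for determinism).  Identity is
  counted over columns where both sequences place residues — the closest
  analogue of percent identity over the aligned region — and coverage is
  query-side (the fraction of the candidate's residues aligned opposite
  subject residues); which side BLAST coverage referred to is not
  recoverable, so the query side is the default and both thresholds are
  configurable.  A candidate is novel iff its best-hit identity is below
  0.90 and its coverage against that hit is at least 0.50; redundancy
  uses the same 0.90 identity cutoff.
* Column filters implement HMM match/insert semantics: columns containing
  lowercase residues or `.` are insert states, terminal insert runs are
  flank (N/C) states, and both are removed; afterwards every column in
  which any row has a gap is removed.  Both filters are idempotent.
* Novel members are merged against a position-specific profile of the
  master's match columns: per-column amino-acid frequencies with a 1/20
  pseudocount, scored log-odds against a uniform background, affine gaps
  (open −2, extend −1).  Residues that cannot be assigned to a match
  column are insertions and are discarded, so the master's column count
  and existing rows are invariant under merging; sequences placing fewer
  than the coverage threshold of their residues in match columns are
  skipped with a warning.

## Tree inference

Distances are per-pair mismatch fractions with pairwise deletion of gap
columns, Poisson-corrected as d = −ln(1 − p).  Saturated pairs (p ≥ 1 is
impossible for p-distances but can arise from user-supplied matrices) are
clamped at d = 10 with a warning, keeping matrices finite.  Neighbor
joining follows Saitou–Nei with two deterministic conventions: Q-matrix
ties are resolved toward the smallest (row, column) index pair, and
negative branch-length estimates are clamped to zero with the deficit
moved to the sister branch, which keeps downstream node-height orderings
monotone.  On additive matrices the implementation recovers the
generating topology and branch lengths to ≤ 1e−9 (tested on random trees
up to 12 leaves, and cross-checked against an independent NJ
implementation on non-additive matrices).

Bootstrap supports resample alignment columns with replacement (same
length), rebuild each replicate by the same distance→NJ chain, and report
per internal edge the percentage of successful replicates containing the
same bipartition; replicates with undefined distances are skipped,
counted and warned, and the denominator is the number of successful
replicates.  All resampling derives from a single seed.

Only neighbor joining is implemented.  Likelihood and minimum-evolution
tree estimation are deliberately out of scope: NJ is fully specified,
deterministic, and sufficient to exercise every downstream inference, at
the cost that support values are single numbers rather than
multi-method ranges.

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

* **Gene content**: per-edge loss probability 0.1 by default (a "rarely
  lost" regime in which most families survive in most lineages, matching
  the patchy-but-broad distributions the reconstruction is designed for);
  root state configurable; no regain.
* **Sequences**: 20-state uniform-exchange substitution (the amino-acid
  analogue of Jukes–Cantor), chosen because its closed-form expectations
  — P(same) = 1/20 + (19/20)e^(−20d/19) along a branch of length d —
  allow exact statistical tests without empirical rate matrices.  No
  indels, no among-site rate variation.
* **Endosymbiosis scenarios**: 6 eubacterial tips by default split
  between the eukaryotic clade's sister group and an outer bacterial
  clade, eukaryotic tips for a configurable supergroup subset (default
  Opisthokonta + SAR, the two-group minimum that triggers the ancestral
  rule), an optional archaeal two-tip outgroup, and an optional
  pre-eukaryotic duplication producing two paralog clades with distinct
  bacterial sisters.  Branch lengths are moderate (tips ≈ 0.1–0.2,
  internal ≈ 0.05–0.5 expected substitutions/site, jittered ±20% by the
  seed) so that 2,000-column alignments carry recoverable signal without
  saturation.  With a duplication, the minimal clade around *all*
  eukaryotic members spans the whole duplicated core and its sister is
  the archaeal outgroup, so whole-family origin calls are legitimately
  ambiguous there; per-paralog-clade calls recover the eubacterial
  origin, and the duplicated scenario is used to validate the divergence
  (predates) test.

What passing these simulations shows — and does not.  The generators
emulate vertical descent with a single endosymbiotic transfer pattern,
site-independent uniform-exchange evolution, and clock-like branch
lengths.  Real protein families add alignment error, rate heterogeneity,
long-branch effects, hidden paralogy and horizontal transfer; success on
the synthetic conditions validates the correctness of the machinery, not
the robustness of the biological conclusions to those complications.

## Validation thresholds and problem sizes

Recovery thresholds are repository constants fixed by an initial
calibration and then frozen: Dollo root-state recovery ≥ 95% at loss
probability 0.1 on the five-leaf star (the analytic expectation is
P(≥ 2 of 5 tips survive) ≈ 99.95%), and ≥ 90% end-to-end recovery of
origin and divergence calls over 200 seeded endosymbiosis replicates with
2,000-column alignments (observed ≈ 100%).  Exhaustive oracles run over
all 2^n presence rows on fixture trees of 4–8 leaves, and NJ recovery
over 50 random 10-taxon additive matrices — sizes at which the brute-force
oracles remain exact and the full suite runs in seconds.

## Numerical and degenerate-input conventions

Sequence alphabet is the 20 amino acids plus X; other letters are coerced
to X with a warning, and X scores neutrally (log-odds 0) in profiles.
Gap characters `-` and `.` are both accepted on input; match columns are
written with `-`.  Internal Newick labels that parse as numbers are
bootstrap supports; values in [0, 1] are rescaled ×100 with a warning.
Empty alignments, all-gap rows, absent families (all-false rows) and
empty pipelines are legal and return empty results rather than errors;
pairs of rows with no comparable columns are an error naming the pair.

## Known limitations

Single-linkage of family membership to domain presence (no domain-
architecture reasoning); no gene-tree/species-tree reconciliation, so
hidden paralogy can inflate presence calls; the chronology is ordinal
only; the in-package matrices transcribe published organism-level
reports and inherit any incompleteness of those reports (in particular
the API5 row lists only the named supergroup, which is fewer than the
source asserts, so its rule call is conservative).
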