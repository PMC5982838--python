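"""End-to-end orchestration: curation -> trees -> origin calls -> report.

A pipeline run is driven by a :class:`PipelineConfig` (usually parsed from
YAML).  Each configured family is processed independently: its alignment
is loaded and quality-controlled, optional candidate sequences are
screened for novelty and merged into the profile, a neighbor-joining tree
with bootstrap supports is built, the family's origin is classified
against the taxonomy, and its presence row feeds the ancestral
reconstruction.  A failure in any stage marks that family "failed" in the
report without aborting the run (unless ``keep_going`` is off).

Runs are deterministic given the config seed; two runs with the same
config produce byte-identical JSON reports.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import curation
from .ancestral import (
    collapse_to_groups,
    default_supergroup_tree,
    reconstruct_repertoire,
)
from .clades import classify_family_origin
from .curation import CurationConfig
from .phylo import (
    BootstrapSpec,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
    poisson_correct,
)
from .seqio import (
    load_taxonomy,
    read_alignment,
    read_fasta,
    read_newick,
    write_newick,
)

__all__ = ["FamilySpec", "PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("apoptrace")


@dataclass
class FamilySpec:
    name: str
    alignment: str
    category: str | None = None
    candidates: str | None = None


@dataclass
class PipelineConfig:
    families: list[FamilySpec] = field(default_factory=list)
    taxonomy: str | None = None
    supergroup_tree: str | None = None
    identity_threshold: float = 0.90
    coverage_threshold: float = 0.50
    redundancy_threshold: float = 0.90
    k: int = 2
    bootstrap_replicates: int = 100
    seed: int = 0
    outdir: str = "apoptrace_out"
    keep_going: bool = True

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            raw = yaml.safe_load(source)
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        raw = raw or {}
        fams = [FamilySpec(**f) for f in raw.pop("families", [])]
        return cls(families=fams, **raw)

    def curation_config(self) -> CurationConfig:
        return CurationConfig(
            identity_threshold=self.identity_threshold,
            coverage_threshold=self.coverage_threshold,
            redundancy_threshold=self.redundancy_threshold,
        )


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Static checks; returns an empty list iff the config is runnable."""
    findings: list[str] = []
    for name in ("identity_threshold", "coverage_threshold", "redundancy_threshold"):
        v = getattr(cfg, name)
        if not 0.0 < v <= 1.0:
            findings.append(f"{name} out of range (0, 1]: {v}")
    if cfg.k < 1:
        findings.append(f"k must be >= 1, got {cfg.k}")
    if cfg.bootstrap_replicates < 0:
        findings.append(f"bootstrap_replicates must be >= 0, got {cfg.bootstrap_replicates}")
    seen = set()
    for fam in cfg.families:
        if fam.name in seen:
            findings.append(f"duplicate family name {fam.name!r}")
        seen.add(fam.name)
        if not os.path.exists(fam.alignment):
            findings.append(f"family {fam.name!r}: alignment path missing: {fam.alignment}")
        if fam.candidates and not os.path.exists(fam.candidates):
            findings.append(f"family {fam.name!r}: candidates path missing: {fam.candidates}")
    if cfg.families and cfg.taxonomy is None:
        findings.append("taxonomy path is required when families are configured")
    elif cfg.taxonomy is not None and not os.path.exists(cfg.taxonomy):
        findings.append(f"taxonomy path missing: {cfg.taxonomy}")
    if cfg.supergroup_tree is not None and not os.path.exists(cfg.supergroup_tree):
        findings.append(f"supergroup tree path missing: {cfg.supergroup_tree}")
    return findings


def _process_family(fam: FamilySpec, cfg: PipelineConfig, taxonomy, outdir: str, seed: int):
    """One family: curate, build tree, classify origin.  Returns
    (members, origin_call, artifacts dict)."""
    ccfg = cfg.curation_config()
    aln = read_alignment(fam.alignment)
    n0 = len(aln.rows)
    aln = curation.strip_nonmatch_columns(aln)
    aln = curation.strip_columns_with_any_gap_insertion(aln)
    log.info("family %s: %d rows, %d match columns after stripping", fam.name, n0, aln.length)

    if fam.candidates:
        candidates = read_fasta(fam.candidates)
        db = aln.to_records()
        novel = curation.find_novel(candidates, db, ccfg)
        log.info(
            "family %s: %d candidates, %d novel after identity/coverage filter",
            fam.name,
            len(candidates),
            len(novel),
        )
        aln = curation.merge_into_profile(novel, aln, ccfg)

    curated_path = os.path.join(outdir, f"{fam.name}.curated.fasta")
    with open(curated_path, "w") as fh:
        fh.write(aln.to_fasta())

    tree = None
    tree_path = None
    if len(aln.rows) >= 3 and aln.length > 0:
        if cfg.bootstrap_replicates > 0:
            tree = bootstrap_support(
                aln, BootstrapSpec(replicates=cfg.bootstrap_replicates, seed=seed)
            )
        else:
            tree = neighbor_joining(poisson_correct(p_distance_matrix(aln)))
        tree_path = os.path.join(outdir, f"{fam.name}.tree.nwk")
        write_newick(tree, tree_path)

    members = [i for i in aln.ids if i in taxonomy]
    origin = None
    if tree is not None:
        euk = [i for i in members if taxonomy.is_eukaryote(i)]
        if euk:
            origin = classify_family_origin(tree, members, taxonomy, family=fam.name)
    artifacts = {"curated_alignment": curated_path, "tree": tree_path}
    return members, origin, artifacts


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured families end to end; returns the report dict and
    writes report.json plus a TSV summary under ``cfg.outdir``."""
    findings = validate_config(cfg)
    if findings:
        raise ValueError("invalid pipeline config: " + "; ".join(findings))
    os.makedirs(cfg.outdir, exist_ok=True)
    taxonomy = load_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
    sg_tree = (
        read_newick(cfg.supergroup_tree) if cfg.supergroup_tree else default_supergroup_tree()
    )
    sg_tree.is_rooted = True

    memberships: dict[str, list[str]] = {}
    origin_calls = {}
    categories = {}
    family_status: dict[str, dict] = {}
    for i, fam in enumerate(cfg.families):
        categories[fam.name] = fam.category
        try:
            members, origin, artifacts = _process_family(
                fam, cfg, taxonomy, cfg.outdir, seed=cfg.seed + i
            )
            memberships[fam.name] = members
            if origin is not None:
                origin_calls[fam.name] = origin
            family_status[fam.name] = {"status": "ok", **artifacts}
        except Exception as exc:  # noqa: BLE001 - stage failures are reported per family
            log.error("family %s failed: %s", fam.name, exc)
            family_status[fam.name] = {"status": "failed", "error": str(exc)}
            if not cfg.keep_going:
                raise

    report_payload: dict = {"families": family_status}
    if memberships:
        matrix = collapse_to_groups(memberships, taxonomy)
        report = reconstruct_repertoire(
            matrix,
            tree=sg_tree,
            origin_calls=origin_calls,
            k=cfg.k,
            categories=categories,
        )
        report_payload["reconstruction"] = json.loads(report.to_json())
        matrix.to_tsv(os.path.join(cfg.outdir, "presence_matrix.tsv"))
        report.summary_table().to_csv(os.path.join(cfg.outdir, "summary.tsv"), sep="\t")
    else:
        report_payload["reconstruction"] = {
            "families": [],
            "ancestral_families": [],
            "category_counts_ancestral": {},
        }

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report_payload, fh, indent=2, sort_keys=True)
    return report_payload
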