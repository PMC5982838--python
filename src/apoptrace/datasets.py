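"""Bundled literature-derived presence/absence matrices.

The package ships a small curated dataset: presence of the core apoptotic
protein families (DNases ENDOG/ZEN1/NUC1, AIF oxidoreductase lineages
AIFM1/AIFM2/AIFM3/NDI1, caspase/metacaspase and the two OMI/HTRA lineages,
and the BIR/API5 inhibitors) across the five ancient eukaryotic
supergroups and the prokaryotic/viral domains, as reported in the
apoptosis literature.  Every presence cell is backed by an organism-level
evidence annotation so the worked examples are auditable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ancestral import PresenceMatrix

__all__ = [
    "literature_presence_matrix",
    "literature_categories",
    "literature_evidence",
]


def _data_path(name: str):
    return resources.files("apoptrace.data").joinpath(name)


def literature_presence_matrix() -> PresenceMatrix:
    """Families x lineage-groups matrix curated from published homolog
    reports."""
    with _data_path("literature_presence.tsv").open() as fh:
        return PresenceMatrix.from_tsv(fh)


def literature_categories() -> dict[str, str]:
    """family -> functional category (DNase, AIF, Protease, Inhibitor)."""
    with _data_path("literature_categories.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["family"], df["category"]))


def literature_evidence() -> pd.DataFrame:
    """Per-cell evidence annotations (family, group, evidence)."""
    with _data_path("literature_evidence.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
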