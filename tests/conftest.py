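import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from apoptrace.seqio import TaxonomyMap


@pytest.fixture
def taxonomy():
    """Small mixed taxonomy: two eukaryotes per supergroup style plus
    prokaryotes and a virus."""
    seq_to_species = {
        "Yeast": "S_cerevisiae",
        "Human": "H_sapiens",
        "AmoebaA": "D_discoideum",
        "PlantA": "A_thaliana",
        "CiliateA": "P_tetraurelia",
        "TrichoA": "T_vaginalis",
        "Ecoli1": "E_coli",
        "Ecoli2": "B_subtilis",
        "ArchA": "S_solfataricus",
        "Virus1": "NPV",
    }
    species_to_group = {
        "S_cerevisiae": "Opisthokonta",
        "H_sapiens": "Opisthokonta",
        "D_discoideum": "Amoebozoa",
        "A_thaliana": "Archaeplastida",
        "P_tetraurelia": "SAR",
        "T_vaginalis": "Excavata",
        "E_coli": "Eubacteria",
        "B_subtilis": "Eubacteria",
        "S_solfataricus": "Archaea",
        "NPV": "Virus",
    }
    return TaxonomyMap(seq_to_species, species_to_group)
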