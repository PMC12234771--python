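import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def strain_table():
    from camscan.io import StrainTable

    strains = ("A1-1", "A1-2", "A1-3", "A2-1", "A2-2", "A2-3", "A2-4")
    lineage = {s: s.split("-")[0] for s in strains}
    return StrainTable(strains=strains, lineage_of=lineage)


@pytest.fixture
def small_alignment(strain_table):
    from camscan.io import GeneAlignment

    rows = {
        "A1-1": "ATGAAACCCTAA",
        "A1-2": "ATGAAACCCTAA",
        "A1-3": "ATGAAACCGTAA",
        "A2-1": "ATGAAA---TAA",
        "A2-2": "ATGAAA---TAA",
        "A2-3": "ATGAAA---TAA",
        "A2-4": "ATGAAA---TAA",
    }
    return GeneAlignment(gene_id="demo", rows=rows)
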