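import pytest

from citrusrisk import (
    PesticideInfo,
    ReferenceSet,
    ResidueRecord,
    ResidueTable,
    default_reference_set,
    default_survey_scenario,
    generate_residue_table,
)


@pytest.fixture
def tiny_table() -> ResidueTable:
    """Three samples, two pesticides, one non-detect and one clean sample."""
    records = [
        ResidueRecord("S1", "orange", "imazalil", 0.5, True),
        ResidueRecord("S1", "orange", "thiabendazole", 0.2, True),
        ResidueRecord("S2", "lemon", "imazalil", 1.2, True),
        ResidueRecord("S2", "lemon", "thiabendazole", 0.0, False),
        ResidueRecord("S3", "orange", "imazalil", 0.0, False),
        ResidueRecord("S3", "orange", "thiabendazole", 0.0, False),
    ]
    return ResidueTable(records)


@pytest.fixture
def tiny_refs() -> ReferenceSet:
    return ReferenceSet(
        [
            PesticideInfo("imazalil", ld50=227, adi=0.025, arfd=0.05, mrl={"*": 5.0}),
            PesticideInfo("thiabendazole", ld50=3100, adi=0.1, arfd=0.1, mrl={"*": 7.0}),
        ]
    )


@pytest.fixture(scope="session")
def survey_table() -> ResidueTable:
    """One generated default-scenario survey (seeded, shared across tests)."""
    return generate_residue_table(default_survey_scenario(seed=11))


@pytest.fixture(scope="session")
def refs() -> ReferenceSet:
    return default_reference_set()
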