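import pytest

from condsirna import (
    NucleicSequence,
    assemble_construct,
    build_core,
    build_guide,
    build_sensor,
    normalize_to_rna,
    reverse_complement,
)

# The published worked example: an Nppa-sensing construct silencing
# calcineurin. The guide is a validated 21-mer siRNA 5'-extended by the
# GC-rich tetramer CGAG into a 23-bp Dicer substrate.
PRINTED_GUIDE = "CGAGUGUUGUUUGGCUUUUCCUGUU"
PRINTED_SENSOR = "CUUCACCACCUCUCAGUGGCAAUGCGACCAA"
PRINTED_CORE = "AGGUGGUGAAGCAGGAAAAGCCAAACAACACUCGAUUGCCACUGAG"
BASE_SIRNA = "UGUUGUUUGGCUUUUCCUGUU"
EXTENSION = "CGAG"


@pytest.fixture(scope="session")
def printed_window() -> NucleicSequence:
    """The trigger-mRNA window implied by the published sensor."""
    return reverse_complement(
        normalize_to_rna(PRINTED_SENSOR, "printed_sensor"), id="window"
    )


@pytest.fixture(scope="session")
def printed_construct(printed_window):
    sensor = build_sensor(printed_window)
    guide = build_guide(normalize_to_rna(BASE_SIRNA, "sirna"), extension=EXTENSION)
    core = build_core(sensor, guide)
    return assemble_construct(guide, sensor, core)


@pytest.fixture(scope="session")
def nn_table():
    from condsirna.thermo import load_nn_table

    return load_nn_table()
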