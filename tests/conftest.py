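import pytest

from pepscaffold import (
    H2DB_ANCHORS,
    GeneratorSpec,
    anchor_consensus,
    build_pwm,
    default_registry,
    motif_from_display,
    parse_peptide,
    sample_binders,
    sequence_weights,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def h2db_motif():
    """The H-2Db anchor-consensus scaffold template."""
    return motif_from_display("xALxNxxxL")


@pytest.fixture(scope="session")
def e7_wt():
    return parse_peptide("RAHYNIVTF")


@pytest.fixture(scope="session")
def trp2_wt():
    return parse_peptide("SVYDFFVWL")


@pytest.fixture(scope="session")
def synthetic_pwm():
    """PWM built from the default seeded synthetic strong-binder set."""
    binders = sample_binders(GeneratorSpec(seed=7, n=250))
    return build_pwm(binders, sequence_weights(binders))


@pytest.fixture(scope="session")
def anchors():
    return H2DB_ANCHORS
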