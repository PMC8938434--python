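import pytest

from fgphase import seqthermo, tract


@pytest.fixture(scope="session")
def unit():
    return "GGLFGGNTQPAT"


@pytest.fixture(scope="session")
def full_spec(unit):
    """The 52-repeat construct with default hydration parameters."""
    return seqthermo.MoleculeSpec(sequence=seqthermo.build_repeat_sequence(unit, 52))


@pytest.fixture(scope="session")
def fragment_spec(unit):
    """The 7-repeat fragment."""
    return seqthermo.MoleculeSpec(sequence=seqthermo.build_repeat_sequence(unit, 7))


@pytest.fixture(scope="session")
def spin_params():
    return tract.SpinParameters()
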