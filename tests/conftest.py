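import pytest

from tripletseq import IncorporationModel, design_balanced_templates


@pytest.fixture(scope="session")
def design():
    return design_balanced_templates(seed=0)


@pytest.fixture(scope="session")
def error_model(design):
    """A fixed random misincorporation profile with no sequencing noise."""
    return IncorporationModel.random_errors(design, seed=11)
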