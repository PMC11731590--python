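from pathlib import Path

import pytest

from noduleoffset import paper_base_case

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture
def stated_params():
    return paper_base_case("stated")


@pytest.fixture
def calibrated_params():
    return paper_base_case("calibrated")


@pytest.fixture
def fixture_dir():
    return FIXTURE_DIR
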