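import pytest

import stwinscan as sw
from stwinscan.motifs import parse_pattern_string

#: The operational [D5,6] whole-genome screen pattern (relaxed profile,
#: default distance rules) — also what build_stwintron_pattern must emit.
D56_SCREEN = "GTRWGGTRWGH(25,120)DYTRAY(4,24)HAGH(25,120)DYTRAY(4,24)HAG"


@pytest.fixture(scope="session")
def d56_pattern():
    return parse_pattern_string(D56_SCREEN)


@pytest.fixture(scope="session")
def plain_fixture():
    """Genome with one planted [D5,6] stwintron (75/76 nt) + truth."""
    return sw.plant_stwintron(sw.FixtureSpec(seed=3))


@pytest.fixture(scope="session")
def aniger_fixture():
    """Alt-acceptor fixture: secondary CAG 26 nt downstream, 15-nt exon II."""
    return sw.plant_alt_acceptor_fixture(variant="a_niger", seed=1)


@pytest.fixture(scope="session")
def ncrassa_fixture():
    """Alt-acceptor fixture re-using the external acceptor; 33-nt exon II."""
    return sw.plant_alt_acceptor_fixture(variant="n_crassa", seed=1)


@pytest.fixture(scope="session")
def dual_fixture():
    """Dual intervening sequence: stwintron + intron 2 inside a
    discontinuous second-order intron (four excisions)."""
    return sw.plant_dual_is_fixture(seed=5)
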