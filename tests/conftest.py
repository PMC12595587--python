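import pytest

from hlakit.fixtures import (
    FixtureSpec,
    make_alignment_fixture,
    make_frequency_fixture,
    make_history_fixture,
)


@pytest.fixture(scope="session")
def gen_fixture():
    """Genomic alignment fixture: (emitted text, ground-truth table)."""
    return make_alignment_fixture(FixtureSpec(seed=101), align_type="gen")


@pytest.fixture(scope="session")
def prot_fixture():
    return make_alignment_fixture(FixtureSpec(seed=102), align_type="prot")


@pytest.fixture(scope="session")
def nuc_fixture():
    return make_alignment_fixture(FixtureSpec(seed=103), align_type="nuc")


@pytest.fixture(scope="session")
def history_fixture():
    return make_history_fixture(FixtureSpec(seed=104), n_accessions=30)


@pytest.fixture(scope="session")
def frequency_fixture():
    """(frequency table, haplotype table, truth) with a planted signal."""
    return make_frequency_fixture(
        FixtureSpec(seed=105), planted=("A", "A*01:01", 0.55)
    )
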