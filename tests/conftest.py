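import pytest

from cbscan import composition, seqio


def make_protein_comp(overrides=None):
    """Protein composition with given frequencies; the rest share the remainder."""
    overrides = dict(overrides or {})
    rest = [r for r in seqio.PROTEIN.letters if r not in overrides]
    remainder = 1.0 - sum(overrides.values())
    freq = dict(overrides)
    for r in rest:
        freq[r] = remainder / len(rest)
    return composition.CompositionTable(seqio.PROTEIN, freq, 0, source="test")


@pytest.fixture
def uniform_protein_comp():
    return composition.CompositionTable(
        seqio.PROTEIN, {r: 0.05 for r in seqio.PROTEIN.letters}, 0, source="uniform"
    )


@pytest.fixture
def uniform_dna_comp():
    return composition.CompositionTable(
        seqio.DNA, {b: 0.25 for b in seqio.DNA.letters}, 0, source="uniform"
    )


@pytest.fixture
def protein_comp_factory():
    return make_protein_comp
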