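import pytest

from locsig import secstruct, synth
from locsig.io import RnaSequence


def make_annotated(element):
    """(sequence, pair table, annotation) for a (seq, dotbracket) element."""
    seq_str, db = element
    seq = RnaSequence("element", seq_str)
    pt = secstruct.build_pair_table(seq, db)
    ann = secstruct.annotate_stemloop(pt, sequence=seq)
    return seq, pt, ann


@pytest.fixture(scope="session")
def tls_annotated():
    """The synthetic 44-nt primary-signal hairpin, annotated."""
    return make_annotated(synth.tls_like_element())


@pytest.fixture(scope="session")
def support_annotated():
    return make_annotated(synth.support_element())


@pytest.fixture(scope="session")
def gc_mutant_annotated():
    return make_annotated(synth.gc_mutant_element())
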