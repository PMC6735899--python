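"""Shared fixtures: packaged toy reference and a handcrafted mini-ORF."""

import pytest

from poolscreen.datasets import load_toy_reference
from poolscreen.reference import OrfReference


@pytest.fixture(scope="session")
def toy():
    """Packaged 300-codon ORF with flanks and 4 nested domains."""
    ref, annotations = load_toy_reference()
    return ref, annotations


@pytest.fixture(scope="session")
def toy_ref(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_annotations(toy):
    return toy[1]


@pytest.fixture(scope="session")
def mini_ref():
    """Six-codon ORF MEALWH with hand-checkable codon arithmetic.

    Codons: ATG GAA GCT CTG TGG CAC. Notable single-base changes:
    pos 4 G>A -> E2K (missense), pos 8 C>T -> A3V, pos 12 G>A -> L4L
    (synonymous), pos 15 G>A -> TGG>TGA, the opal stop (W5*).
    """
    return OrfReference(id="mini", seq="ATGGAAGCTCTGTGGCAC")
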