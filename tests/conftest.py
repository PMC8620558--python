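import pytest

from mtspectrum import MtReference, VariantCall, mouse_like_reference, toy_reference
from mtspectrum.genome_model import Feature


@pytest.fixture(scope="session")
def toy_ref() -> MtReference:
    return toy_reference()


@pytest.fixture(scope="session")
def mouse_ref() -> MtReference:
    return mouse_like_reference()


@pytest.fixture
def wrap_ref() -> MtReference:
    """16-bp genome with a tRNA wrapping the origin (start 15, end 3)."""
    return MtReference(
        name="mini",
        sequence="ACGTACGTACGTACGT",
        features=[
            Feature(name="geneX", kind="CDS", start=5, end=13, strand="+"),
            Feature(name="wrapT", kind="tRNA", start=15, end=3, strand="+"),
        ],
    )


def make_call(pos, ref="C", alt="T", af=0.5, animal="A01", tissue="liver",
              depth=100):
    return VariantCall(animal_id=animal, tissue=tissue, pos=pos, ref_allele=ref,
                       alt_allele=alt, allele_fraction=af, depth=depth)


@pytest.fixture
def call_factory():
    return make_call
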