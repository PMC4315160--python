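import pytest

from mtqc.reference import CircularReference, load_rcrs


def make_ref(seq: str, circular: bool = True, name: str = "toy") -> CircularReference:
    seq = seq.upper()
    placeholders = frozenset(i + 1 for i, c in enumerate(seq) if c not in "ACGT")
    return CircularReference(
        name=name, sequence=seq, placeholder_positions=placeholders, circular=circular
    )


@pytest.fixture(scope="session")
def rcrs():
    return load_rcrs()
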