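import numpy as np
import pytest

from mosaicscan import AlignedRead, Reference, random_reference

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@pytest.fixture
def small_reference() -> Reference:
    return random_reference(100, seed=1234)


@pytest.fixture
def locus_reference() -> Reference:
    """A reference long enough for multi-kilobase deletion simulations."""
    return random_reference(16000, seed=99)


def make_read(
    ref: Reference,
    start: int,
    length: int = 20,
    orientation: str = "forward",
    read_id: str = "r1",
    mapq: int = 60,
    qual: int = 30,
    insert_size: int | None = None,
    sequence: str | None = None,
    cigar: str = "",
    sample_id: str = "",
) -> AlignedRead:
    seq = sequence if sequence is not None else ref.sequence[start - 1 : start - 1 + length]
    return AlignedRead(
        read_id=read_id,
        contig=ref.name,
        start=start,
        orientation=orientation,
        sequence=seq,
        base_qualities=np.full(len(seq), qual, dtype=np.int16),
        mapping_quality=mapq,
        cigar=cigar,
        insert_size=insert_size,
        sample_id=sample_id,
    )
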