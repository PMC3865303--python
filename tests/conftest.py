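import pytest

from fae1pop.seqio import AlignmentMatrix, SequenceRecord
from fae1pop import synthdata


def make_matrix(seqs, coding_offset=1, ids=None, clades=None, **kw):
    """Build a small AlignmentMatrix from raw sequence strings."""
    ids = ids or [f"s{i}" for i in range(1, len(seqs) + 1)]
    clades = clades or [""] * len(seqs)
    records = [
        SequenceRecord(record_id=i, sequence=s, clade=c)
        for i, s, c in zip(ids, seqs, clades)
    ]
    return AlignmentMatrix(records, coding_offset=coding_offset, **kw)


@pytest.fixture
def toy_matrix():
    # 4 records x 12 columns, in frame (offset 1), no gaps
    return make_matrix(
        [
            "ATGGCTTGCAAA",
            "ATGGCTTGCAAA",
            "ATGGCCTGCAAG",
            "ATGGCCAGCAAG",
        ]
    )


@pytest.fixture(scope="session")
def study_bundle():
    """One study-scale synthetic dataset reused by read-only tests."""
    return synthdata.generate_dataset(synthdata.SynthConfig(seed=11))
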