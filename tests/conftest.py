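import io

import pytest

from subsetq.fastq_io import ReadPair, ReadRecord


def make_read(read_id: str, qualities, sequence=None, offset: int = 33) -> ReadRecord:
    """Build a ReadRecord from integer quality scores."""
    qual = "".join(chr(q + offset) for q in qualities)
    seq = sequence if sequence is not None else "A" * len(qualities)
    return ReadRecord(read_id=read_id, sequence=seq, quality=qual)


def make_pair(pair_id: str, quals1, quals2) -> ReadPair:
    return ReadPair(
        mate1=make_read(f"{pair_id}/1", quals1),
        mate2=make_read(f"{pair_id}/2", quals2),
        pair_id=pair_id,
    )


def fastq_text(records) -> str:
    return "".join(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n" for r in records)


def fastq_stream(records) -> io.StringIO:
    return io.StringIO(fastq_text(records))


@pytest.fixture
def simple_reads():
    return [
        make_read("r1", [40, 40, 40, 40], sequence="ACGT"),
        make_read("r2", [2, 40, 40, 40], sequence="GGCC"),
        make_read("r3", [10, 10, 10, 10], sequence="ATAT"),
    ]
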