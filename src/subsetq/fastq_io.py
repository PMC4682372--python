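"""FASTQ/FASTA streaming I/O with gzip transparency and paired-end handling.

Records are modelled as a key/value pair: the read identifier is the key,
the sequence and quality strings are the value. Input may be single-end,
interleaved ("shuffled") paired-end, or two positionally synchronized files.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

__all__ = [
    "ReadRecord",
    "ReadPair",
    "FastqParseError",
    "PairSyncError",
    "read_fastq",
    "read_pairs",
    "write_subset",
    "write_pairs",
    "pair_stem",
    "open_maybe_gzip",
]

GZIP_MAGIC = b"\x1f\x8b"

#: lowest / highest legal quality characters ('!' .. '~')
_QCHAR_LO, _QCHAR_HI = 33, 126
_MAX_SCORE = 93

FASTA_WRAP = 80


class FastqParseError(ValueError):
    """Malformed FASTQ input; message names the record ordinal and violation."""


class PairSyncError(ValueError):
    """Paired-end streams lost synchronization."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases and per-base quality characters."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """Two mates bound by a shared identifier stem."""

    mate1: ReadRecord
    mate2: ReadRecord
    pair_id: str


def pair_stem(read_id: str) -> str:
    """Identifier stem shared by both mates.

    Strips a trailing ``/1`` or ``/2``; otherwise takes the first
    whitespace-delimited token (CASAVA 1.8-style headers).
    """
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id.split(None, 1)[0]


def open_maybe_gzip(
    source: Union[str, Path, IO], mode: str = "rt"
) -> IO:
    """Open ``source`` as a text stream, decompressing gzip transparently.

    Gzip is detected by the ``.gz`` extension or by the magic bytes when a
    binary stream is given. Text streams pass through unchanged.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, mode)
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == GZIP_MAGIC:
            return gzip.open(path, mode)
        return open(path, mode)
    # file-like
    if isinstance(source, io.TextIOBase):
        return source
    buffered = source if hasattr(source, "peek") else io.BufferedReader(source)
    if buffered.peek(2)[:2] == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=buffered))
    return io.TextIOWrapper(buffered)


def _validate_quality(quality: str, offset: int, ordinal: int, read_id: str) -> None:
    for pos, ch in enumerate(quality):
        code = ord(ch)
        if not (_QCHAR_LO <= code <= _QCHAR_HI) or not (
            0 <= code - offset <= _MAX_SCORE
        ):
            raise FastqParseError(
                f"record {ordinal} ({read_id!r}): quality character {ch!r} at "
                f"position {pos} is outside the valid range for offset {offset}"
            )


def read_fastq(
    source: Union[str, Path, IO], offset: int = 33
) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects from a 4-line FASTQ stream.

    Parameters
    ----------
    source:
        Path or stream; plain or gzip-compressed.
    offset:
        Quality encoding offset, 33 (Sanger) or 64.

    Raises
    ------
    FastqParseError
        On missing ``@``/``+`` markers, sequence/quality length mismatch, a
        truncated final record, or out-of-range quality characters. The error
        names the 1-based record ordinal.
    """
    if offset not in (33, 64):
        raise ValueError(f"unsupported quality offset {offset}")
    handle = open_maybe_gzip(source)
    ordinal = 0
    it = iter(handle)
    while True:
        header = next(it, None)
        if header is None:
            break
        header = header.rstrip("\n")
        if header == "" and next(it, None) is None:
            break  # trailing blank line
        ordinal += 1
        if not header.startswith("@"):
            raise FastqParseError(
                f"record {ordinal}: header line does not start with '@': "
                f"{header[:50]!r}"
            )
        lines = [next(it, None) for _ in range(3)]
        if any(line is None for line in lines):
            raise FastqParseError(f"record {ordinal}: truncated record at end of file")
        seq, plus, qual = (line.rstrip("\n") for line in lines)  # type: ignore[union-attr]
        if not plus.startswith("+"):
            raise FastqParseError(
                f"record {ordinal}: separator line does not start with '+': "
                f"{plus[:50]!r}"
            )
        read_id = header[1:]
        if len(seq) != len(qual):
            raise FastqParseError(
                f"record {ordinal} ({read_id!r}): sequence length {len(seq)} "
                f"!= quality length {len(qual)}"
            )
        if len(seq) == 0:
            raise FastqParseError(f"record {ordinal} ({read_id!r}): empty sequence")
        _validate_quality(qual, offset, ordinal, read_id)
        yield ReadRecord(read_id=read_id, sequence=seq, quality=qual)


def _pair_up(r1: ReadRecord, r2: ReadRecord) -> ReadPair:
    s1, s2 = pair_stem(r1.read_id), pair_stem(r2.read_id)
    if s1 != s2:
        raise PairSyncError(
            f"mate identifiers do not share a stem: {r1.read_id!r} vs {r2.read_id!r}"
        )
    return ReadPair(mate1=r1, mate2=r2, pair_id=s1)


def read_pairs(
    source1: Union[str, Path, IO],
    source2: Optional[Union[str, Path, IO]] = None,
    offset: int = 33,
) -> Iterator[ReadPair]:
    """Yield :class:`ReadPair` objects.

    With one source the stream is treated as interleaved (mate1, mate2,
    mate1, ...); with two sources the files must be positionally
    synchronized. Identifier stems are verified for every pair.
    """
    if source2 is None:
        it = read_fastq(source1, offset)
        while True:
            r1 = next(it, None)
            if r1 is None:
                return
            r2 = next(it, None)
            if r2 is None:
                raise PairSyncError(
                    f"interleaved input has an odd number of records; "
                    f"unpaired read {r1.read_id!r}"
                )
            yield _pair_up(r1, r2)
    else:
        it1, it2 = read_fastq(source1, offset), read_fastq(source2, offset)
        while True:
            r1, r2 = next(it1, None), next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                longer = source2 if r1 is None else source1
                raise PairSyncError(
                    f"paired files have unequal record counts ({longer!s} is longer)"
                )
            yield _pair_up(r1, r2)


def _write_fasta_record(record: ReadRecord, out: IO) -> None:
    out.write(f">{record.read_id}\n")
    seq = record.sequence
    for start in range(0, len(seq), FASTA_WRAP):
        out.write(seq[start : start + FASTA_WRAP])
        out.write("\n")


def _write_fastq_record(record: ReadRecord, out: IO) -> None:
    out.write(f"@{record.read_id}\n{record.sequence}\n+\n{record.quality}\n")


def write_subset(
    records: Iterable[ReadRecord], format: str, stream: IO
) -> int:
    """Write records as FASTA (quality dropped) or strict 4-line FASTQ.

    Returns the number of records written. Input order is preserved.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown output format {format!r}")
    writer = _write_fasta_record if format == "fasta" else _write_fastq_record
    count = 0
    for record in records:
        writer(record, stream)
        count += 1
    return count


def write_pairs(
    pairs: Iterable[ReadPair],
    format: str,
    stream1: IO,
    stream2: Optional[IO] = None,
) -> int:
    """Write pairs interleaved (one stream) or split by mate (two streams).

    Returns the number of pairs written.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown output format {format!r}")
    writer = _write_fasta_record if format == "fasta" else _write_fastq_record
    count = 0
    for pair in pairs:
        writer(pair.mate1, stream1)
        writer(pair.mate2, stream2 if stream2 is not None else stream1)
        count += 1
    return count
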