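"""Score distributions, cumulative views, dataset summaries, chunked merge.

Four distribution kinds are supported: per-base quality, per-read MQV,
per-read correctness score (product score binned on the 0-100 scale), and
per-pair PE-MQV. Large inputs can be processed in chunks whose partial
results merge into a result bit-identical to the serial computation.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

from .fastq_io import ReadPair, ReadRecord
from .scoring import decode_qualities, kmer_min_product_q, min_quality, product_q

__all__ = [
    "ScoreHistogram",
    "DatasetSummary",
    "HISTOGRAM_KINDS",
    "histogram",
    "merge",
    "cumulative",
    "summarize",
    "chunked_stats",
]

HISTOGRAM_KINDS = ("base_quality", "mqv", "correctness_score", "pe_mqv")

_BIN_RANGE = {
    "base_quality": (0, 93),
    "mqv": (0, 93),
    "pe_mqv": (0, 93),
    "correctness_score": (0, 100),
}


@dataclass
class ScoreHistogram:
    """Integer-binned counts of one score kind."""

    kind: str
    bins: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in HISTOGRAM_KINDS:
            raise ValueError(f"unknown histogram kind {self.kind!r}")

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def add(self, bin_: int, count: int = 1) -> None:
        lo, hi = _BIN_RANGE[self.kind]
        if not (lo <= bin_ <= hi):
            raise ValueError(
                f"bin {bin_} out of range [{lo}, {hi}] for kind {self.kind!r}"
            )
        self.bins[bin_] = self.bins.get(bin_, 0) + count


@dataclass
class DatasetSummary:
    """Whole-dataset statistics (read counts, lengths, quality, GC)."""

    n_reads: int
    total_bases: int
    mean_read_length: float
    mean_quality: float
    pct_bases_ge_q30: float
    pct_gc: float
    n_pairs: Optional[int] = None


def _bin_product(value: float) -> int:
    # floor(product * 100); a product of exactly 1.0 bins to 100
    return min(100, math.floor(value * 100.0))


def histogram(items: Iterable[Union[int, float]], kind: str) -> ScoreHistogram:
    """Bin scores into a :class:`ScoreHistogram`.

    Integer kinds bin identically; ``correctness_score`` takes raw products
    in ``[0, 1]`` and bins by ``floor(product * 100)``.
    """
    h = ScoreHistogram(kind=kind)
    if kind == "correctness_score":
        for value in items:
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"product score {value} outside [0, 1]")
            h.add(_bin_product(value))
    else:
        for value in items:
            h.add(int(value))
    return h


def merge(h1: ScoreHistogram, h2: ScoreHistogram) -> ScoreHistogram:
    """Bin-wise sum of two histograms of the same kind."""
    if h1.kind != h2.kind:
        raise ValueError(f"histogram kind mismatch: {h1.kind!r} vs {h2.kind!r}")
    bins = dict(h1.bins)
    for b, c in h2.bins.items():
        bins[b] = bins.get(b, 0) + c
    return ScoreHistogram(kind=h1.kind, bins=bins)


def cumulative(h: ScoreHistogram, direction: str = "at_least") -> Dict[int, float]:
    """Cumulative percentage view of a histogram.

    ``at_least[t]`` is the percentage of items with score >= t;
    ``at_most[t]`` the percentage with score <= t. The mapping covers every
    integer threshold from the smallest occupied bin to one past the
    largest (where ``at_least`` reaches 0).
    """
    if direction not in ("at_least", "at_most"):
        raise ValueError(f"unknown direction {direction!r}")
    total = h.total
    if total < 1:
        raise ValueError("cumulative view of an empty histogram is undefined")
    lo, hi = min(h.bins), max(h.bins)
    out: Dict[int, float] = {}
    if direction == "at_least":
        running = 0
        out[hi + 1] = 0.0
        for t in range(hi, lo - 1, -1):
            running += h.bins.get(t, 0)
            out[t] = 100.0 * running / total
    else:
        running = 0
        for t in range(lo, hi + 2):
            running += h.bins.get(t, 0)
            out[t] = 100.0 * running / total
    return out


# --- summary accumulation (integer partials so chunked == serial exactly) ---


@dataclass
class _Accum:
    kind: str
    n_reads: int = 0
    n_pairs: int = 0
    total_bases: int = 0
    quality_sum: int = 0
    bases_ge_q30: int = 0
    bases_gt_q30: int = 0
    gc_bases: int = 0
    bins: Dict[int, int] = field(default_factory=dict)

    def merge(self, other: "_Accum") -> "_Accum":
        merged_bins = dict(self.bins)
        for b, c in other.bins.items():
            merged_bins[b] = merged_bins.get(b, 0) + c
        return _Accum(
            kind=self.kind,
            n_reads=self.n_reads + other.n_reads,
            n_pairs=self.n_pairs + other.n_pairs,
            total_bases=self.total_bases + other.total_bases,
            quality_sum=self.quality_sum + other.quality_sum,
            bases_ge_q30=self.bases_ge_q30 + other.bases_ge_q30,
            bases_gt_q30=self.bases_gt_q30 + other.bases_gt_q30,
            gc_bases=self.gc_bases + other.gc_bases,
            bins=merged_bins,
        )


def _accumulate_read(acc: _Accum, read: ReadRecord, offset: int) -> None:
    acc.n_reads += 1
    acc.total_bases += len(read)
    scores = decode_qualities(read.quality, offset)
    acc.quality_sum += sum(scores)
    acc.bases_ge_q30 += sum(1 for s in scores if s >= 30)
    acc.bases_gt_q30 += sum(1 for s in scores if s > 30)
    acc.gc_bases += sum(1 for b in read.sequence if b in "GCgc")


def _score_chunk(
    chunk: Sequence[Union[ReadRecord, ReadPair]],
    kind: str,
    k: Optional[int],
    offset: int,
) -> _Accum:
    acc = _Accum(kind=kind)

    def add(bin_: int) -> None:
        acc.bins[bin_] = acc.bins.get(bin_, 0) + 1

    for item in chunk:
        if kind == "pe_mqv":
            assert isinstance(item, ReadPair)
            acc.n_pairs += 1
            _accumulate_read(acc, item.mate1, offset)
            _accumulate_read(acc, item.mate2, offset)
            add(
                min(
                    min_quality(item.mate1, offset),
                    min_quality(item.mate2, offset),
                )
            )
        else:
            assert isinstance(item, ReadRecord)
            _accumulate_read(acc, item, offset)
            if kind == "base_quality":
                for s in decode_qualities(item.quality, offset):
                    add(s)
            elif kind == "mqv":
                add(min_quality(item, offset))
            elif kind == "correctness_score":
                prod = (
                    product_q(item, offset)
                    if k is None
                    else kmer_min_product_q(item, k, offset)
                )
                add(_bin_product(prod))
    return acc


def _finalize(acc: _Accum, strict_q30: bool) -> Tuple[ScoreHistogram, DatasetSummary]:
    if acc.n_reads == 0:
        raise ValueError("no input records")
    q30 = acc.bases_gt_q30 if strict_q30 else acc.bases_ge_q30
    summary = DatasetSummary(
        n_reads=acc.n_reads,
        n_pairs=acc.n_pairs or None,
        total_bases=acc.total_bases,
        mean_read_length=acc.total_bases / acc.n_reads,
        mean_quality=acc.quality_sum / acc.total_bases,
        pct_bases_ge_q30=100.0 * q30 / acc.total_bases,
        pct_gc=100.0 * acc.gc_bases / acc.total_bases,
    )
    return ScoreHistogram(kind=acc.kind, bins=acc.bins), summary


def summarize(
    reads_or_pairs: Iterable[Union[ReadRecord, ReadPair]],
    offset: int = 33,
    strict_q30: bool = False,
) -> DatasetSummary:
    """Dataset summary over reads or pairs.

    ``pct_bases_ge_q30`` counts bases with score >= 30 by default
    (Illumina's Q30 convention); ``strict_q30`` switches to a strict >.
    """
    acc = _Accum(kind="mqv")
    for item in reads_or_pairs:
        if isinstance(item, ReadPair):
            acc.n_pairs += 1
            _accumulate_read(acc, item.mate1, offset)
            _accumulate_read(acc, item.mate2, offset)
        else:
            _accumulate_read(acc, item, offset)
    return _finalize(acc, strict_q30)[1]


def _chunks(
    items: Iterable, chunk_size: int
) -> Iterator[List]:
    chunk: List = []
    for item in items:
        chunk.append(item)
        if len(chunk) >= chunk_size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def chunked_stats(
    items: Iterable[Union[ReadRecord, ReadPair]],
    kind: str,
    k: Optional[int] = None,
    offset: int = 33,
    chunk_size: int = 10000,
    workers: int = 1,
    strict_q30: bool = False,
) -> Tuple[ScoreHistogram, DatasetSummary]:
    """Histogram + summary computed chunk-by-chunk and merged in order.

    The result is bit-identical to the serial computation for any
    ``chunk_size`` and ``workers``: all partial statistics are integer
    counts and sums, merged in input order, with divisions applied once at
    the end.
    """
    if kind not in HISTOGRAM_KINDS:
        raise ValueError(f"unknown histogram kind {kind!r}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if workers < 1:
        raise ValueError("workers must be >= 1")

    total = _Accum(kind=kind)
    chunks = _chunks(items, chunk_size)
    if workers == 1:
        for chunk in chunks:
            total = total.merge(_score_chunk(chunk, kind, k, offset))
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            for acc in pool.map(lambda c: _score_chunk(c, kind, k, offset), chunks):
                total = total.merge(acc)
    return _finalize(total, strict_q30)
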