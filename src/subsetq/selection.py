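"""Threshold determination and subset filtering.

Thresholds come either from a target subset fraction read off the
cumulative ("at least") score distribution, or from a target coverage depth
combined with a genome size. Filters keep single-end reads by MQV or
product score, pairs by PE-MQV, or items at random (seeded Bernoulli
baseline). The keep rule is inclusive (score >= threshold) everywhere; the
paired-end filter offers a strict > variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Optional, Tuple, TypeVar, Union

import numpy as np

from .fastq_io import ReadPair, ReadRecord
from .scoring import kmer_min_product_q, min_quality, product_q
from .stats import ScoreHistogram

__all__ = [
    "ThresholdSpec",
    "SelectionReport",
    "threshold_for_fraction",
    "fraction_for_depth",
    "filter_minq",
    "filter_productq",
    "filter_pe",
    "filter_random",
]

T = TypeVar("T", ReadRecord, ReadPair)


@dataclass(frozen=True)
class ThresholdSpec:
    """Selection mode plus its threshold (and mode-specific parameters)."""

    mode: str  # {"minq", "productq", "pe_minq", "random"}
    threshold: Union[int, float]
    k: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode in ("minq", "pe_minq"):
            if not (0 <= int(self.threshold) <= 93):
                raise ValueError(f"MQV threshold {self.threshold} outside [0, 93]")
        elif self.mode == "productq":
            if not (0.0 <= float(self.threshold) <= 1.0):
                raise ValueError(f"product threshold {self.threshold} outside [0, 1]")
        elif self.mode == "random":
            if not (0.0 < float(self.threshold) <= 1.0):
                raise ValueError(f"random fraction {self.threshold} outside (0, 1]")
        else:
            raise ValueError(f"unknown selection mode {self.mode!r}")


@dataclass
class SelectionReport:
    """Provenance of a filtering run: mode, threshold, counts."""

    mode: str
    threshold: Union[int, float]
    n_in: int = 0
    n_kept: int = 0
    k: Optional[int] = None
    seed: Optional[int] = None
    strict: bool = False
    estimated_depth_kept: Optional[float] = None
    warning: Optional[str] = None

    @property
    def kept_fraction(self) -> float:
        return self.n_kept / self.n_in if self.n_in else 0.0

    def as_dict(self) -> Dict:
        d = {
            "mode": self.mode,
            "threshold": self.threshold,
            "n_in": self.n_in,
            "n_kept": self.n_kept,
            "kept_fraction": self.kept_fraction,
        }
        if self.k is not None:
            d["k"] = self.k
        if self.seed is not None:
            d["seed"] = self.seed
        if self.strict:
            d["strict"] = True
        if self.estimated_depth_kept is not None:
            d["estimated_depth_kept"] = self.estimated_depth_kept
        if self.warning:
            d["warning"] = self.warning
        return d


def threshold_for_fraction(
    source: Union[ScoreHistogram, Dict[int, int]], target_fraction: float
) -> int:
    """Largest integer threshold keeping at least ``target_fraction``.

    The kept fraction at threshold t is the share of items scoring >= t.
    When the target falls between achievable fractions the threshold
    over-keeps (errs toward more data). Accepts a histogram or a raw
    bin -> count mapping.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError(f"target fraction {target_fraction} outside (0, 1]")
    bins = source.bins if isinstance(source, ScoreHistogram) else dict(source)
    if not bins:
        raise ValueError("cannot derive a threshold from an empty histogram")
    total = sum(bins.values())
    running = 0
    for t in sorted(bins, reverse=True):
        running += bins[t]
        if running / total >= target_fraction:
            return t
    # unreachable for target <= 1, kept for contract completeness
    warnings.warn("no threshold reaches the target fraction; keeping everything")
    return min(bins)


def fraction_for_depth(
    target_depth: float, genome_size: float, total_bases: float
) -> float:
    """Subset fraction needed to reach a target coverage depth.

    ``min(1, target_depth * genome_size / total_bases)``.
    """
    if target_depth <= 0 or genome_size <= 0 or total_bases <= 0:
        raise ValueError("target_depth, genome_size and total_bases must be positive")
    return min(1.0, target_depth * genome_size / total_bases)


def filter_minq(
    reads: Iterable[ReadRecord], t: int, offset: int = 33
) -> Tuple[Iterator[ReadRecord], SelectionReport]:
    """Keep reads with MQV >= ``t``, preserving order.

    Returns a lazy iterator plus a report that is populated as the iterator
    is consumed (final after exhaustion).
    """
    if not (0 <= t <= 93):
        raise ValueError(f"threshold {t} outside [0, 93]")
    report = SelectionReport(mode="minq", threshold=t)

    def gen() -> Iterator[ReadRecord]:
        for read in reads:
            report.n_in += 1
            if min_quality(read, offset) >= t:
                report.n_kept += 1
                yield read

    return gen(), report


def filter_productq(
    reads: Iterable[ReadRecord],
    threshold_product: float,
    k: Optional[int] = None,
    offset: int = 33,
) -> Tuple[Iterator[ReadRecord], SelectionReport]:
    """Keep reads whose product score is >= ``threshold_product``.

    Whole-read product when ``k`` is None, else the k-mer minimal product.
    """
    if not (0.0 <= threshold_product <= 1.0):
        raise ValueError(f"product threshold {threshold_product} outside [0, 1]")
    if k is not None and k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    report = SelectionReport(mode="productq", threshold=threshold_product, k=k)

    def gen() -> Iterator[ReadRecord]:
        for read in reads:
            report.n_in += 1
            score = (
                product_q(read, offset)
                if k is None
                else kmer_min_product_q(read, k, offset)
            )
            if score >= threshold_product:
                report.n_kept += 1
                yield read

    return gen(), report


def filter_pe(
    pairs: Iterable[ReadPair], t: int, offset: int = 33, strict: bool = False
) -> Tuple[Iterator[ReadPair], SelectionReport]:
    """Keep pairs whose PE-MQV passes ``t`` (>= by default, > if strict)."""
    if not (0 <= t <= 93):
        raise ValueError(f"threshold {t} outside [0, 93]")
    report = SelectionReport(mode="pe_minq", threshold=t, strict=strict)

    def gen() -> Iterator[ReadPair]:
        for pair in pairs:
            report.n_in += 1
            value = min(min_quality(pair.mate1, offset), min_quality(pair.mate2, offset))
            if (value > t) if strict else (value >= t):
                report.n_kept += 1
                yield pair

    return gen(), report


def filter_random(
    items: Iterable[T], fraction: float, seed: int
) -> Tuple[Iterator[T], SelectionReport]:
    """Keep each item independently with probability ``fraction``.

    Single-pass Bernoulli sampling; deterministic for a fixed seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    report = SelectionReport(mode="random", threshold=fraction, seed=seed)
    rng = np.random.default_rng(seed)

    def gen() -> Iterator[T]:
        for item in items:
            report.n_in += 1
            if rng.random() < fraction:
                report.n_kept += 1
                yield item

    return gen(), report
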