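"""Genome-size and coverage-depth estimation from k-mer multiplicities.

Genome size is estimated as the total number of k-mers in the reads
divided by the modal k-mer depth; coverage depth is then total bases
divided by the estimated genome size. Useful for depth-targeted subset
selection when no reference genome is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

from .fastq_io import ReadRecord

__all__ = [
    "CoverageEstimate",
    "reverse_complement",
    "kmer_multiplicity_histogram",
    "modal_kmer_depth",
    "estimate_coverage",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CoverageEstimate:
    """k-mer based genome size and coverage depth estimate."""

    k: int
    total_kmers: int
    kmer_depth_mode: int
    genome_size_est: float
    coverage_depth_est: float
    total_bases: int
    low_confidence: bool = False

    def as_dict(self) -> Dict:
        return {
            "k": self.k,
            "total_kmers": self.total_kmers,
            "kmer_depth_mode": self.kmer_depth_mode,
            "genome_size_est": self.genome_size_est,
            "coverage_depth_est": self.coverage_depth_est,
            "total_bases": self.total_bases,
            "low_confidence": self.low_confidence,
        }


def _iter_sequences(reads: Iterable) -> Iterable[str]:
    for read in reads:
        yield read.sequence if isinstance(read, ReadRecord) else str(read)


def kmer_multiplicity_histogram(
    reads: Iterable, k: int, canonical: bool = True
) -> Dict[int, int]:
    """Map multiplicity m -> number of distinct k-mers seen exactly m times.

    k-mers containing N are skipped. Canonical mode counts each k-mer as
    the lexicographic minimum of itself and its reverse complement, making
    the histogram strand-symmetric.
    """
    counts = _count_kmers(reads, k, canonical)[0]
    hist: Dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


def _count_kmers(
    reads: Iterable, k: int, canonical: bool
) -> Tuple[Dict[str, int], int, int]:
    """Returns (kmer counts, total windows incl. N-containing, total bases)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    counts: Dict[str, int] = {}
    total_windows = 0
    total_bases = 0
    for seq in _iter_sequences(reads):
        seq = seq.upper()
        total_bases += len(seq)
        n_windows = len(seq) - k + 1
        if n_windows <= 0:
            continue
        total_windows += n_windows
        for i in range(n_windows):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                rc = reverse_complement(kmer)
                if rc < kmer:
                    kmer = rc
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts, total_windows, total_bases


def modal_kmer_depth(multiplicity_histogram: Dict[int, int]) -> int:
    """Modal multiplicity, skipping the error-induced low-multiplicity tail.

    Scans the dense multiplicity axis for the first local minimum and
    returns the multiplicity with the largest distinct-k-mer count at or
    after it. A monotonically decreasing histogram has no such peak;
    multiplicity 1 is returned with a low-confidence warning.
    """
    if not multiplicity_histogram:
        raise ValueError("empty multiplicity histogram")
    hi = max(multiplicity_histogram)
    dense = [multiplicity_histogram.get(m, 0) for m in range(1, hi + 2)]
    local_min = None
    for i in range(len(dense) - 1):
        if dense[i + 1] > dense[i]:
            local_min = i
            break
    if local_min is None:
        warnings.warn(
            "k-mer multiplicity histogram is monotonically decreasing; "
            "no coverage peak found (low confidence)",
            stacklevel=2,
        )
        return 1
    best = max(range(local_min, len(dense)), key=lambda i: dense[i])
    return best + 1


def estimate_coverage(
    reads: Iterable, k: int = 25, canonical: bool = True
) -> CoverageEstimate:
    """Estimate genome size and coverage depth from reads.

    ``total_kmers`` counts every length-k window (including N-containing
    ones, which reflect sequencing volume) while the multiplicity histogram
    used for the peak skips them.
    """
    counts, total_windows, total_bases = _count_kmers(reads, k, canonical)
    if total_windows == 0:
        raise ValueError(f"no read of length >= k={k}; cannot estimate coverage")
    hist: Dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        mode = modal_kmer_depth(hist)
        low_confidence = any("low confidence" in str(w.message) for w in caught)
    genome_size = total_windows / mode
    return CoverageEstimate(
        k=k,
        total_kmers=total_windows,
        kmer_depth_mode=mode,
        genome_size_est=genome_size,
        coverage_depth_est=total_bases / genome_size,
        total_bases=total_bases,
        low_confidence=low_confidence,
    )
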