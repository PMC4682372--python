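"""Per-read quality scores.

Three read-level scores are computed from Phred base qualities:

* **MQV** — the minimal base quality of a read (minimum-quality selection
  statistic);
* **whole-read product score** — the product over all bases of the
  per-base correctness probability ``1 - 10**(-Q/10)``, suited to
  overlap/string-graph assembly;
* **k-mer minimal product score** — the minimum over the ``L - k + 1``
  length-k windows of the within-window product, suited to de Bruijn graph
  assembly.

For read pairs the pair score (PE-MQV) is the minimum of the two mates'
MQVs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .fastq_io import ReadPair, ReadRecord

__all__ = [
    "ScoredRead",
    "ScoredPair",
    "decode_qualities",
    "error_prob",
    "min_quality",
    "product_q",
    "kmer_min_product_q",
    "pe_mqv",
    "score_read",
]

_QCHAR_LO, _QCHAR_HI = 33, 126
_MAX_SCORE = 93


@dataclass(frozen=True)
class ScoredRead:
    """A read identifier with its integer MQV and/or real product score."""

    read_id: str
    read_length: int
    mqv: Optional[int] = None
    product_q: Optional[float] = None

    @property
    def correctness_score(self) -> Optional[float]:
        """Product score on the 0-100 reporting scale."""
        if self.product_q is None:
            return None
        return self.product_q * 100.0


@dataclass(frozen=True)
class ScoredPair:
    """A pair identifier with the pair-level minimal quality (PE-MQV)."""

    pair_id: str
    pe_mqv: int


def decode_qualities(quality: str, offset: int = 33) -> List[int]:
    """Decode a quality string into integer Phred scores.

    ``result[i] == ord(quality[i]) - offset``; every character must lie in
    ``'!'..'~'`` and decode into ``[0, 93]``.
    """
    scores: List[int] = []
    for pos, ch in enumerate(quality):
        code = ord(ch)
        score = code - offset
        if not (_QCHAR_LO <= code <= _QCHAR_HI) or not (0 <= score <= _MAX_SCORE):
            raise ValueError(
                f"quality character {ch!r} at position {pos} is invalid "
                f"for offset {offset}"
            )
        scores.append(score)
    return scores


def error_prob(q: int) -> float:
    """Base-calling error probability ``p = 10**(-Q/10)`` for score ``Q``."""
    if q < 0:
        raise ValueError(f"quality score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def min_quality(read: ReadRecord, offset: int = 33) -> int:
    """MQV of a read: the minimum decoded base quality."""
    # min over the raw characters equals min over decoded scores; validate
    # both extremes so out-of-range characters are never silently accepted.
    q = read.quality
    lo, hi = min(q), max(q)
    for ch in (lo, hi):
        code = ord(ch)
        if not (_QCHAR_LO <= code <= _QCHAR_HI) or not (
            0 <= code - offset <= _MAX_SCORE
        ):
            raise ValueError(
                f"read {read.read_id!r}: quality character {ch!r} invalid "
                f"for offset {offset}"
            )
    return ord(lo) - offset


def _quality_array(read: ReadRecord, offset: int) -> np.ndarray:
    codes = np.frombuffer(read.quality.encode("ascii"), dtype=np.uint8)
    q = codes.astype(np.int64) - offset
    if codes.min() < _QCHAR_LO or codes.max() > _QCHAR_HI or q.min() < 0 or q.max() > _MAX_SCORE:
        bad = int(np.argmax((codes < _QCHAR_LO) | (codes > _QCHAR_HI) | (q < 0) | (q > _MAX_SCORE)))
        raise ValueError(
            f"read {read.read_id!r}: quality character {read.quality[bad]!r} at "
            f"position {bad} invalid for offset {offset}"
        )
    return q


def product_q(read: ReadRecord, offset: int = 33) -> float:
    """Whole-read product of per-base correctness probabilities.

    Returns ``prod_i (1 - 10**(-Q_i/10))``; exactly ``0.0`` if any base has
    ``Q == 0``. Accumulated as a sum of ``log1p(-p)`` terms to avoid
    underflow on long reads.
    """
    q = _quality_array(read, offset)
    if (q == 0).any():
        return 0.0
    p = 10.0 ** (-q / 10.0)
    return float(math.exp(np.log1p(-p).sum()))


def kmer_min_product_q(read: ReadRecord, k: int, offset: int = 33) -> float:
    """Minimum over all length-``k`` windows of the within-window product.

    A read of length ``L`` has ``L - k + 1`` windows. Computed in O(L) via
    log-space prefix sums; windows containing a ``Q == 0`` base score
    exactly ``0.0``. Reads shorter than ``k`` are scored as their whole-read
    product (single short window) with a warning.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    q = _quality_array(read, offset)
    length = q.shape[0]
    if length < k:
        warnings.warn(
            f"read {read.read_id!r} shorter than k ({length} < {k}); "
            "scored as whole-read product",
            stacklevel=2,
        )
        k = length
    if (q == 0).any():
        # every zero-quality base lies in at least one window, and a window
        # containing a zero scores exactly 0, which is the global minimum
        return 0.0
    p = 10.0 ** (-q / 10.0)
    logs = np.log1p(-p)
    log_prefix = np.concatenate(([0.0], np.cumsum(logs)))
    n_windows = length - k + 1
    window_sums = log_prefix[k : k + n_windows] - log_prefix[:n_windows]
    return float(math.exp(window_sums.min()))


def pe_mqv(pair: ReadPair, offset: int = 33) -> ScoredPair:
    """Pair score: the minimum of the two mates' MQVs."""
    value = min(min_quality(pair.mate1, offset), min_quality(pair.mate2, offset))
    return ScoredPair(pair_id=pair.pair_id, pe_mqv=value)


def score_read(
    read: ReadRecord,
    offset: int = 33,
    with_product: bool = False,
    k: Optional[int] = None,
) -> ScoredRead:
    """Bundle a read's MQV (always) and product score (on request).

    With ``k`` set, the product score is the k-mer minimal variant;
    otherwise the whole-read product.
    """
    prod: Optional[float] = None
    if with_product or k is not None:
        prod = (
            product_q(read, offset) if k is None else kmer_min_product_q(read, k, offset)
        )
    return ScoredRead(
        read_id=read.read_id,
        read_length=len(read),
        mqv=min_quality(read, offset),
        product_q=prod,
    )
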