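"""Seeded synthetic FASTQ generation.

Provides i.i.d. quality models (uniform, categorical, and a low-quality
spike mixture that mimics datasets where most bases clear Q30 yet most
reads contain at least one low-quality base) and read sampling from random
toy genomes at a known depth, so every pipeline stage can be tested without
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .fastq_io import ReadPair, ReadRecord
from .kmer_coverage import reverse_complement

__all__ = [
    "QualityModel",
    "generate_reads",
    "generate_read_pairs",
    "generate_from_genome",
    "random_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_SCORE = 93


@dataclass(frozen=True)
class QualityModel:
    """Distribution of i.i.d. per-base quality scores.

    Kinds:

    * ``uniform`` — every base gets the same score;
    * ``iid_categorical`` — scores drawn from a finite set with given
      probabilities;
    * ``low_spike_mixture`` — with probability ``spike_prob`` a base draws
      uniformly from ``low_range``, otherwise uniformly from
      ``high_range``.
    """

    kind: str
    scores: Tuple[int, ...] = ()
    probs: Tuple[float, ...] = ()
    spike_prob: float = 0.0
    low_range: Tuple[int, int] = (2, 9)
    high_range: Tuple[int, int] = (30, 40)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "iid_categorical", "low_spike_mixture"):
            raise ValueError(f"unknown quality model kind {self.kind!r}")
        if self.kind == "uniform":
            if len(self.scores) != 1:
                raise ValueError("uniform model requires exactly one score")
        if self.kind == "iid_categorical":
            if len(self.scores) != len(self.probs) or not self.scores:
                raise ValueError("categorical model needs matching scores/probs")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError("categorical probabilities must sum to 1")
        if self.kind == "low_spike_mixture" and not (0.0 <= self.spike_prob <= 1.0):
            raise ValueError("spike probability must be in [0, 1]")
        for s in self._all_scores():
            if not (0 <= s <= _MAX_SCORE):
                raise ValueError(f"score {s} outside [0, {_MAX_SCORE}]")

    def _all_scores(self) -> Sequence[int]:
        if self.kind in ("uniform", "iid_categorical"):
            return self.scores
        return (*self.low_range, *self.high_range)

    @classmethod
    def uniform(cls, score: int) -> "QualityModel":
        return cls(kind="uniform", scores=(score,))

    @classmethod
    def categorical(
        cls, scores: Sequence[int], probs: Sequence[float]
    ) -> "QualityModel":
        return cls(kind="iid_categorical", scores=tuple(scores), probs=tuple(probs))

    @classmethod
    def low_spike(
        cls,
        spike_prob: float = 0.02,
        low_range: Tuple[int, int] = (2, 9),
        high_range: Tuple[int, int] = (30, 40),
    ) -> "QualityModel":
        return cls(
            kind="low_spike_mixture",
            spike_prob=spike_prob,
            low_range=low_range,
            high_range=high_range,
        )

    def sample_matrix(self, rng: np.random.Generator, n: int, length: int) -> np.ndarray:
        """Sample an (n, length) integer score matrix."""
        if self.kind == "uniform":
            return np.full((n, length), self.scores[0], dtype=np.int64)
        if self.kind == "iid_categorical":
            return rng.choice(
                np.array(self.scores, dtype=np.int64), size=(n, length), p=self.probs
            )
        low = rng.integers(self.low_range[0], self.low_range[1] + 1, size=(n, length))
        high = rng.integers(self.high_range[0], self.high_range[1] + 1, size=(n, length))
        spikes = rng.random((n, length)) < self.spike_prob
        return np.where(spikes, low, high)

    def base_prob_at_least(self, t: int) -> float:
        """P(single base quality >= t) under this model (analytic)."""
        if self.kind == "uniform":
            return 1.0 if self.scores[0] >= t else 0.0
        if self.kind == "iid_categorical":
            return sum(p for s, p in zip(self.scores, self.probs) if s >= t)

        def uniform_tail(lo: int, hi: int) -> float:
            width = hi - lo + 1
            return max(0, min(hi, _MAX_SCORE) - max(t, lo) + 1) / width

        return self.spike_prob * uniform_tail(*self.low_range) + (
            1.0 - self.spike_prob
        ) * uniform_tail(*self.high_range)


def _qual_string(scores: np.ndarray, offset: int = 33) -> str:
    return (scores.astype(np.uint8) + offset).tobytes().decode("ascii")


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_reads(
    n: int, length: int, model: QualityModel, seed: int, id_prefix: str = "sr"
) -> Iterator[ReadRecord]:
    """Yield ``n`` reads with uniform random bases and model-drawn qualities.

    Deterministic for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if length < 1:
        raise ValueError("read length must be >= 1")
    rng = np.random.default_rng(seed)
    batch = 10000
    emitted = 0
    while emitted < n:
        size = min(batch, n - emitted)
        quals = model.sample_matrix(rng, size, length)
        bases = rng.choice(_BASES, size=(size, length))
        for i in range(size):
            yield ReadRecord(
                read_id=f"{id_prefix}{emitted + i}",
                sequence=bases[i].tobytes().decode("ascii"),
                quality=_qual_string(quals[i]),
            )
        emitted += size


def generate_read_pairs(
    n: int, length: int, model: QualityModel, seed: int, id_prefix: str = "pr"
) -> Iterator[ReadPair]:
    """Yield ``n`` synthetic pairs (mates share an identifier stem)."""
    reads = generate_reads(2 * n, length, model, seed, id_prefix="tmp")
    index = 0
    for r1 in reads:
        r2 = next(reads)
        stem = f"{id_prefix}{index}"
        yield ReadPair(
            mate1=ReadRecord(f"{stem}/1", r1.sequence, r1.quality),
            mate2=ReadRecord(f"{stem}/2", r2.sequence, r2.quality),
            pair_id=stem,
        )
        index += 1


def random_genome(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass
class GenomeSimTruth:
    """Ground truth for reads simulated from a toy genome."""

    genome: str
    positions: List[int] = field(default_factory=list)
    inserts: List[int] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {
            "genome": self.genome,
            "positions": self.positions,
            "inserts": self.inserts,
        }


def generate_from_genome(
    genome_length: int,
    depth: float,
    read_length: int,
    model: QualityModel,
    seed: int,
    paired: bool = False,
    insert_mean: Optional[float] = None,
    insert_sd: float = 0.0,
    error_rate: float = 0.0,
    circular: bool = True,
):
    """Simulate reads (or pairs) from a random toy genome at a given depth.

    Returns ``(truth, reads)`` where ``truth`` records the genome and the
    0-based start position (and insert size, for pairs) of every fragment.
    Single-end mode emits ``round(depth * G / L)`` forward-strand reads;
    paired mode emits ``round(depth * G / (2 L))`` pairs whose mate2 is the
    reverse complement of the fragment end. Bases are error-free unless
    ``error_rate`` sets a uniform substitution probability.

    The genome is treated as circular by default (fragments may wrap past
    the end), giving every position identical expected coverage; set
    ``circular=False`` for a linear genome with edge effects.
    """
    if genome_length < read_length:
        raise ValueError("genome must be at least one read long")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    genome = random_genome(genome_length, rng)
    truth = GenomeSimTruth(genome=genome)

    def fragment(start: int, size: int) -> str:
        if start + size <= genome_length:
            return genome[start : start + size]
        return genome[start:] + genome[: start + size - genome_length]

    if paired:
        if insert_mean is None:
            insert_mean = 2.5 * read_length
        if insert_mean < read_length:
            raise ValueError("insert size must be at least the read length")
        n_pairs = round(depth * genome_length / (2 * read_length))
        pairs: List[ReadPair] = []
        quals = model.sample_matrix(rng, 2 * n_pairs, read_length)
        for i in range(n_pairs):
            insert = int(round(rng.normal(insert_mean, insert_sd))) if insert_sd else int(insert_mean)
            insert = max(read_length, min(insert, genome_length))
            hi = genome_length if circular else genome_length - insert + 1
            start = int(rng.integers(0, hi))
            frag = fragment(start, insert)
            seq1 = _mutate(frag[:read_length], rng, error_rate)
            seq2 = _mutate(reverse_complement(frag[-read_length:]), rng, error_rate)
            truth.positions.append(start)
            truth.inserts.append(insert)
            pairs.append(
                ReadPair(
                    mate1=ReadRecord(f"gp{i}/1", seq1, _qual_string(quals[2 * i])),
                    mate2=ReadRecord(f"gp{i}/2", seq2, _qual_string(quals[2 * i + 1])),
                    pair_id=f"gp{i}",
                )
            )
        return truth, pairs

    n_reads = round(depth * genome_length / read_length)
    quals = model.sample_matrix(rng, n_reads, read_length)
    reads: List[ReadRecord] = []
    hi = genome_length if circular else genome_length - read_length + 1
    for i in range(n_reads):
        start = int(rng.integers(0, hi))
        seq = _mutate(fragment(start, read_length), rng, error_rate)
        truth.positions.append(start)
        reads.append(ReadRecord(f"gr{i}", seq, _qual_string(quals[i])))
    return truth, reads


def _mutate(sequence: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")
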