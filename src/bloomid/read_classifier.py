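"""Read-to-genome assignment by k-mer voting.

Each k-mer window of a read that passes the mean-Phred quality gate is queried
against the index; unanimous k-mers cast a vote for their genome. The read is
assigned to the modal genome id iff strictly more than ``majority_threshold``
of the votes agree (the default 0.5 is a strict ">50%" majority); otherwise it
is discarded. Modal ties discard the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bloom_index import BloomIndex, encode_kmers, query_codes
from .io_formats import DISCARD, ReadAssignment, SequencingRead


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables for read classification.

    majority_threshold: fraction of kept k-mer votes the winner must strictly
        exceed; default 0.5.
    quality_threshold: minimum mean Phred score of a k-mer's bases for it to
        be queried at all; 0 disables the gate.
    """

    majority_threshold: float = 0.5
    quality_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.majority_threshold < 1.0:
            raise ValueError("majority_threshold must be in [0, 1)")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")


@dataclass
class ClassifierStats:
    total_reads: int = 0
    identified_reads: int = 0
    per_genome_reads: dict[int, int] = field(default_factory=dict)

    @property
    def discarded_reads(self) -> int:
        return self.total_reads - self.identified_reads

    @property
    def identified_fraction(self) -> float:
        return self.identified_reads / self.total_reads if self.total_reads else 0.0

    @property
    def identified_percent(self) -> float:
        return 100.0 * self.identified_fraction

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "identified_reads": self.identified_reads,
            "discarded_reads": self.discarded_reads,
            "identified_percent": self.identified_percent,
            "per_genome_reads": {str(k): v for k, v in self.per_genome_reads.items()},
        }


def kmer_quality_ok(
    qualities: Sequence[int], quality_threshold: float
) -> bool:
    """True iff the mean Phred score of the slice reaches the threshold."""
    if quality_threshold <= 0:
        return True
    return float(np.mean(qualities)) >= quality_threshold


def _window_mean_quality(qualities: Sequence[int], k: int) -> np.ndarray:
    q = np.asarray(qualities, dtype=np.float64)
    c = np.concatenate(([0.0], np.cumsum(q)))
    return (c[k:] - c[:-k]) / k


def classify_read(
    index: BloomIndex, read: SequencingRead, config: ClassifierConfig | None = None
) -> ReadAssignment:
    """Assign one read to a genome id, or discard it.

    Reads shorter than k, reads with no surviving k-mers, majority failures
    and modal ties all yield a DISCARD assignment.
    """
    config = config or ClassifierConfig()
    k = index.k

    def discarded(votes_total: int = 0, skipped: int = 0) -> ReadAssignment:
        return ReadAssignment(
            read_id=read.read_id, predicted_genome_id=DISCARD, votes_for=0,
            votes_total=votes_total, read_length=len(read),
            kmers_skipped_quality=skipped,
        )

    if len(read) < k:
        return discarded()
    codes, positions = encode_kmers(read.bases, k)
    skipped = 0
    if config.quality_threshold > 0 and codes.size:
        mean_q = _window_mean_quality(read.qualities, k)[positions]
        keep = mean_q >= config.quality_threshold
        skipped = int(codes.size - keep.sum())
        codes = codes[keep]
    if codes.size == 0:
        return discarded(skipped=skipped)

    votes = query_codes(index, codes)
    votes = votes[votes != DISCARD]
    votes_total = int(votes.size)
    if votes_total == 0:
        return discarded(skipped=skipped)
    counts = np.bincount(votes)
    top = int(counts.max())
    if (counts == top).sum() > 1:  # modal tie
        return discarded(votes_total=votes_total, skipped=skipped)
    winner = int(counts.argmax())
    if top / votes_total > config.majority_threshold:
        return ReadAssignment(
            read_id=read.read_id, predicted_genome_id=winner, votes_for=top,
            votes_total=votes_total, read_length=len(read),
            kmers_skipped_quality=skipped,
        )
    return discarded(votes_total=votes_total, skipped=skipped)


def classify_sample(
    index: BloomIndex,
    reads: Iterable[SequencingRead],
    config: ClassifierConfig | None = None,
) -> tuple[list[ReadAssignment], ClassifierStats]:
    """Classify a stream of reads; paired mates are treated independently.

    Returns the assignments of identified reads only, plus summary stats
    (total reads, identified count and percentage, per-genome read counts).
    """
    config = config or ClassifierConfig()
    stats = ClassifierStats()
    identified: list[ReadAssignment] = []
    for read in reads:
        a = classify_read(index, read, config)
        stats.total_reads += 1
        if a.identified:
            stats.identified_reads += 1
            stats.per_genome_reads[a.predicted_genome_id] = (
                stats.per_genome_reads.get(a.predicted_genome_id, 0) + 1
            )
            identified.append(a)
    return identified, stats
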