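"""Length and mean-quality filtering of raw long reads.

The mean read quality is defined in error-probability space: per-base Phred
scores are converted to error probabilities, averaged, and converted back
(mean_q = -10*log10(mean(10^(-q/10)))).  This is the convention of long-read
QC tools and weights low-quality bases more heavily than a plain arithmetic
mean of Q scores.  Both thresholds are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mean_phred(qual) -> float:
    """Phred-scaled mean error probability of a quality vector."""
    q = np.asarray(qual, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality vector")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


@dataclass
class ReadRecord:
    """One sequencing read: id, bases and per-base Phred scores."""

    read_id: str
    seq: str
    qual: np.ndarray

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != self.qual.size:
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")
        if self.qual.size and self.qual.min() < 0:
            raise ValueError(f"read {self.read_id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_q(self) -> float:
        return mean_phred(self.qual)

    def reverse_complement(self) -> "ReadRecord":
        return ReadRecord(self.read_id, revcomp(self.seq), self.qual[::-1].copy())


@dataclass(frozen=True)
class QcParams:
    min_length: int = 2900
    min_mean_q: float = 10.0

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_mean_q < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class DropLog:
    """Per-read drop reasons, in input order."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, read_id: str, reason: str) -> None:
        self.entries.append((read_id, reason))

    def __len__(self) -> int:
        return len(self.entries)


def filter_reads(
    reads: list[ReadRecord], params: QcParams
) -> tuple[list[ReadRecord], DropLog]:
    """Keep reads with length >= min_length and mean quality >= min_mean_q.

    Order is preserved; every dropped read is logged with the first failing
    criterion (length before quality).  Reads containing N are not rejected.
    """
    kept: list[ReadRecord] = []
    log = DropLog()
    for r in reads:
        if len(r) < params.min_length:
            log.add(r.read_id, "length")
        elif r.mean_q < params.min_mean_q:
            log.add(r.read_id, "quality")
        else:
            kept.append(r)
    return kept, log
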