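"""FASTQ handling, read filtering, and read-set summary statistics.

The filter removes reads shorter than ``min_length`` or with a mean quality
below ``min_quality``; both thresholds are inclusive on the keep side, i.e.
a 100 bp read at mean Q7.0 survives the defaults.  Mean quality is the
Phred-scaled arithmetic mean of per-base error probabilities, matching the
behaviour of standard nanopore filtering tools (not the arithmetic mean of
the Q values themselves).
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "ReadSetStats",
    "mean_read_quality",
    "filter_reads",
    "read_stats",
    "read_fastq",
    "write_fastq",
]

PHRED_OFFSET = 33


@dataclass
class Read:
    read_id: str
    sequence: str
    qualities: Sequence[int]  # list or integer ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return mean_read_quality(self.qualities)


def mean_read_quality(qualities: Iterable[int]) -> float:
    """Phred score of the mean per-base error probability.

    Q = -10 * log10( mean(10^(-q_i/10)) )
    """
    arr = np.asarray(qualities if not isinstance(qualities, (list, tuple)) else list(qualities),
                     dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute mean quality of an empty quality list")
    mean_p = float(np.mean(10.0 ** (-arr / 10.0)))
    return -10.0 * math.log10(mean_p)


def filter_reads(
    reads: Iterable[Read],
    min_length: int = 100,
    min_quality: float = 7.0,
) -> tuple[list[Read], list[tuple[Read, str]]]:
    """Partition reads into (kept, removed-with-reason).

    A read is removed if it is shorter than *min_length* OR its mean quality
    is below *min_quality*; length is checked first, so a short low-quality
    read is reported as "short".
    """
    kept: list[Read] = []
    removed: list[tuple[Read, str]] = []
    for read in reads:
        if len(read) < min_length:
            removed.append((read, "short"))
        # tolerance keeps reads at exactly the threshold despite log/exp rounding
        elif min_quality > 0 and read.mean_quality < min_quality - 1e-9:
            removed.append((read, "low_quality"))
        else:
            kept.append(read)
    return kept, removed


@dataclass
class ReadSetStats:
    n_reads: int
    total_bases: int
    mean_length: float
    n50: int | None  # None when the set is empty
    mean_quality: float | None

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "total_bases": self.total_bases,
            "mean_length": self.mean_length,
            "n50": self.n50,
            "mean_quality": self.mean_quality,
        }


def read_stats(reads: Iterable[Read]) -> ReadSetStats:
    """Summary statistics; n50 is the length L such that reads of length >= L
    together account for at least half of all bases."""
    reads = list(reads)
    if not reads:
        return ReadSetStats(0, 0, 0.0, None, None)
    lengths = sorted((len(r) for r in reads), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for length in lengths:
        acc += length
        if acc * 2 >= total:
            n50 = length
            break
    # pooled mean error probability over all bases
    total_p = sum(
        float(np.sum(10.0 ** (-np.asarray(r.qualities, dtype=float) / 10.0)))
        for r in reads
        if len(r.qualities)
    )
    mean_q = -10.0 * math.log10(total_p / total) if total else None
    return ReadSetStats(
        n_reads=len(reads),
        total_bases=total,
        mean_length=total / len(reads),
        n50=n50,
        mean_quality=mean_q,
    )


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode.rstrip("t") or "r")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate 4-line FASTQ records (plain or gzip), Phred+33."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            read_id = title.split()[0]
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int)
            yield Read(read_id, seq, (quals - PHRED_OFFSET).tolist())


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for read in reads:
            qarr = np.asarray(read.qualities, dtype=np.uint8) + PHRED_OFFSET
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qarr.tobytes().decode('ascii')}\n")


def write_stats_json(stats: ReadSetStats, path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(stats.to_dict(), out, indent=2)
        out.write("\n")
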