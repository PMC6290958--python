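"""Paired-end read self-assembly into full-length amplicon consensus reads.

An amplicon fragment shorter than twice the read length guarantees that read 1
and read 2 overlap in the middle; merging the pair into one consensus sequence
covers the whole amplicon and lets the two reads error-correct each other in
the overlap.  The contract here is a simplified, fully specified stand-in for
a read assembler: the overlap maximizing (matches - mismatches) wins, ties go
to the longer overlap, and consensus bases take the higher-quality read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from ._fastq import FastqRead, revcomp

__all__ = ["MergedRead", "MergeStats", "merge_pair", "merge_pairs"]

_MAX_Q = 41


@dataclass(frozen=True)
class MergedRead:
    """One merged pair: full-length consensus plus overlap diagnostics."""

    sequence: str
    quality: str
    overlap_len: int
    n_overlap_mismatches: int


@dataclass
class MergeStats:
    n_input: int = 0
    n_merged: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_merged

    @property
    def merge_rate(self) -> float:
        return self.n_merged / self.n_input if self.n_input else 0.0


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33


def merge_pair(
    read1: FastqRead,
    read2: FastqRead,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
) -> MergedRead | None:
    """Merge one pair, or return None when the pair is rejected.

    ``read2`` is supplied in sequencing orientation and reverse-complemented
    here.  The best overlap maximizes (matches - mismatches); among equal
    scores the longer overlap wins.  In the overlap, agreeing bases get
    quality min(q1 + q2, 41); disagreeing positions take the higher-quality
    base (read 1 on ties) with quality |q1 - q2|.  Rejection (no overlap of at
    least ``min_overlap``, or a mismatch fraction above ``max_mismatch_frac``)
    is an outcome, not an error.
    """
    s1 = np.frombuffer(read1.sequence.encode(), dtype=np.uint8)
    s2 = np.frombuffer(revcomp(read2.sequence).encode(), dtype=np.uint8)
    q1 = _phred(read1.quality)
    q2 = _phred(read2.quality)[::-1]
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        raise ValueError("reads must be non-empty")

    best_score = None
    best_ov = 0
    best_matches = 0
    for ov in range(min_overlap, min(n1, n2) + 1):
        matches = int(np.count_nonzero(s1[n1 - ov :] == s2[:ov]))
        score = 2 * matches - ov
        if best_score is None or score >= best_score:
            best_score, best_ov, best_matches = score, ov, matches
    if best_score is None:
        return None
    mismatches = best_ov - best_matches
    if mismatches / best_ov > max_mismatch_frac:
        return None

    ov = best_ov
    o1, o2 = s1[n1 - ov :], s2[:ov]
    oq1, oq2 = q1[n1 - ov :], q2[:ov]
    agree = o1 == o2
    cons = np.where(oq1 >= oq2, o1, o2)
    cons_q = np.where(agree, np.minimum(oq1 + oq2, _MAX_Q), np.abs(oq1 - oq2))
    seq = (s1[: n1 - ov].tobytes() + cons.tobytes() + s2[ov:].tobytes()).decode()
    qual = np.concatenate([q1[: n1 - ov], cons_q, q2[ov:]])
    qual_str = (qual.astype(np.uint8) + 33).tobytes().decode()
    return MergedRead(
        sequence=seq,
        quality=qual_str,
        overlap_len=ov,
        n_overlap_mismatches=int(mismatches),
    )


def merge_pairs(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.25,
    stats: MergeStats | None = None,
) -> Iterator[MergedRead]:
    """Merge a stream of pairs, yielding merged reads (rejections are dropped
    and tallied in ``stats``).

    Amplicon libraries contain massive read duplication, so results are
    memoized on the (sequence, quality) strings of the pair; merging is a pure
    function of those, which keeps deep samples fast without changing output.
    """
    own_stats = stats if stats is not None else MergeStats()
    cache: dict[tuple[str, str, str, str], MergedRead | None] = {}
    for r1, r2 in pairs:
        key = (r1.sequence, r1.quality, r2.sequence, r2.quality)
        if key not in cache:
            cache[key] = merge_pair(r1, r2, min_overlap, max_mismatch_frac)
        merged = cache[key]
        own_stats.n_input += 1
        if merged is not None:
            own_stats.n_merged += 1
            yield merged
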