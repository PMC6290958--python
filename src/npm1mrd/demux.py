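"""Dual-index demultiplexing.

Each read carries two independent 10-nt sample indices (i7 on the forward
primer, i5 on the reverse).  A read is assigned to a sample only when *both*
indices match that sample within ``max_mismatch``; reads whose two indices
point at different samples are the signature of index hopping / barcode
cross-contamination and are quarantined rather than assigned, which is the
point of the dual-index design for an assay calling variants at 1e-5 VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._fastq import FastqRead

__all__ = ["SampleSheet", "DemuxReport", "DemuxResult", "demultiplex", "hamming"]


def hamming(a: str, b: str) -> int:
    """Hamming distance; length mismatch counts each extra position."""
    if len(a) != len(b):
        return max(len(a), len(b)) - min(len(a), len(b)) + hamming(
            a[: min(len(a), len(b))], b[: min(len(a), len(b))]
        )
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SampleSheet:
    """Rows of (sample_id, i7, i5); ids and index pairs must be unique."""

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        pairs = [(r[1], r[2]) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(i7, i5) pairs must be unique")
        for _, i7, i5 in self.rows:
            if len(i7) != 10 or len(i5) != 10:
                raise ValueError("indices must be exactly 10 nt")

    def sample_ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        rows = []
        lines = Path(path).read_text().splitlines()
        for line in lines:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[:3] == ["sample_id", "i7", "i5"]:
                continue
            rows.append((cols[0], cols[1], cols[2]))
        return cls(rows=tuple(rows))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\ti7\ti5\n")
            for sid, i7, i5 in self.rows:
                fh.write(f"{sid}\t{i7}\t{i5}\n")


@dataclass
class DemuxReport:
    """Read-assignment tallies; assigned + unassigned + conflict == total."""

    assigned: dict[str, int]
    unassigned: int = 0
    conflict: int = 0

    @property
    def total(self) -> int:
        return sum(self.assigned.values()) + self.unassigned + self.conflict

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for sid, n in self.assigned.items():
                fh.write(f"{sid}\t{n}\n")
            fh.write(f"unassigned\t{self.unassigned}\n")
            fh.write(f"conflict\t{self.conflict}\n")


@dataclass
class DemuxResult:
    by_sample: dict[str, tuple[list[FastqRead], list[FastqRead]]]
    conflict_reads: tuple[list[FastqRead], list[FastqRead]]
    unassigned_reads: tuple[list[FastqRead], list[FastqRead]]
    report: DemuxReport = field(default=None)  # type: ignore[assignment]


def _match_index(obs: str, known: Sequence[str], max_mismatch: int) -> int | None:
    """Row index of the unique sheet index within max_mismatch, else None.

    N (or any non-ACGT) bases count as mismatches via plain Hamming distance.
    """
    for i, k in enumerate(known):
        if hamming(obs, k) <= max_mismatch:
            return i
    return None


def demultiplex(
    reads1: Iterable[FastqRead],
    reads2: Iterable[FastqRead],
    sheet: SampleSheet,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Partition a multiplexed run into per-sample read pairs.

    Assignment requires both indices to match the same sample row within
    ``max_mismatch``; i7 matching one sample and i5 another is a conflict
    (quarantined); any index matching no sample leaves the read unassigned.
    The sheet must keep same-role indices at Hamming distance >= 2*max_mismatch+1
    so matches are unambiguous; this is checked before any read is processed.
    """
    i7s = [r[1] for r in sheet.rows]
    i5s = [r[2] for r in sheet.rows]
    for pool in (i7s, i5s):
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if hamming(pool[i], pool[j]) < 2 * max_mismatch + 1:
                    raise ValueError(
                        "sample sheet indices too close for "
                        f"max_mismatch={max_mismatch}: {pool[i]} vs {pool[j]}"
                    )

    by_sample: dict[str, tuple[list[FastqRead], list[FastqRead]]] = {
        sid: ([], []) for sid in sheet.sample_ids()
    }
    conflict: tuple[list[FastqRead], list[FastqRead]] = ([], [])
    unassigned: tuple[list[FastqRead], list[FastqRead]] = ([], [])
    report = DemuxReport(assigned={sid: 0 for sid in sheet.sample_ids()})
    cache: dict[tuple[str, str] | None, tuple[str, str | None]] = {}

    for r1, r2 in zip(reads1, reads2):
        pair = r1.index_pair
        if pair not in cache:
            if pair is None:
                cache[pair] = ("unassigned", None)
            else:
                hit7 = _match_index(pair[0], i7s, max_mismatch)
                hit5 = _match_index(pair[1], i5s, max_mismatch)
                if hit7 is None or hit5 is None:
                    cache[pair] = ("unassigned", None)
                elif hit7 == hit5:
                    cache[pair] = ("assigned", sheet.rows[hit7][0])
                else:
                    cache[pair] = ("conflict", None)
        kind, sid = cache[pair]
        if kind == "assigned":
            assert sid is not None
            by_sample[sid][0].append(r1)
            by_sample[sid][1].append(r2)
            report.assigned[sid] += 1
        elif kind == "conflict":
            conflict[0].append(r1)
            conflict[1].append(r2)
            report.conflict += 1
        else:
            unassigned[0].append(r1)
            unassigned[1].append(r2)
            report.unassigned += 1

    return DemuxResult(
        by_sample=by_sample,
        conflict_reads=conflict,
        unassigned_reads=unassigned,
        report=report,
    )
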