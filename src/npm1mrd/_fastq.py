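"""Shared FASTQ record type and gzip text I/O (Phred+33, 4-line records)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pysam

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class FastqRead(NamedTuple):
    """One FASTQ record; ``comment`` holds the Illumina-style header tail
    (``1:N:0:<i7>+<i5>``) carrying the dual sample indices."""

    name: str
    sequence: str
    quality: str
    comment: str | None = None

    @property
    def index_pair(self) -> tuple[str, str] | None:
        """(i7, i5) parsed from the header comment, or None."""
        if not self.comment:
            return None
        tail = self.comment.rsplit(":", 1)[-1]
        if "+" not in tail:
            return None
        i7, _, i5 = tail.partition("+")
        return i7, i5


def _open_text_out(path: Path):
    if path.suffix == ".gz":
        # fixed mtime so identical record streams give identical bytes
        import io

        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return io.TextIOWrapper(gz)
    return open(path, "w")


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    """Write records to ``path`` (gzipped iff the suffix is ``.gz``).

    Output bytes are a pure function of the records, so reruns of a seeded
    simulation produce byte-identical files.
    """
    path = Path(path)
    n = 0
    with _open_text_out(path) as fh:
        for r in reads:
            header = f"@{r.name} {r.comment}" if r.comment else f"@{r.name}"
            fh.write(f"{header}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream records via pysam's FASTX reader (handles gzip transparently)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRead(
                name=entry.name,
                sequence=entry.sequence,
                quality=entry.quality or "",
                comment=entry.comment,
            )
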