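"""Amplicon reference model, HGVS insertion parsing and the mutation catalog.

The assay targets a single PCR amplicon covering NPM1 exon 12, where AML-defining
frameshift insertions (type A = insTCTG, type B = insCATG, type D = insCCTG and
rarer variants) cluster in a short hotspot window.  Everything downstream —
simulation, alignment, calling — is parameterized by :class:`AmpliconReference`,
so the packaged synthetic stand-in amplicon can be replaced by a real one
without code changes.

Coordinates are 0-based half-open throughout; HGVS ``c.``-numbering appears only
at the parse/format boundary, where cDNA coordinate ``c`` maps to amplicon index
``c - coding_offset``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "AmpliconReference",
    "InsertionSpec",
    "MutationCatalog",
    "HgvsParseError",
    "parse_hgvs_ins",
    "format_hgvs_ins",
    "left_normalize",
    "classify_insertion",
    "apply_insertion",
    "load_default_reference",
    "load_default_catalog",
    "BIOINF_CONTROL_HGVS",
    "CONTROL_SAMPLE_ID",
]

_DNA = re.compile(r"^[ACGT]+$")

#: HGVS string of the synthetic 20-nt pipeline-integrity control insertion that
#: is spiked into every sequencing run under a reserved index pair.
BIOINF_CONTROL_HGVS = "c.869_870insACGTTAGCCTAGGATCATGC"

#: Sample-sheet id reserved for the bioinformatics control library.
CONTROL_SAMPLE_ID = "BIOINF-CTRL"


class HgvsParseError(ValueError):
    """Raised when an HGVS insertion string cannot be parsed."""


@dataclass(frozen=True)
class AmpliconReference:
    """A single amplicon sequence plus its insertion hotspot and cDNA anchor.

    Parameters
    ----------
    name:
        Record name (FASTA id).
    sequence:
        Uppercase A/C/G/T amplicon sequence, 150-400 nt.
    hotspot:
        Half-open ``[start, end)`` interval in 0-based amplicon coordinates
        where exon-12 insertions are expected; at least 12 nt wide.
    coding_offset:
        cDNA coordinate (``c.``-number) of ``sequence[0]``; amplicon index ``i``
        corresponds to ``c.(coding_offset + i)``.
    """

    name: str
    sequence: str
    hotspot: tuple[int, int]
    coding_offset: int

    def __post_init__(self) -> None:
        if not _DNA.match(self.sequence):
            raise ValueError("amplicon sequence must be uppercase A/C/G/T only")
        if not 150 <= len(self.sequence) <= 400:
            raise ValueError("amplicon length must be in [150, 400] nt")
        start, end = self.hotspot
        if not 0 <= start < end <= len(self.sequence):
            raise ValueError("hotspot must satisfy 0 <= start < end <= length")
        if end - start < 12:
            raise ValueError("hotspot must be at least 12 nt wide")

    def __len__(self) -> int:
        return len(self.sequence)

    def index_to_cdna(self, index: int) -> int:
        return self.coding_offset + index

    def cdna_to_index(self, cdna: int) -> int:
        return cdna - self.coding_offset

    def in_hotspot(self, position0: int) -> bool:
        return self.hotspot[0] <= position0 < self.hotspot[1]


@dataclass(frozen=True, order=True)
class InsertionSpec:
    """One insertion: ``inserted`` bases placed between amplicon positions
    ``position0 - 1`` and ``position0`` (0-based gap coordinate)."""

    position0: int
    inserted: str

    def __post_init__(self) -> None:
        if not self.inserted or not _DNA.match(self.inserted):
            raise ValueError("inserted sequence must be non-empty A/C/G/T")
        if self.position0 < 0:
            raise ValueError("position0 must be non-negative")


def parse_hgvs_ins(hgvs: str, ref: AmpliconReference) -> InsertionSpec:
    """Parse an HGVS-style insertion such as ``c.873_874insGCCA``.

    The two cDNA coordinates must be consecutive; the gap they flank maps to a
    0-based amplicon position through ``ref.coding_offset``.

    Raises
    ------
    HgvsParseError
        On a malformed string (the message names the offending token).
    ValueError
        When the coordinates fall outside the amplicon.
    """
    m = re.match(r"^c\.(\d+)_(\d+)ins([A-Za-z]+)$", hgvs.strip())
    if m is None:
        raise HgvsParseError(f"not a c.<int>_<int>ins<DNA> insertion: {hgvs!r}")
    left, right, inserted = int(m.group(1)), int(m.group(2)), m.group(3).upper()
    if right != left + 1:
        raise HgvsParseError(f"coordinates not consecutive: {left}_{right}")
    if not _DNA.match(inserted):
        raise HgvsParseError(f"inserted sequence is not DNA: {m.group(3)!r}")
    position0 = ref.cdna_to_index(right)
    if not 1 <= position0 <= len(ref) - 1:
        raise ValueError(
            f"insertion gap c.{left}_{right} lies outside amplicon {ref.name!r}"
        )
    return InsertionSpec(position0=position0, inserted=inserted)


def format_hgvs_ins(spec: InsertionSpec, ref: AmpliconReference) -> str:
    """Inverse of :func:`parse_hgvs_ins`: render ``c.<l>_<r>ins<seq>``."""
    left = ref.index_to_cdna(spec.position0 - 1)
    return f"c.{left}_{left + 1}ins{spec.inserted}"


def apply_insertion(spec: InsertionSpec, ref: AmpliconReference) -> str:
    """Return the mutant amplicon sequence implied by ``spec``."""
    if spec.position0 > len(ref):
        raise ValueError("insertion position beyond amplicon end")
    s = ref.sequence
    return s[: spec.position0] + spec.inserted + s[spec.position0 :]


def left_normalize(spec: InsertionSpec, ref: AmpliconReference) -> InsertionSpec:
    """Shift an insertion maximally left (VCF-style left alignment).

    While the base immediately left of the gap equals the last inserted base,
    the insertion can be slid one position left by rotating the inserted
    string; the mutant sequence is unchanged.  Idempotent by construction.
    """
    pos, ins = spec.position0, spec.inserted
    s = ref.sequence
    while pos > 0 and s[pos - 1] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        pos -= 1
    if (pos, ins) == (spec.position0, spec.inserted):
        return spec
    return InsertionSpec(position0=pos, inserted=ins)


@dataclass(frozen=True)
class MutationCatalog:
    """Known exon-12 insertion types, keyed by left-normalized (gap, bases)."""

    entries: tuple[tuple[str, InsertionSpec], ...]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("catalog labels must be unique")
        keys = [(s.position0, s.inserted) for _, s in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("catalog entries must be distinct after normalization")

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return [label for label, _ in self.entries]

    def spec_for(self, label: str) -> InsertionSpec:
        for lab, spec in self.entries:
            if lab == label:
                return spec
        raise KeyError(label)

    def lookup(self, spec: InsertionSpec) -> str | None:
        for label, entry in self.entries:
            if (entry.position0, entry.inserted) == (spec.position0, spec.inserted):
                return label
        return None

    @classmethod
    def from_tsv(cls, path: str | Path, ref: AmpliconReference) -> "MutationCatalog":
        """Load a TSV with columns ``label`` and ``hgvs`` (``#`` comments allowed);
        entries are left-normalized against ``ref`` on load."""
        entries: list[tuple[str, InsertionSpec]] = []
        header_seen = False
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            if not header_seen:
                if line.split("\t")[:2] != ["label", "hgvs"]:
                    raise ValueError("catalog TSV must have columns: label, hgvs")
                header_seen = True
                continue
            label, hgvs = line.split("\t")[:2]
            spec = left_normalize(parse_hgvs_ins(hgvs, ref), ref)
            entries.append((label, spec))
        return cls(entries=tuple(entries))


def classify_insertion(spec: InsertionSpec, catalog: MutationCatalog) -> str:
    """Catalog label for a left-normalized insertion, or ``"novel"``."""
    label = catalog.lookup(spec)
    return label if label is not None else "novel"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("npm1mrd").joinpath("data", name)))


def load_default_reference() -> AmpliconReference:
    """Load the packaged amplicon (a synthetic stand-in for the assay's NPM1
    exon-12 amplicon, whose primer-defined sequence is not public)."""
    fasta = _data_path("synthetic_amplicon.fasta")
    record = next(SeqIO.parse(str(fasta), "fasta"))
    meta: dict[str, int] = {}
    for line in _data_path("synthetic_amplicon.meta.tsv").read_text().splitlines()[1:]:
        key, value = line.split("\t")
        meta[key] = int(value)
    return AmpliconReference(
        name=record.id,
        sequence=str(record.seq).upper(),
        hotspot=(meta["hotspot_start"], meta["hotspot_end"]),
        coding_offset=meta["coding_offset"],
    )


def load_default_catalog(ref: AmpliconReference | None = None) -> MutationCatalog:
    """Load the packaged 12-entry insertion catalog (see the TSV header for
    which entries are literature-anchored and which are synthetic fixtures)."""
    if ref is None:
        ref = load_default_reference()
    catalog = MutationCatalog.from_tsv(_data_path("mutation_catalog.tsv"), ref)
    for _, spec in catalog.entries:
        if not ref.in_hotspot(spec.position0):
            raise ValueError("catalog entry outside hotspot after normalization")
    return catalog
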