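"""Targeted alignment and ultrasensitive insertion calling on the amplicon.

Because the assay interrogates a single locus, merged reads are aligned
directly to the amplicon with an affine-gap global aligner instead of a
genome-wide mapper: for a one-amplicon library both carry the same
information, and the direct route allows exact-match fast paths that make
million-read samples tractable.  Detected insertions are left-normalized,
grouped, and subjected to the assay's calling rule: a variant needs at least
``min_mutant_reads`` (default 2) supporting reads to pass.  VAF is supporting
reads over hotspot-spanning depth.

Scoring contract: match +1, mismatch -2, gap open -6 plus -1 per gapped base,
leftmost (normalized) gap placement.  A read with more than 20% of its bases
mismatched is unalignable and excluded from depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
from Bio import Align

from .pairmerge import MergedRead
from .reference_catalog import (
    BIOINF_CONTROL_HGVS,
    CONTROL_SAMPLE_ID,
    AmpliconReference,
    InsertionSpec,
    MutationCatalog,
    classify_insertion,
    format_hgvs_ins,
    left_normalize,
    parse_hgvs_ins,
)

__all__ = [
    "ReadAlignment",
    "InsertionCall",
    "SampleCallResult",
    "ControlVerdict",
    "AmpliconAligner",
    "align_read",
    "call_sample",
    "verify_bioinformatics_control",
    "calls_to_tsv",
    "calls_to_vcf",
]

MATCH = 1
MISMATCH = -2
GAP_OPEN = -6       # charged once per gap, on top of the per-base extension
GAP_EXTEND = -1
MISMATCH_FLOOR_FRAC = 0.20


@dataclass(frozen=True)
class ReadAlignment:
    """Alignment summary of one merged read against the amplicon."""

    insertions: tuple[InsertionSpec, ...]
    n_mismatches: int
    score: float
    ref_span: tuple[int, int]
    unalignable: bool = False


class AmpliconAligner:
    """Glocal affine aligner for one amplicon with exact-match fast paths.

    Fast paths (``fast_path=True``, the default):

    * a read identical to the reference needs no alignment at all;
    * any sequence seen before (reference haplotype, a mutant haplotype, or a
      recurring error read) is served from a hash map;
    * a read of reference length with at most 3 mismatches cannot be improved
      by gaps under this scoring (two gap opens cost more than the mismatches
      they could save), so it is scored gap-free directly.

    All fast paths are bit-identical to the full dynamic program; the property
    is covered by tests.
    """

    def __init__(self, ref: AmpliconReference, fast_path: bool = True) -> None:
        self.ref = ref
        self.fast_path = fast_path
        self._ref_bytes = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        self._cache: dict[str, ReadAlignment] = {}
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "global"
        self._aligner.match_score = MATCH
        self._aligner.mismatch_score = MISMATCH
        # Biopython charges open_gap_score for the first gapped base, so a
        # length-L gap costs GAP_OPEN + L * GAP_EXTEND as advertised above.
        self._aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
        self._aligner.extend_gap_score = GAP_EXTEND

    def align(self, sequence: str) -> ReadAlignment:
        L = len(self.ref)
        if self.fast_path:
            hit = self._cache.get(sequence)
            if hit is not None:
                return hit
        result = self._align_uncached(sequence, L)
        if self.fast_path:
            self._cache[sequence] = result
        return result

    def _align_uncached(self, sequence: str, L: int) -> ReadAlignment:
        if not 0.5 * L <= len(sequence) <= 1.5 * L:
            return ReadAlignment((), 0, float("-inf"), (0, 0), unalignable=True)
        if sequence == self.ref.sequence:
            return ReadAlignment((), 0, float(L), (0, L))
        if self.fast_path and len(sequence) == L:
            m = int(
                np.count_nonzero(
                    np.frombuffer(sequence.encode(), dtype=np.uint8)
                    != self._ref_bytes
                )
            )
            if m <= 3:
                return ReadAlignment((), m, float(L - 3 * m), (0, L))
        return self._full_alignment(sequence)

    def _full_alignment(self, sequence: str) -> ReadAlignment:
        alignment = self._aligner.align(self.ref.sequence, sequence)[0]
        ref_blocks, read_blocks = (np.asarray(b) for b in alignment.aligned)
        insertions: list[InsertionSpec] = []
        n_mismatch = 0

        # leading read overhang = insertion at the first aligned ref position
        if read_blocks[0][0] > 0:
            insertions.append(
                InsertionSpec(
                    position0=int(ref_blocks[0][0]),
                    inserted=sequence[: read_blocks[0][0]],
                )
            )
        for k in range(len(ref_blocks)):
            r0, r1 = ref_blocks[k]
            q0, q1 = read_blocks[k]
            seg_ref = self.ref.sequence[r0:r1]
            seg_read = sequence[q0:q1]
            n_mismatch += sum(a != b for a, b in zip(seg_ref, seg_read))
            if k + 1 < len(ref_blocks):
                gap_read = sequence[q1 : read_blocks[k + 1][0]]
                if gap_read:  # ref gap -> insertion in the read
                    insertions.append(
                        InsertionSpec(position0=int(r1), inserted=gap_read)
                    )
        if read_blocks[-1][1] < len(sequence):
            insertions.append(
                InsertionSpec(
                    position0=int(ref_blocks[-1][1]),
                    inserted=sequence[read_blocks[-1][1] :],
                )
            )

        if n_mismatch > MISMATCH_FLOOR_FRAC * len(sequence):
            return ReadAlignment((), n_mismatch, float(alignment.score),
                                 (0, 0), unalignable=True)
        normalized = tuple(left_normalize(s, self.ref) for s in insertions)
        span = (int(ref_blocks[0][0]), int(ref_blocks[-1][1]))
        return ReadAlignment(normalized, n_mismatch, float(alignment.score), span)


def align_read(
    read: MergedRead | str,
    ref: AmpliconReference,
    aligner: AmpliconAligner | None = None,
) -> ReadAlignment:
    """Align one merged read (see :class:`AmpliconAligner` for the contract)."""
    seq = read.sequence if isinstance(read, MergedRead) else read
    if aligner is None:
        aligner = AmpliconAligner(ref)
    return aligner.align(seq)


@dataclass(frozen=True)
class InsertionCall:
    """One detected insertion in one sample."""

    spec: InsertionSpec
    label: str
    supporting_reads: int
    depth: int
    vaf: float
    passed: bool

    def __post_init__(self) -> None:
        if not 0 <= self.supporting_reads <= self.depth:
            raise ValueError("supporting_reads must lie in [0, depth]")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must lie in [0, 1]")


@dataclass
class SampleCallResult:
    """Per-sample calling outcome with QC tallies."""

    sample_id: str
    calls: list[InsertionCall]
    depth: int
    n_input: int
    n_unalignable: int
    n_wildtype: int
    no_coverage: bool = False
    control_verdict: "ControlVerdict | None" = field(default=None)

    def pass_calls(self) -> list[InsertionCall]:
        return [c for c in self.calls if c.passed]

    def vaf_of(self, spec: InsertionSpec) -> float:
        for call in self.calls:
            if call.spec == spec:
                return call.vaf
        return 0.0

    def has_pass_call(self, spec: InsertionSpec) -> bool:
        return any(c.passed and c.spec == spec for c in self.calls)


def call_sample(
    reads: Iterable[MergedRead | str],
    ref: AmpliconReference,
    catalog: MutationCatalog,
    sample_id: str = "sample",
    min_mutant_reads: int = 2,
    min_flank: int = 10,
    aligner: AmpliconAligner | None = None,
) -> SampleCallResult:
    """Call exon-12 insertions in one sample of merged reads.

    Depth counts reads whose alignment spans the hotspot with at least
    ``min_flank`` reference bases on each side; identical left-normalized
    insertions inside the hotspot are grouped, and a call passes when its
    supporting reads reach ``min_mutant_reads`` (assay rule: 2).  All distinct
    insertions are reported — the assay watches for clonal switches, so
    secondary insertions matter.  Calls are sorted by VAF, descending.
    """
    if aligner is None:
        aligner = AmpliconAligner(ref)
    hs_lo, hs_hi = ref.hotspot
    need_lo = max(0, hs_lo - min_flank)
    need_hi = min(len(ref), hs_hi + min_flank)

    depth = 0
    n_input = 0
    n_unalignable = 0
    n_wildtype = 0
    support: dict[InsertionSpec, int] = {}
    for read in reads:
        n_input += 1
        aln = align_read(read, ref, aligner)
        if aln.unalignable:
            n_unalignable += 1
            continue
        spans = aln.ref_span[0] <= need_lo and aln.ref_span[1] >= need_hi
        if spans:
            depth += 1
        hotspot_ins = {s for s in aln.insertions if ref.in_hotspot(s.position0)}
        if spans and hotspot_ins:
            for spec in hotspot_ins:
                support[spec] = support.get(spec, 0) + 1
        else:
            n_wildtype += 1

    if depth == 0:
        return SampleCallResult(
            sample_id=sample_id, calls=[], depth=0, n_input=n_input,
            n_unalignable=n_unalignable, n_wildtype=n_wildtype, no_coverage=True,
        )
    calls = [
        InsertionCall(
            spec=spec,
            label=classify_insertion(spec, catalog),
            supporting_reads=n_sup,
            depth=depth,
            vaf=n_sup / depth,
            passed=n_sup >= min_mutant_reads,
        )
        for spec, n_sup in support.items()
    ]
    calls.sort(key=lambda c: (-c.vaf, c.spec))
    return SampleCallResult(
        sample_id=sample_id, calls=calls, depth=depth, n_input=n_input,
        n_unalignable=n_unalignable, n_wildtype=n_wildtype,
    )


class ControlVerdict(NamedTuple):
    """Run-level verdict of the 20-nt-insertion bioinformatics control."""

    passed: bool
    detail: str
    call: InsertionCall | None = None


def verify_bioinformatics_control(
    results: Mapping[str, SampleCallResult],
    ref: AmpliconReference,
    control_sample_id: str = CONTROL_SAMPLE_ID,
    expected: InsertionSpec | None = None,
) -> ControlVerdict:
    """Check that the run's spiked control sample recovered its 20-nt insertion.

    A failing control invalidates MRD reporting for the whole run: it means
    the pipeline could not see a large, abundant insertion and cannot be
    trusted with a 1e-5 one.
    """
    if expected is None:
        expected = left_normalize(parse_hgvs_ins(BIOINF_CONTROL_HGVS, ref), ref)
    result = results.get(control_sample_id)
    if result is None:
        return ControlVerdict(False, "control missing")
    if result.no_coverage:
        return ControlVerdict(False, "control sample has no coverage")
    for call in result.calls:
        if call.passed and call.spec == expected:
            return ControlVerdict(
                True,
                f"control insertion recovered ({len(call.spec.inserted)} nt, "
                f"VAF {call.vaf:.3f})",
                call,
            )
    return ControlVerdict(False, "control insertion not recovered")


def calls_to_tsv(result: SampleCallResult, path: str | Path,
                 ref: AmpliconReference) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\thgvs\tlabel\tsupporting_reads\tdepth\tvaf\tpass\n")
        for c in result.calls:
            fh.write(
                f"{result.sample_id}\t{format_hgvs_ins(c.spec, ref)}\t{c.label}\t"
                f"{c.supporting_reads}\t{c.depth}\t{c.vaf:.6g}\t"
                f"{'PASS' if c.passed else 'FAIL'}\n"
            )


def calls_to_vcf(result: SampleCallResult, path: str | Path,
                 ref: AmpliconReference) -> None:
    """Minimal single-sample VCF 4.2 with the anchored-base insertion encoding."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.name},length={len(ref)}>\n")
        fh.write('##INFO=<ID=SUP,Number=1,Type=Integer,Description='
                 '"Supporting reads">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description='
                 '"Hotspot-spanning depth">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description='
                 '"Variant allele frequency">\n')
        fh.write('##INFO=<ID=LABEL,Number=1,Type=String,Description='
                 '"Catalog label">\n')
        fh.write('##FILTER=<ID=min_reads,Description='
                 '"Fewer supporting reads than the calling threshold">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in result.calls:
            anchor = ref.sequence[c.spec.position0 - 1]
            fh.write(
                f"{ref.name}\t{c.spec.position0}\t.\t{anchor}\t"
                f"{anchor + c.spec.inserted}\t.\t"
                f"{'PASS' if c.passed else 'min_reads'}\t"
                f"SUP={c.supporting_reads};DP={c.depth};VAF={c.vaf:.6g};"
                f"LABEL={c.label.replace(' ', '_')}\n"
            )
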