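"""Seeded synthetic-read generator for the NPM1 amplicon MRD assay.

Emulates what the wet lab puts on the sequencer: dual-indexed paired-end
amplicon libraries in which a known fraction of input molecules carry an
exon-12 insertion (cell-line dilutions, patient samples, blanks), plus the
synthetic 20-nt "bioinformatics control" library spiked into every run under a
reserved index pair.  Every fragment spans the full amplicon; read 1 is the
fragment's first ``read_length`` bases and read 2 the reverse complement of its
last ``read_length`` bases, as for 150-bp paired-end chemistry on a ~250-bp
amplicon.

Error model: independent per-base substitutions at ``sub_error_rate`` and rare
1-nt insertion/deletion errors at ``indel_error_rate``; base qualities are the
Phred equivalent of the substitution rate.  Index hopping swaps one of a read's
two indices to another sample's index at ``hop_rate``.  All randomness derives
from explicit integer seeds; identical configuration gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, NamedTuple

import numpy as np

from ._fastq import FastqRead, revcomp
from .demux import SampleSheet
from .reference_catalog import (
    BIOINF_CONTROL_HGVS,
    CONTROL_SAMPLE_ID,
    AmpliconReference,
    InsertionSpec,
    apply_insertion,
    parse_hgvs_ins,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "RunTruth",
    "simulate_sample",
    "simulate_run",
    "simulate_blank_cohort",
    "simulate_dilution_series",
    "dilution_series_configs",
    "derive_seed",
    "default_index_pairs",
    "control_insertion",
    "CONTROL_SAMPLE_ID",
    "CONTROL_INDEX_PAIR",
]

# 10-mer index pools with pairwise Hamming distance >= 5 within each role;
# the last pair is reserved for the run's bioinformatics control.
_I7_POOL = [
    "CTTCCCGTGT", "TATATCCCAT", "GTCTTCGAGA", "AGGTGGATCG", "GTAACAACTG",
    "TTTGGCTTCA", "CGTAATTATT", "CGCCTCCTTC", "AGACAATGTT", "GGCATGAAGT",
    "TACGCTGAGT", "GGTAAAGTCT", "ATCGTAGGTG", "TCCTGTGCAG", "GTGAGACTAG",
    "TCAACGGTGA", "CAGCAGGCGA",
]
_I5_POOL = [
    "GTATAAGGCG", "CCCAGAAGGG", "ATGTGTCAAT", "GGAGCAATGC", "CCCTTGGTTA",
    "GACTACACGA", "AAGGATTAAC", "TCGACTAACG", "GCTGAGTAGA", "CGCGAGGCTT",
    "TGAAGCTCGG", "TGGGCGACTG", "GTACATGAAC", "GATACCAGAA", "GCGTATTTAT",
    "GAATTGGTAT", "TCCTTGACAC",
]

CONTROL_INDEX_PAIR = (_I7_POOL[-1], _I5_POOL[-1])

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_index_pairs(n: int) -> list[tuple[str, str]]:
    """First ``n`` packaged (i7, i5) index pairs (control pair excluded)."""
    if n > len(_I7_POOL) - 1:
        raise ValueError(f"at most {len(_I7_POOL) - 1} sample index pairs available")
    return list(zip(_I7_POOL[:n], _I5_POOL[:n]))


def control_insertion(ref: AmpliconReference) -> InsertionSpec:
    """The fixed 20-nt control insertion in amplicon coordinates."""
    return parse_hgvs_ins(BIOINF_CONTROL_HGVS, ref)


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and integer keys."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SimConfig:
    """Per-sample simulation settings.

    ``mutant_fraction`` is the probability that an input molecule carries
    ``mutation``; with 2n template molecules per diploid genome this is the VAF
    being emulated.
    """

    sample_id: str
    seed: int
    n_fragments: int
    mutant_fraction: float = 0.0
    mutation: InsertionSpec | None = None
    read_length: int = 150
    sub_error_rate: float = 1e-3
    indel_error_rate: float = 1e-6
    index_pair: tuple[str, str] | None = None
    hop_rate: float = 0.0

    def __post_init__(self) -> None:
        for rate in (self.mutant_fraction, self.sub_error_rate,
                     self.indel_error_rate, self.hop_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be non-negative")
        if self.index_pair is not None:
            i7, i5 = self.index_pair
            if len(i7) != 10 or len(i5) != 10:
                raise ValueError("index sequences must be exactly 10 nt")
        if self.mutant_fraction > 0 and self.mutation is None:
            raise ValueError("mutant_fraction > 0 requires a mutation")


class TruthRecord(NamedTuple):
    """Ground truth for one simulated sample."""

    sample_id: str
    n_fragments: int
    n_mutant: int
    mutation: InsertionSpec | None

    @property
    def true_fraction(self) -> float:
        return self.n_mutant / self.n_fragments if self.n_fragments else 0.0


class RunTruth(NamedTuple):
    """Ground truth for a multiplexed run."""

    samples: dict[str, TruthRecord]
    hopped: dict[str, int]

    @property
    def total_hopped(self) -> int:
        return sum(self.hopped.values())


def _phred_char(rate: float) -> str:
    q = 40 if rate <= 0 else int(round(-10.0 * np.log10(rate)))
    return chr(33 + min(40, max(2, q)))


def _reads_from_template(
    template: str,
    n: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    qual_char: str,
) -> tuple[list[str], list[str]]:
    """Vectorized read generation: n fragments of ``template`` -> (r1, r2)."""
    if n == 0:
        return [], []
    out: list[list[str]] = []
    for mate_template in (template, revcomp(template)):
        t = mate_template[: cfg.read_length]
        codes = _CODE[np.frombuffer(t.encode(), dtype=np.uint8)]
        arr = np.tile(codes, (n, 1))
        total = arr.size
        # substitutions: sample error positions with replacement (collisions
        # are negligible at the rates simulated) and force a different base
        k = rng.binomial(total, cfg.sub_error_rate)
        if k:
            flat = arr.reshape(-1)
            idx = rng.integers(0, total, size=k)
            flat[idx] = (flat[idx] + rng.integers(1, 4, size=k)) % 4
        raw = _ASCII[arr].tobytes()
        w = len(t)
        seqs = [raw[i * w : (i + 1) * w].decode("ascii") for i in range(n)]
        # rare 1-nt indel errors, applied per affected read
        k2 = rng.binomial(total, cfg.indel_error_rate)
        for ridx, pos, is_ins, base in zip(
            rng.integers(0, n, size=k2),
            rng.integers(0, w, size=k2),
            rng.random(size=k2) < 0.5,
            rng.integers(0, 4, size=k2),
        ):
            s = seqs[ridx]
            if is_ins:
                seqs[ridx] = s[:pos] + "ACGT"[base] + s[pos:]
            else:
                seqs[ridx] = s[:pos] + s[pos + 1 :]
        out.append(seqs)
    return out[0], out[1]


def simulate_sample(
    cfg: SimConfig, ref: AmpliconReference
) -> tuple[list[FastqRead], list[FastqRead], TruthRecord]:
    """Simulate one dual-indexed amplicon library.

    Each of ``cfg.n_fragments`` molecules is mutant with probability
    ``cfg.mutant_fraction`` (one binomial draw); mutant molecules carry
    ``cfg.mutation`` applied to the reference.  Returns read-1 records, read-2
    records (same order) and the exact ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fragments
    n_mut = int(rng.binomial(n, cfg.mutant_fraction)) if cfg.mutant_fraction else 0
    qual = _phred_char(cfg.sub_error_rate)

    mut_r1: list[str] = []
    mut_r2: list[str] = []
    if n_mut:
        assert cfg.mutation is not None
        mut_template = apply_insertion(cfg.mutation, ref)
        mut_r1, mut_r2 = _reads_from_template(mut_template, n_mut, cfg, rng, qual)
    wt_r1, wt_r2 = _reads_from_template(ref.sequence, n - n_mut, cfg, rng, qual)

    order = rng.permutation(n)
    all_r1 = mut_r1 + wt_r1
    all_r2 = mut_r2 + wt_r2
    comment = None
    if cfg.index_pair is not None:
        comment = f"1:N:0:{cfg.index_pair[0]}+{cfg.index_pair[1]}"
    reads1 = []
    reads2 = []
    for out_i, src_i in enumerate(order):
        name = f"{cfg.sample_id}:{out_i}"
        s1, s2 = all_r1[src_i], all_r2[src_i]
        reads1.append(FastqRead(name, s1, qual * len(s1), comment))
        reads2.append(FastqRead(name, s2, qual * len(s2), comment))
    truth = TruthRecord(cfg.sample_id, n, n_mut, cfg.mutation)
    return reads1, reads2, truth


def _control_config(seed: int, n_reads: int, ref: AmpliconReference) -> SimConfig:
    return SimConfig(
        sample_id=CONTROL_SAMPLE_ID,
        seed=seed,
        n_fragments=n_reads,
        mutant_fraction=1.0,
        mutation=control_insertion(ref),
        index_pair=CONTROL_INDEX_PAIR,
        indel_error_rate=0.0,
    )


def simulate_run(
    samples: list[SimConfig],
    ref: AmpliconReference,
    include_bioinf_control: bool = False,
    control_reads: int = 2000,
) -> tuple[list[FastqRead], list[FastqRead], SampleSheet, RunTruth]:
    """Simulate a multiplexed sequencing run.

    Concatenates all samples' reads with index sequences in the header comment,
    optionally adds the 20-nt-insertion bioinformatics control under its
    reserved index pair, then applies index hopping: for each sample, a
    ``hop_rate`` fraction of reads has one index (i7 or i5, coin flip) replaced
    by the corresponding index of another sample in the run.
    """
    cfgs = list(samples)
    for cfg in cfgs:
        if cfg.index_pair is None:
            raise ValueError(f"sample {cfg.sample_id!r} has no index pair")
    if include_bioinf_control:
        ctrl_seed = derive_seed(cfgs[0].seed, 0xC0)
        cfgs.append(_control_config(ctrl_seed, control_reads, ref))
    pairs = [cfg.index_pair for cfg in cfgs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate index pair in run")

    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    truths: dict[str, TruthRecord] = {}
    hopped: dict[str, int] = {}
    for cfg in cfgs:
        r1, r2, truth = simulate_sample(cfg, ref)
        n_hop = 0
        if cfg.hop_rate > 0:
            if len(cfgs) < 2:
                raise ValueError("index hopping requires >= 2 samples in the run")
            hrng = np.random.default_rng(derive_seed(cfg.seed, 0x40))
            n_hop = int(hrng.binomial(len(r1), cfg.hop_rate))
            which = hrng.choice(len(r1), size=n_hop, replace=False)
            others = [p for p in pairs if p != cfg.index_pair]
            for ridx in which:
                donor = others[int(hrng.integers(0, len(others)))]
                i7, i5 = cfg.index_pair
                if hrng.random() < 0.5:
                    i7 = donor[0]
                else:
                    i5 = donor[1]
                comment = f"1:N:0:{i7}+{i5}"
                r1[ridx] = r1[ridx]._replace(comment=comment)
                r2[ridx] = r2[ridx]._replace(comment=comment)
        reads1.extend(r1)
        reads2.extend(r2)
        truths[cfg.sample_id] = truth
        hopped[cfg.sample_id] = n_hop

    sheet = SampleSheet(
        rows=tuple((c.sample_id, c.index_pair[0], c.index_pair[1]) for c in cfgs)
    )
    return reads1, reads2, sheet, RunTruth(samples=truths, hopped=hopped)


def simulate_blank_cohort(
    template: SimConfig, ref: AmpliconReference, n_samples: int = 30
) -> Iterator[tuple[list[FastqRead], list[FastqRead], TruthRecord]]:
    """Yield ``n_samples`` mutation-free samples differing only in seed.

    Mirrors a limit-of-blank experiment on normal donor DNA; per-sample seeds
    are derived from ``template.seed`` via :func:`derive_seed`.
    """
    if template.mutant_fraction != 0:
        raise ValueError("blank template must have mutant_fraction == 0")
    for i in range(n_samples):
        cfg = replace(
            template,
            sample_id=f"{template.sample_id}-blank{i:02d}",
            seed=derive_seed(template.seed, 0xB1, i),
        )
        yield simulate_sample(cfg, ref)


def dilution_series_configs(
    fractions: list[float],
    depth: int,
    seed: int,
    mutation: InsertionSpec,
    read_length: int = 150,
    sub_error_rate: float = 1e-3,
    indel_error_rate: float = 1e-6,
) -> list[SimConfig]:
    """One config per mutant fraction, identical depth and error settings."""
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if any(a < b for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be in descending order")
    return [
        SimConfig(
            sample_id=f"dil-{fraction:g}",
            seed=derive_seed(seed, 0xD1, i),
            n_fragments=depth,
            mutant_fraction=fraction,
            mutation=mutation if fraction > 0 else None,
            read_length=read_length,
            sub_error_rate=sub_error_rate,
            indel_error_rate=indel_error_rate,
        )
        for i, fraction in enumerate(fractions)
    ]


def simulate_dilution_series(
    fractions: list[float],
    depth: int,
    seed: int,
    ref: AmpliconReference,
    mutation: InsertionSpec,
    **kwargs,
) -> Iterator[tuple[float, list[FastqRead], list[FastqRead], TruthRecord]]:
    """Yield (fraction, reads1, reads2, truth) per dilution level, lazily so a
    deep series never holds more than one level in memory."""
    cfgs = dilution_series_configs(fractions, depth, seed, mutation, **kwargs)
    for fraction, cfg in zip(fractions, cfgs):
        r1, r2, truth = simulate_sample(cfg, ref)
        yield fraction, r1, r2, truth
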