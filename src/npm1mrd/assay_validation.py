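"""Assay validation: limit of blank, limit of detection, precision controls.

The clinical claim behind an MRD assay is not "we can align reads" but "a
reported VAF of 1e-5 means mutant DNA was present".  That claim rests on three
designed experiments, implemented here in their standard clinical-laboratory
forms:

* **Limit of blank** — highest apparent mutant signal expected from
  mutation-free DNA, taken as the nonparametric (1 - alpha) order statistic of
  background VAFs over a cohort of blanks (30 normal samples in the assay's
  own validation).
* **Limit of detection** — lowest mutant fraction of a dilution series at
  which the spiked mutation is called in at least ``required_hit_rate`` of
  replicates with every measured VAF above the LOB.
* **Precision controls** — high (0.2% VAF) and low (0.02% VAF) controls run
  alongside every sequencing run and monitored Levey-Jennings style against
  the running mean/SD of previous runs: beyond 2 SD warns, beyond 3 SD (or two
  consecutive same-side warnings) fails the run.

The module also provides simulation drivers that regenerate these experiments
end-to-end (simulate reads, merge, call) so the validation statistics can be
recomputed from scratch at any time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .insertion_caller import AmpliconAligner, SampleCallResult, call_sample
from .pairmerge import merge_pairs
from .readsim import SimConfig, derive_seed, simulate_blank_cohort, simulate_sample
from .reference_catalog import (
    AmpliconReference,
    InsertionSpec,
    MutationCatalog,
    left_normalize,
    load_default_catalog,
    load_default_reference,
)

__all__ = [
    "limit_of_blank",
    "limit_of_detection",
    "monitor_precision",
    "DilutionObservation",
    "LodResult",
    "ControlSeries",
    "ValidationReport",
    "precision_control_config",
    "measure_sample_vaf",
    "run_blank_experiment",
    "run_dilution_experiment",
    "run_sensitivity_experiment",
    "PRECISION_CONTROL_VAF",
]

#: Nominal VAFs of the high and low run precision controls (mutant cell-line
#: DNA diluted into normal DNA at 0.2% and 0.02%).
PRECISION_CONTROL_VAF = {"high": 0.002, "low": 0.0002}


def limit_of_blank(blank_vafs: Sequence[float], alpha: float = 0.05) -> float:
    """Nonparametric LOB: the (1 - alpha) order statistic of blank VAFs.

    With sorted blanks ``x(1) <= ... <= x(n)``, returns ``x(ceil((1-alpha)*n))``
    (so ``alpha=0`` gives the maximum); 0 when every blank is clean.  Needs at
    least two blanks.
    """
    if len(blank_vafs) < 2:
        raise ValueError("limit_of_blank requires at least 2 blank samples")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    if all(v == 0 for v in blank_vafs):
        return 0.0
    s = sorted(blank_vafs)
    rank = math.ceil((1.0 - alpha) * len(s))  # 1-based
    return float(s[max(rank, 1) - 1])


@dataclass(frozen=True)
class DilutionObservation:
    """One replicate of one dilution level."""

    fraction: float
    detected: bool
    vaf: float


@dataclass
class LodResult:
    lod_fraction: float | None
    reached: bool
    table: pd.DataFrame  # fraction, replicates, detected, min_vaf

    def __str__(self) -> str:
        if self.reached:
            return f"LOD = {self.lod_fraction:g}"
        return "LOD not reached"


def limit_of_detection(
    observations: Iterable[DilutionObservation],
    lob_vaf: float = 0.0,
    required_hit_rate: float = 0.95,
) -> LodResult:
    """Hit-rate LOD over a dilution series.

    The LOD is the smallest fraction whose replicates are detected at
    ``required_hit_rate`` or better *and* whose measured VAFs all exceed the
    LOB; when no level qualifies the result is flagged not-reached with the
    full table attached.
    """
    obs = list(observations)
    fractions = sorted({o.fraction for o in obs}, reverse=True)
    if len(fractions) < 2:
        raise ValueError("limit_of_detection requires >= 2 dilution levels")
    rows = []
    qualifying: list[float] = []
    for fraction in fractions:
        level = [o for o in obs if o.fraction == fraction]
        n_det = sum(o.detected for o in level)
        hit_rate = n_det / len(level)
        min_vaf = min(o.vaf for o in level)
        ok = hit_rate >= required_hit_rate and all(o.vaf > lob_vaf for o in level)
        rows.append(
            {
                "fraction": fraction,
                "replicates": len(level),
                "detected": n_det,
                "hit_rate": hit_rate,
                "min_vaf": min_vaf,
                "qualifies": ok,
            }
        )
        if ok:
            qualifying.append(fraction)
    table = pd.DataFrame(rows)
    if not qualifying:
        return LodResult(lod_fraction=None, reached=False, table=table)
    return LodResult(lod_fraction=min(qualifying), reached=True, table=table)


@dataclass
class ControlSeries:
    """Run-indexed measurements of the high/low precision controls.

    ``runs`` maps run label -> {"high": vaf or None, "low": vaf or None};
    insertion order is chronological.
    """

    runs: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def add_run(self, run_id: str, high: float | None, low: float | None) -> None:
        self.runs[run_id] = {"high": high, "low": low}


def monitor_precision(series: ControlSeries, baseline_n: int = 5) -> dict[str, str]:
    """Levey-Jennings evaluation of a precision-control series.

    The first ``baseline_n`` runs establish the baseline and are in-control by
    definition (unless a control is missing, which always fails that run).
    Later runs are judged per level against the running mean/SD of all prior
    runs: |z| > 3 fails, |z| > 2 warns, and two consecutive same-side warnings
    on the same level escalate the second to a failure.  A run's verdict is
    the worst verdict across the two levels.
    """
    rank = {"in-control": 0, "warn": 1, "fail": 2}
    verdicts: dict[str, str] = {}
    history: dict[str, list[float]] = {"high": [], "low": []}
    last_warn_side: dict[str, int] = {"high": 0, "low": 0}
    for i, (run_id, values) in enumerate(series.runs.items()):
        if values.get("high") is None or values.get("low") is None:
            verdicts[run_id] = "fail"
            last_warn_side = {"high": 0, "low": 0}
            continue
        verdict = "in-control"
        for level in ("high", "low"):
            x = float(values[level])  # type: ignore[arg-type]
            prior = history[level]
            level_verdict = "in-control"
            side = 0
            if i >= baseline_n and len(prior) >= 2:
                mean = sum(prior) / len(prior)
                sd = math.sqrt(
                    sum((v - mean) ** 2 for v in prior) / (len(prior) - 1)
                )
                if sd == 0:
                    if x != mean:
                        level_verdict = "fail"
                else:
                    z = (x - mean) / sd
                    if abs(z) > 2:
                        side = int(math.copysign(1, z))
                    if abs(z) > 3:
                        level_verdict = "fail"
                    elif abs(z) > 2:
                        level_verdict = "warn"
                        if side == last_warn_side[level]:
                            level_verdict = "fail"
            last_warn_side[level] = side if level_verdict == "warn" else 0
            if rank[level_verdict] > rank[verdict]:
                verdict = level_verdict
            # failing measurements do not update the control limits; warns do
            # (excluding warns would truncate the spread and bias SD low)
            if level_verdict != "fail":
                history[level].append(x)
        verdicts[run_id] = verdict
    return verdicts


@dataclass
class ValidationReport:
    """Bundle of the three validation experiments."""

    lob_vaf: float
    blank_vafs: list[float]
    lod: LodResult | None
    control_verdicts: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lob_vaf": self.lob_vaf,
            "blank_vafs": self.blank_vafs,
            "lod_fraction": self.lod.lod_fraction if self.lod else None,
            "lod_reached": self.lod.reached if self.lod else None,
            "lod_table": self.lod.table.to_dict(orient="records")
            if self.lod
            else [],
            "control_verdicts": self.control_verdicts,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path: str | Path) -> None:
        table = self.lod.table if self.lod else pd.DataFrame()
        table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Simulation drivers: regenerate the validation experiments end to end.
# ---------------------------------------------------------------------------

def precision_control_config(
    level: str,
    seed: int,
    depth: int = 50_000,
    mutation: InsertionSpec | None = None,
    ref: AmpliconReference | None = None,
) -> SimConfig:
    """Simulation config of a run precision control.

    The controls emulate mutant cell-line DNA (which carries the type A
    insertion) diluted into normal DNA at 0.2% ("high") or 0.02% ("low") VAF,
    sequenced to ``depth`` fragments.  Error processes are off: the controls
    measure counting (binomial sampling) precision of the assay, which is the
    dominant noise source at these depths.
    """
    if level not in PRECISION_CONTROL_VAF:
        raise ValueError("level must be 'high' or 'low'")
    if mutation is None:
        if ref is None:
            ref = load_default_reference()
        catalog = load_default_catalog(ref)
        mutation = catalog.spec_for("type A")
    return SimConfig(
        sample_id=f"precision-{level}",
        seed=seed,
        n_fragments=depth,
        mutant_fraction=PRECISION_CONTROL_VAF[level],
        mutation=mutation,
        sub_error_rate=0.0,
        indel_error_rate=0.0,
    )


def measure_sample_vaf(
    cfg: SimConfig,
    ref: AmpliconReference,
    catalog: MutationCatalog,
    target: InsertionSpec | None = None,
    min_mutant_reads: int = 2,
    aligner: AmpliconAligner | None = None,
) -> tuple[SampleCallResult, float, bool]:
    """Simulate one sample, merge, call; return (result, VAF, detected).

    ``detected`` means a pass call of ``target`` (default: the sample's own
    spiked mutation, left-normalized).
    """
    if target is None and cfg.mutation is not None:
        target = left_normalize(cfg.mutation, ref)
    r1, r2, _ = simulate_sample(cfg, ref)
    merged = merge_pairs(zip(r1, r2))
    result = call_sample(
        merged, ref, catalog, sample_id=cfg.sample_id,
        min_mutant_reads=min_mutant_reads, aligner=aligner,
    )
    if target is None:
        return result, 0.0, False
    return result, result.vaf_of(target), result.has_pass_call(target)


def _background_vaf(result: SampleCallResult) -> float:
    """Background signal of a blank: the largest single-insertion VAF seen."""
    return max((c.vaf for c in result.calls), default=0.0)


def run_blank_experiment(
    seed: int,
    ref: AmpliconReference,
    catalog: MutationCatalog,
    n_blanks: int = 30,
    depth: int = 50_000,
    sub_error_rate: float = 1e-3,
    indel_error_rate: float = 1e-6,
    alpha: float = 0.05,
) -> tuple[float, list[float]]:
    """Simulate a blank cohort of normal DNA and return (LOB, per-blank VAFs)."""
    template = SimConfig(
        sample_id="lob",
        seed=seed,
        n_fragments=depth,
        mutant_fraction=0.0,
        sub_error_rate=sub_error_rate,
        indel_error_rate=indel_error_rate,
    )
    aligner = AmpliconAligner(ref)
    vafs = []
    for r1, r2, _ in simulate_blank_cohort(template, ref, n_samples=n_blanks):
        merged = merge_pairs(zip(r1, r2))
        result = call_sample(merged, ref, catalog, aligner=aligner)
        vafs.append(_background_vaf(result))
    return limit_of_blank(vafs, alpha=alpha), vafs


def run_sensitivity_experiment(
    seed: int,
    ref: AmpliconReference,
    catalog: MutationCatalog,
    mutation: InsertionSpec | None = None,
    fractions: Sequence[float] = (1e-2, 1e-3, 1e-4, 1e-5),
    depth: int = 500_000,
    sub_error_rate: float = 1e-3,
    indel_error_rate: float = 0.0,
    min_mutant_reads: int = 2,
) -> tuple[float | None, pd.DataFrame]:
    """End-to-end analytical-sensitivity experiment.

    One single-sample run per dilution level, each taken through the full
    pipeline — demultiplex by dual index, merge pairs, call insertions — and
    the smallest mutant fraction whose spiked insertion receives a pass call
    is returned along with the per-level table.  Levels are processed one at a
    time so memory stays flat regardless of series depth.
    """
    from .demux import demultiplex
    from .readsim import default_index_pairs, simulate_run

    if mutation is None:
        mutation = catalog.spec_for("type A")
    target = left_normalize(mutation, ref)
    index_pair = default_index_pairs(1)[0]
    aligner = AmpliconAligner(ref)
    rows = []
    detected_fractions: list[float] = []
    for i, fraction in enumerate(fractions):
        cfg = SimConfig(
            sample_id=f"dil-{fraction:g}",
            seed=derive_seed(seed, 0xA1, i),
            n_fragments=depth,
            mutant_fraction=fraction,
            mutation=mutation if fraction > 0 else None,
            sub_error_rate=sub_error_rate,
            indel_error_rate=indel_error_rate,
            index_pair=index_pair,
        )
        r1, r2, sheet, truth = simulate_run([cfg], ref)
        demuxed = demultiplex(r1, r2, sheet)
        del r1, r2
        s1, s2 = demuxed.by_sample[cfg.sample_id]
        merged = merge_pairs(zip(s1, s2))
        result = call_sample(
            merged, ref, catalog, sample_id=cfg.sample_id,
            min_mutant_reads=min_mutant_reads, aligner=aligner,
        )
        detected = result.has_pass_call(target)
        if detected:
            detected_fractions.append(fraction)
        rows.append(
            {
                "fraction": fraction,
                "true_mutants": truth.samples[cfg.sample_id].n_mutant,
                "vaf": result.vaf_of(target),
                "detected": detected,
            }
        )
    lowest = min(detected_fractions) if detected_fractions else None
    return lowest, pd.DataFrame(rows)


def run_dilution_experiment(
    fractions: Sequence[float],
    depth: int,
    seed: int,
    ref: AmpliconReference,
    catalog: MutationCatalog,
    mutation: InsertionSpec | None = None,
    replicates: int = 3,
    lob_vaf: float = 0.0,
    required_hit_rate: float = 0.95,
    sub_error_rate: float = 1e-3,
    indel_error_rate: float = 0.0,
) -> tuple[LodResult, list[DilutionObservation]]:
    """Simulate a dilution series with replicates and derive the LOD."""
    if mutation is None:
        mutation = catalog.spec_for("type A")
    target = left_normalize(mutation, ref)
    aligner = AmpliconAligner(ref)
    observations: list[DilutionObservation] = []
    for rep in range(replicates):
        for i, fraction in enumerate(fractions):
            cfg = SimConfig(
                sample_id=f"dil-{fraction:g}-rep{rep}",
                seed=derive_seed(seed, 0xD2, rep, i),
                n_fragments=depth,
                mutant_fraction=fraction,
                mutation=mutation if fraction > 0 else None,
                sub_error_rate=sub_error_rate,
                indel_error_rate=indel_error_rate,
            )
            _, vaf, detected = measure_sample_vaf(
                cfg, ref, catalog, target=target, aligner=aligner
            )
            observations.append(DilutionObservation(fraction, detected, vaf))
    lod = limit_of_detection(
        observations, lob_vaf=lob_vaf, required_hit_rate=required_hit_rate
    )
    return lod, observations
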