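"""Patient-level MRD classification by VAF log-reduction.

A patient is measured at two time points — post-induction (PI) and
post-consolidation (PC) — and the change in mutant burden is summarized as

    log_reduction = log10(VAF_PI / VAF_PC).

Failure to clear a full log of disease between the time points
(log_reduction < 1) defines MRD positivity in this assay.  Zero VAFs get
explicit sentinel semantics: PC = 0 with PI > 0 is maximal clearance
(+infinity, negative); PI = 0 with PC > 0 is -infinity (positive); both zero
is recorded as NaN and classified negative, the rule the assay states for
double-negative patients.

For re-deriving the cutoff on a new cohort with outcome labels,
:func:`youden_cutoff` scans ROC thresholds (midpoints between consecutive
distinct finite log-reductions, plus the infinite sentinels) and maximizes
Youden's J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "PatientTimepoints",
    "MRDResult",
    "CutoffPoint",
    "log_reduction",
    "classify",
    "classify_cohort",
    "youden_cutoff",
    "read_patient_tsv",
    "write_mrd_tsv",
]


@dataclass(frozen=True)
class PatientTimepoints:
    """PI/PC VAF pair for one patient, optionally with a binary outcome label
    (1 = event, e.g. death or relapse; used only to train a cutoff)."""

    patient_id: str
    vaf_pi: float
    vaf_pc: float
    outcome: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_pi <= 1.0 or not 0.0 <= self.vaf_pc <= 1.0:
            raise ValueError("VAFs must lie in [0, 1]")
        if self.outcome not in (None, 0, 1):
            raise ValueError("outcome must be None, 0 or 1")


@dataclass(frozen=True)
class MRDResult:
    patient_id: str
    log_reduction: float  # may be +/-inf or NaN (both time points zero)
    classification: str   # "positive" | "negative"


@dataclass(frozen=True)
class CutoffPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def log_reduction(vaf_pi: float, vaf_pc: float) -> float:
    """log10(VAF_PI / VAF_PC) with sentinel handling for zero VAFs.

    Returns +inf when the mutation cleared (PC = 0 < PI), -inf when it
    appeared (PI = 0 < PC), and NaN when both time points are zero.
    Scale-invariant: multiplying both VAFs by the same factor changes nothing.
    """
    if vaf_pi < 0 or vaf_pc < 0:
        raise ValueError("VAFs must be non-negative")
    if vaf_pi == 0 and vaf_pc == 0:
        return math.nan
    if vaf_pc == 0:
        return math.inf
    if vaf_pi == 0:
        return -math.inf
    return math.log10(vaf_pi / vaf_pc)


def classify(patient: PatientTimepoints, cutoff: float = 1.0) -> MRDResult:
    """MRD-positive iff log_reduction < cutoff; the NaN (both-zero) and +inf
    (full clearance) sentinels are negative."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lr = log_reduction(patient.vaf_pi, patient.vaf_pc)
    positive = (not math.isnan(lr)) and lr < cutoff
    return MRDResult(
        patient_id=patient.patient_id,
        log_reduction=lr,
        classification="positive" if positive else "negative",
    )


def classify_cohort(
    patients: list[PatientTimepoints], cutoff: float = 1.0
) -> list[MRDResult]:
    return [classify(p, cutoff) for p in patients]


def _roc_values(patients: list[PatientTimepoints]) -> tuple[list[float], list[int]]:
    values, outcomes = [], []
    for p in patients:
        if p.outcome is None:
            raise ValueError(f"patient {p.patient_id!r} lacks an outcome label")
        lr = log_reduction(p.vaf_pi, p.vaf_pc)
        # both-zero patients are always classified negative; in ROC space that
        # is indistinguishable from full clearance
        values.append(math.inf if math.isnan(lr) else lr)
        outcomes.append(int(p.outcome))
    return values, outcomes


def youden_cutoff(
    patients: list[PatientTimepoints],
) -> tuple[CutoffPoint, pd.DataFrame]:
    """Optimal log-reduction cutoff by Youden's J, with the full ROC table.

    "Test positive" means log_reduction < threshold, predicting the event.
    Candidate thresholds are the midpoints between consecutive distinct finite
    log-reductions, flanked by -inf and +inf sentinels; ties on J break toward
    higher sensitivity, then lower threshold.
    """
    values, outcomes = _roc_values(patients)
    n_event = sum(outcomes)
    n_none = len(outcomes) - n_event
    if n_event == 0 or n_none == 0:
        raise ValueError("youden_cutoff needs at least one event and one non-event")

    finite = sorted({v for v in values if math.isfinite(v)})
    candidates = [-math.inf]
    if finite:
        # a finite threshold below every finite value still separates the
        # -inf sentinel (new mutation at PC) from the finite cohort
        candidates.append(finite[0] - 1.0)
    candidates += [(a + b) / 2 for a, b in zip(finite, finite[1:])]
    candidates.append(math.inf)

    rows = []
    best: CutoffPoint | None = None
    for t in candidates:
        tp = sum(1 for v, y in zip(values, outcomes) if y == 1 and v < t)
        fp = sum(1 for v, y in zip(values, outcomes) if y == 0 and v < t)
        point = CutoffPoint(
            threshold=t, sensitivity=tp / n_event, specificity=1 - fp / n_none
        )
        rows.append(
            {
                "threshold": t,
                "sensitivity": point.sensitivity,
                "specificity": point.specificity,
                "youden_j": point.youden_j,
            }
        )
        if (
            best is None
            or point.youden_j > best.youden_j
            or (
                point.youden_j == best.youden_j
                and (
                    point.sensitivity > best.sensitivity
                    or (
                        point.sensitivity == best.sensitivity
                        and point.threshold < best.threshold
                    )
                )
            )
        ):
            best = point
    assert best is not None
    return best, pd.DataFrame(rows)


def read_patient_tsv(path: str | Path) -> list[PatientTimepoints]:
    """Read a patient table (patient_id, vaf_pi, vaf_pc[, outcome])."""
    df = pd.read_csv(path, sep="\t")
    patients = []
    for _, row in df.iterrows():
        outcome = None
        if "outcome" in df.columns and not pd.isna(row["outcome"]):
            outcome = int(row["outcome"])
        patients.append(
            PatientTimepoints(
                patient_id=str(row["patient_id"]),
                vaf_pi=float(row["vaf_pi"]),
                vaf_pc=float(row["vaf_pc"]),
                outcome=outcome,
            )
        )
    return patients


def write_mrd_tsv(results: list[MRDResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "log_reduction": [r.log_reduction for r in results],
            "classification": [r.classification for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
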