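"""Patient-level N-stage assignment, adjudication and decision impact.

The N-stage rule engine follows the 8th-edition TNM criteria for
nasopharyngeal carcinoma nodal disease: any node over 6 cm short axis or
any positive node below the caudal border of the cricoid cartilage is N3;
otherwise bilateral cervical involvement is N2; otherwise unilateral
cervical and/or retropharyngeal involvement is N1; no positive nodes is N0.
The size and landmark thresholds are module constants so an alternative
edition can be swapped in.

Adjudication compares each modality's patient-level N category with the
biopsy-established truth and tallies the paired 2x2 correctness table that
feeds McNemar's test. Eligibility for upper-neck-only (lower-neck-sparing)
elective irradiation is restricted to N0–N1 disease.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .diagnostics import PairedTestResult, mcnemar_paired
from .types import (
    DecisionRecord,
    DoseCategory,
    Field,
    Laterality,
    NStage,
    Pathology,
    PatientStagingRecord,
    PositiveNode,
    RETROPHARYNGEAL_LEVELS,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: short-axis threshold (mm) above which a node is N3 by size
N3_SIZE_MM = 60.0

DOSE_ORDER = [DoseCategory.LOW, DoseCategory.INTERMEDIATE, DoseCategory.RADICAL]
FIELD_ORDER = [Field.UPPER_NECK_ONLY, Field.WHOLE_NECK]


def assign_n_stage(positive_nodes: Sequence[PositiveNode]) -> NStage:
    """TNM N category from the descriptors of imaging-positive nodes.

    An empty list stages as N0. A positive cervical (non-retropharyngeal)
    node with unknown laterality makes the N1/N2 distinction unguessable
    and raises :class:`ValidationError`.
    """
    if not positive_nodes:
        return NStage.N0
    for node in positive_nodes:
        if node.short_axis_mm is not None and node.short_axis_mm > N3_SIZE_MM:
            return NStage.N3
        if node.below_caudal_cricoid:
            return NStage.N3
    sides = set()
    for node in positive_nodes:
        if node.level in RETROPHARYNGEAL_LEVELS:
            continue  # retropharyngeal involvement alone stays N1 regardless of side
        if node.laterality is Laterality.UNKNOWN:
            raise ValidationError(
                f"positive cervical node at level {node.level.value} has unknown "
                "laterality; N1 vs N2 cannot be determined"
            )
        sides.add(node.laterality)
    if len(sides) > 1:
        return NStage.N2
    return NStage.N1


def eligibility_upper_neck(n_stage: NStage) -> Field:
    """Upper-neck-only irradiation is recommended for N0–N1, whole-neck otherwise."""
    if n_stage in (NStage.N0, NStage.N1):
        return Field.UPPER_NECK_ONLY
    return Field.WHOLE_NECK


@dataclass(frozen=True)
class PairedCorrectnessTable:
    """Counts of (modality A correct?, modality B correct?) across patients."""

    both_correct: int
    a_only_correct: int
    b_only_correct: int
    both_incorrect: int
    excluded_missing_truth: int = 0

    @property
    def total(self) -> int:
        return (
            self.both_correct + self.a_only_correct
            + self.b_only_correct + self.both_incorrect
        )

    def mcnemar(self, correction: bool = True) -> PairedTestResult:
        return mcnemar_paired(self.a_only_correct, self.b_only_correct, correction)


def adjudicate_staging(
    records: Sequence[PatientStagingRecord],
    *,
    modality_a: str = "pet",
    modality_b: str = "mri",
    exact: bool = True,
) -> PairedCorrectnessTable:
    """Tally which modality assigned the adjudicated-correct N stage.

    ``exact=True`` scores a modality correct iff its N category equals the
    truth; ``exact=False`` scores on the binned N0–1 vs N2–3 comparison
    that governs upper-neck-only eligibility. Records without adjudicated
    truth are excluded (count reported on the result).
    """
    cells = Counter()
    excluded = 0
    for rec in records:
        if rec.true_n is None:
            excluded += 1
            continue
        staged = {"pet": rec.pet_n, "mri": rec.mri_n}
        if exact:
            ok = {m: staged[m] == rec.true_n for m in staged}
        else:
            truth_f = eligibility_upper_neck(rec.true_n)
            ok = {m: eligibility_upper_neck(staged[m]) == truth_f for m in staged}
        cells[(ok[modality_a], ok[modality_b])] += 1
    if excluded:
        logger.info("adjudicate_staging: excluded %d records missing true_n", excluded)
    return PairedCorrectnessTable(
        both_correct=cells[(True, True)],
        a_only_correct=cells[(True, False)],
        b_only_correct=cells[(False, True)],
        both_incorrect=cells[(False, False)],
        excluded_missing_truth=excluded,
    )


def eligibility_correctness(
    records: Sequence[PatientStagingRecord],
) -> dict[str, tuple[int, int]]:
    """Per modality: (count with eligibility matching truth, denominator)."""
    table = adjudicate_staging(records, exact=False)
    n = table.total
    return {
        "pet": (table.both_correct + table.a_only_correct, n),
        "mri": (table.both_correct + table.b_only_correct, n),
    }


@dataclass(frozen=True)
class RateWithCounts:
    count: int
    denominator: int

    @property
    def rate(self) -> float:
        return self.count / self.denominator if self.denominator else float("nan")


@dataclass(frozen=True)
class OncologistImpact:
    """Decision-change summary for one oncologist."""

    oncologist_id: int
    #: dose transition matrix per pathology class, rows=before, cols=after
    dose_transitions: Mapping[Pathology, pd.DataFrame]
    #: field transition matrix (patient level), rows=before, cols=after
    field_transitions: pd.DataFrame
    escalation: Mapping[Pathology, RateWithCounts]
    de_escalation: Mapping[Pathology, RateWithCounts]
    expansion: RateWithCounts  # upper-neck-only -> whole-neck, patient denominator


@dataclass(frozen=True)
class DecisionImpactSummary:
    per_oncologist: Mapping[int, OncologistImpact]


def _dose_matrix(records: Sequence[DecisionRecord]) -> pd.DataFrame:
    labels = [d.value for d in DOSE_ORDER]
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for r in records:
        mat.loc[r.dose_before.value, r.dose_after.value] += 1
    return mat


def decision_impact(records: Sequence[DecisionRecord]) -> DecisionImpactSummary:
    """Tabulate before/after PET/CT-review decision changes per oncologist.

    Dose escalation and de-escalation rates use the pathology-class node
    denominator; field-expansion rates use the distinct-patient
    denominator. Duplicate (patient, oncologist, node) keys or
    within-patient field inconsistencies are rejected.
    """
    seen = set()
    for r in records:
        key = (r.patient_id, r.oncologist_id, r.node_id)
        if key in seen:
            raise ValidationError(f"duplicate decision record for {key}")
        seen.add(key)

    summaries: dict[int, OncologistImpact] = {}
    for onc in sorted({r.oncologist_id for r in records}):
        recs = [r for r in records if r.oncologist_id == onc]
        dose_mats, esc, deesc = {}, {}, {}
        for path in Pathology:
            class_recs = [r for r in recs if r.node_pathology is path]
            dose_mats[path] = _dose_matrix(class_recs)
            n = len(class_recs)
            esc[path] = RateWithCounts(
                sum(r.dose_after.ordinal > r.dose_before.ordinal for r in class_recs), n
            )
            deesc[path] = RateWithCounts(
                sum(r.dose_after.ordinal < r.dose_before.ordinal for r in class_recs), n
            )
        # field decisions are patient-level: collapse nodes, demand consistency
        per_patient: dict[str, tuple[Field, Field]] = {}
        for r in recs:
            fields = (r.field_before, r.field_after)
            if per_patient.setdefault(r.patient_id, fields) != fields:
                raise ValidationError(
                    f"inconsistent field decisions within patient {r.patient_id!r} "
                    f"for oncologist {onc}"
                )
        flabels = [f.value for f in FIELD_ORDER]
        fmat = pd.DataFrame(0, index=flabels, columns=flabels)
        for before, after in per_patient.values():
            fmat.loc[before.value, after.value] += 1
        expansion = RateWithCounts(
            int(fmat.loc[Field.UPPER_NECK_ONLY.value, Field.WHOLE_NECK.value]),
            len(per_patient),
        )
        summaries[onc] = OncologistImpact(
            oncologist_id=onc,
            dose_transitions=dose_mats,
            field_transitions=fmat,
            escalation=esc,
            de_escalation=deesc,
            expansion=expansion,
        )
    return DecisionImpactSummary(per_oncologist=summaries)


def impact_long_table(summary: DecisionImpactSummary) -> pd.DataFrame:
    """Long-format transition table (one row per before/after cell) for plotting."""
    rows = []
    for onc, imp in summary.per_oncologist.items():
        for path, mat in imp.dose_transitions.items():
            for before in mat.index:
                for after in mat.columns:
                    rows.append(
                        dict(oncologist=onc, decision="dose", group=path.value,
                             before=before, after=after, count=int(mat.loc[before, after]))
                    )
        fmat = imp.field_transitions
        for before in fmat.index:
            for after in fmat.columns:
                rows.append(
                    dict(oncologist=onc, decision="field", group="all",
                         before=before, after=after, count=int(fmat.loc[before, after]))
                )
    return pd.DataFrame(rows, columns=["oncologist", "decision", "group", "before", "after", "count"])
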