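"""Domain types shared across the pipeline.

The analysis operates on three record kinds mirroring the three nested
cohorts of a nodal-staging study in nasopharyngeal carcinoma (NPC):

* :class:`NodeRecord` — one biopsy-verified cervical lymph node with its
  histopathology label and two ordinal imaging confidence scores (MRI and
  FDG PET/CT, each on a 0–4 scale).
* :class:`PatientStagingRecord` — one patient with the N category (TNM
  N0–N3) assigned by each modality and the biopsy-adjudicated truth.
* :class:`DecisionRecord` — one (patient, oncologist[, node]) radiotherapy
  decision pair: dose category and neck-field extent before and after
  PET/CT review.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Level(str, enum.Enum):
    """Anatomic neck nodal level (localisation compartment, not N-stage)."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    Va = "Va"
    Vb = "Vb"
    VII = "VII"
    VIII = "VIII"


#: Retropharyngeal compartment: involvement there alone never exceeds N1.
RETROPHARYNGEAL_LEVELS = frozenset({Level.VII})


class Pathology(str, enum.Enum):
    METASTATIC = "metastatic"
    BENIGN = "benign"


class Laterality(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class NStage(str, enum.Enum):
    N0 = "N0"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"

    @property
    def ordinal(self) -> int:
        return int(self.value[1])


class TStage(str, enum.Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"


class DoseCategory(str, enum.Enum):
    """Prescribed dose band: low (<60 Gy), intermediate (60–66 Gy), radical (>=66 Gy)."""

    LOW = "low"
    INTERMEDIATE = "intermediate"
    RADICAL = "radical"

    @property
    def ordinal(self) -> int:
        return {"low": 0, "intermediate": 1, "radical": 2}[self.value]


class Field(str, enum.Enum):
    """Elective neck irradiation extent."""

    UPPER_NECK_ONLY = "upper_neck_only"
    WHOLE_NECK = "whole_neck"


SCORE_MIN, SCORE_MAX = 0, 4


class ValidationError(ValueError):
    """A record violated a domain invariant; message names the offending row."""


@dataclass(frozen=True)
class NodeRecord:
    """One biopsied lymph node with pathology truth and paired modality scores."""

    node_id: str
    patient_id: str
    level: Level
    pathology: Pathology
    mri_score: int
    pet_score: int
    laterality: Laterality = Laterality.UNKNOWN
    short_axis_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("mri_score", "pet_score"):
            s = getattr(self, name)
            if not isinstance(s, int) or not SCORE_MIN <= s <= SCORE_MAX:
                raise ValidationError(
                    f"node {self.node_id!r}: {name}={s!r} outside {SCORE_MIN}-{SCORE_MAX}"
                )
        if self.short_axis_mm is not None and self.short_axis_mm < 0:
            raise ValidationError(
                f"node {self.node_id!r}: short_axis_mm={self.short_axis_mm} negative"
            )

    def score(self, modality: str) -> int:
        """Ordinal confidence score for ``modality`` ('mri' or 'pet')."""
        try:
            return {"mri": self.mri_score, "pet": self.pet_score}[modality]
        except KeyError:
            raise KeyError(f"unknown modality {modality!r}; expected 'mri' or 'pet'") from None


@dataclass(frozen=True)
class PatientStagingRecord:
    """Per-patient N categories assigned by each modality plus adjudicated truth."""

    patient_id: str
    mri_n: NStage
    pet_n: NStage
    true_n: Optional[NStage]
    t_stage: Optional[TStage] = None


@dataclass(frozen=True)
class DecisionRecord:
    """One radiotherapy decision pair (before vs after PET/CT review).

    Dose decisions are per target node (node_id set); the neck-field
    decision is a patient-level choice and must agree across a patient's
    records for the same oncologist.
    """

    patient_id: str
    oncologist_id: int
    node_pathology: Pathology
    dose_before: DoseCategory
    dose_after: DoseCategory
    field_before: Field
    field_after: Field
    node_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.oncologist_id not in (1, 2, 3):
            raise ValidationError(
                f"patient {self.patient_id!r}: oncologist_id must be 1-3, "
                f"got {self.oncologist_id}"
            )


@dataclass(frozen=True)
class PositiveNode:
    """Descriptor of one imaging-positive node feeding the N-stage rule engine."""

    level: Level
    laterality: Laterality
    short_axis_mm: Optional[float] = None
    below_caudal_cricoid: bool = False
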