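"""Synthetic cohorts with the statistical structure the analysis assumes.

Three deterministic fixture generators reproduce, exactly, the summary
structure of the study's three cohorts — (A) node-level paired confusion
counts, (B) the patient-level paired-correctness table with eligibility
targets, (C) per-oncologist before/after decision transitions — so every
downstream operation can be exercised and checked against printed summary
statistics without any data download. A fourth, stochastic generator draws
paired ordinal scores from a Gaussian-copula latent-suspicion model with
controllable between-modality agreement, for calibration and power-style
checks.

All generators are seeded and fully reproducible. Fixture generators are
exact by construction: recomputing any summary used to define a fixture
returns the defining counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .types import (
    DecisionRecord,
    DoseCategory,
    Field,
    Laterality,
    Level,
    NodeRecord,
    NStage,
    Pathology,
    PatientStagingRecord,
)

# Level composition of the diagnostic cohort (counts per pathology class)
LEVEL_COUNTS_METASTATIC: dict[Level, int] = {
    Level.I: 13, Level.II: 474, Level.III: 22, Level.IV: 4,
    Level.Va: 17, Level.Vb: 4, Level.VII: 2, Level.VIII: 19,
}
LEVEL_COUNTS_BENIGN: dict[Level, int] = {
    Level.I: 11, Level.II: 92, Level.III: 7, Level.IV: 4,
    Level.Va: 1, Level.Vb: 0, Level.VII: 0, Level.VIII: 24,
}

#: score mix within positive calls (share of 2s, 3s, 4s)
POSITIVE_SCORE_MIX = {2: 0.2, 3: 0.3, 4: 0.5}
NEGATIVE_SCORE_MIX = {0: 0.5, 1: 0.5}


class InfeasibleSpecError(ValueError):
    """Requested joint allocation contradicts its own marginals."""


def largest_remainder(proportions: Mapping, total: int) -> dict:
    """Apportion ``total`` into integer counts matching ``proportions``
    (Hamilton / largest-remainder method). Keys keep their input order."""
    if total < 0:
        raise ValueError("total must be nonnegative")
    keys = list(proportions)
    probs = np.array([proportions[k] for k in keys], dtype=float)
    if probs.min() < 0:
        raise ValueError("proportions must be nonnegative")
    if total > 0 and probs.sum() == 0:
        raise ValueError("cannot apportion over all-zero proportions")
    if probs.sum() > 0:
        probs = probs / probs.sum()
    quotas = probs * total
    counts = np.floor(quotas).astype(int)
    shortfall = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for idx in order[:shortfall]:
        counts[idx] += 1
    return dict(zip(keys, (int(c) for c in counts)))


def _score_list(n: int, mix: Mapping[int, float], rng: np.random.Generator) -> list[int]:
    counts = largest_remainder(mix, n)
    scores = [s for s, c in counts.items() for _ in range(c)]
    return [scores[i] for i in rng.permutation(n)]


@dataclass(frozen=True)
class MarginalCounts:
    """One modality's confusion counts at the primary cutoff."""

    tp: int
    fn: int
    fp: int
    tn: int


@dataclass(frozen=True)
class FixtureCohortSpec:
    """Exact targets for the deterministic diagnostic-cohort fixture.

    ``joint_pos_both`` / ``joint_neg_both`` fix the number of metastatic
    (benign) nodes called positive by BOTH modalities; defaults take the
    maximal overlap compatible with the marginals. The paired discordant
    cells are otherwise unrecoverable from published marginals, so they are
    free spec parameters here.
    """

    pet: MarginalCounts
    mri: MarginalCounts
    joint_pos_both: Optional[int] = None
    joint_neg_both: Optional[int] = None
    level_counts_pos: Mapping[Level, int] = field(
        default_factory=lambda: dict(LEVEL_COUNTS_METASTATIC))
    level_counts_neg: Mapping[Level, int] = field(
        default_factory=lambda: dict(LEVEL_COUNTS_BENIGN))
    seed: int = 0


def cohort_a_spec(seed: int = 0) -> FixtureCohortSpec:
    """Defaults reconstructing the published diagnostic cohort: 555
    metastatic / 139 benign nodes with PET/CT calling (533, 22, 50, 89)
    and MRI (514, 41, 57, 82) at the >=2 cutoff."""
    return FixtureCohortSpec(
        pet=MarginalCounts(533, 22, 50, 89),
        mri=MarginalCounts(514, 41, 57, 82),
        seed=seed,
    )


def _joint_split(n: int, a_pos: int, b_pos: int, both: Optional[int], what: str) -> tuple[int, int, int, int]:
    lo, hi = max(0, a_pos + b_pos - n), min(a_pos, b_pos)
    k = hi if both is None else both
    if not lo <= k <= hi:
        raise InfeasibleSpecError(
            f"{what}: both-positive count {k} incompatible with marginals "
            f"({a_pos}, {b_pos}) of {n}; feasible range [{lo}, {hi}]"
        )
    return k, a_pos - k, b_pos - k, n - a_pos - b_pos + k


def generate_fixture_cohort_a(spec: FixtureCohortSpec) -> list[NodeRecord]:
    """Deterministic diagnostic cohort reproducing the requested per-modality
    2x2 counts exactly at the primary cutoff (>= 2).

    Within each pathology class, nodes are partitioned into the four joint
    call cells; positive calls receive scores 2-4 in fixed proportions and
    negative calls scores 0-1, permuted by the seeded generator; nodal
    levels are apportioned by largest remainder to the class composition.
    """
    if (spec.pet.tp + spec.pet.fn) != (spec.mri.tp + spec.mri.fn):
        raise InfeasibleSpecError("modalities disagree on the metastatic total")
    if (spec.pet.fp + spec.pet.tn) != (spec.mri.fp + spec.mri.tn):
        raise InfeasibleSpecError("modalities disagree on the benign total")
    n_pos = spec.pet.tp + spec.pet.fn
    n_neg = spec.pet.fp + spec.pet.tn
    rng = np.random.default_rng(spec.seed)

    records: list[NodeRecord] = []
    sides = [Laterality.LEFT, Laterality.RIGHT]

    for pathology, n_class, pet_pos, mri_pos, both, level_counts in (
        (Pathology.METASTATIC, n_pos, spec.pet.tp, spec.mri.tp,
         spec.joint_pos_both, spec.level_counts_pos),
        (Pathology.BENIGN, n_neg, spec.pet.fp, spec.mri.fp,
         spec.joint_neg_both, spec.level_counts_neg),
    ):
        k_both, k_pet, k_mri, k_none = _joint_split(
            n_class, pet_pos, mri_pos, both, pathology.value)
        # joint call pattern per node: (pet_positive, mri_positive)
        patterns = (
            [(True, True)] * k_both + [(True, False)] * k_pet
            + [(False, True)] * k_mri + [(False, False)] * k_none
        )
        pet_pos_scores = _score_list(pet_pos, POSITIVE_SCORE_MIX, rng)
        pet_neg_scores = _score_list(n_class - pet_pos, NEGATIVE_SCORE_MIX, rng)
        mri_pos_scores = _score_list(mri_pos, POSITIVE_SCORE_MIX, rng)
        mri_neg_scores = _score_list(n_class - mri_pos, NEGATIVE_SCORE_MIX, rng)
        level_alloc = largest_remainder(level_counts, n_class)
        levels = [lv for lv, c in level_alloc.items() for _ in range(c)]
        levels = [levels[i] for i in rng.permutation(n_class)]
        tag = "m" if pathology is Pathology.METASTATIC else "b"
        for i, (pet_call, mri_call) in enumerate(patterns):
            records.append(NodeRecord(
                node_id=f"a-{tag}{i + 1:04d}",
                patient_id=f"pa-{tag}{i + 1:04d}",
                level=levels[i],
                pathology=pathology,
                mri_score=(mri_pos_scores if mri_call else mri_neg_scores).pop(),
                pet_score=(pet_pos_scores if pet_call else pet_neg_scores).pop(),
                laterality=sides[i % 2],
            ))
    return records


@dataclass(frozen=True)
class CohortSpec:
    """Stochastic paired-cohort parameters (Gaussian-copula latent model)."""

    n_pos: int = 555
    n_neg: int = 139
    sens_by_modality: Mapping[str, float] = field(
        default_factory=lambda: {"pet": 0.960, "mri": 0.926})
    spec_by_modality: Mapping[str, float] = field(
        default_factory=lambda: {"pet": 0.640, "mri": 0.590})
    agreement_rho: float = 0.5
    level_counts_pos: Mapping[Level, int] = field(
        default_factory=lambda: dict(LEVEL_COUNTS_METASTATIC))
    level_counts_neg: Mapping[Level, int] = field(
        default_factory=lambda: dict(LEVEL_COUNTS_BENIGN))
    #: cumulative cutpoints within the positive band splitting scores 4|3|2
    positive_band_cutpoints: tuple[float, float] = (0.5, 0.8)
    #: cutpoint within the negative band splitting scores 1|0
    negative_band_cutpoint: float = 0.5

    def __post_init__(self) -> None:
        for m, p in {**dict(self.sens_by_modality), **dict(self.spec_by_modality)}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {m!r} outside [0, 1]: {p}")
        if not -1.0 <= self.agreement_rho <= 1.0:
            raise ValueError(f"agreement_rho outside [-1, 1]: {self.agreement_rho}")
        c1, c2 = self.positive_band_cutpoints
        if not 0.0 < c1 < c2 < 1.0:
            raise ValueError("positive_band_cutpoints must be strictly increasing in (0,1)")


def _band_score(u: float, p_pos: float, spec: CohortSpec) -> int:
    """Map a latent suspicion quantile (small = suspicious) to a 0-4 score,
    consistent with the binary call (score >= 2 iff u < p_pos)."""
    c1, c2 = spec.positive_band_cutpoints
    if u < p_pos:
        rel = u / p_pos if p_pos > 0 else 0.0
        return 4 if rel < c1 else (3 if rel < c2 else 2)
    rel = (u - p_pos) / (1 - p_pos) if p_pos < 1 else 0.0
    return 1 if rel < spec.negative_band_cutpoint else 0


def sample_paired_cohort(spec: CohortSpec, n: int, seed: int) -> list[NodeRecord]:
    """Draw ``n`` nodes with paired MRI/PET ordinal scores.

    Pathology is Bernoulli with prevalence ``n_pos / (n_pos + n_neg)``. Per
    node a bivariate standard-normal latent pair with correlation
    ``agreement_rho`` is converted to quantiles; each modality calls
    positive when its quantile falls below its class-conditional
    positive-call probability (sensitivity for metastatic nodes, one minus
    specificity for benign), so marginal accuracies match the spec exactly
    in expectation while the copula controls agreement. Quantiles are then
    banded into 0-4 scores.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prevalence = spec.n_pos / (spec.n_pos + spec.n_neg)
    rho = spec.agreement_rho
    levels_pos = list(spec.level_counts_pos)
    p_levels_pos = np.array([spec.level_counts_pos[lv] for lv in levels_pos], dtype=float)
    p_levels_pos /= p_levels_pos.sum()
    levels_neg = list(spec.level_counts_neg)
    p_levels_neg = np.array([spec.level_counts_neg[lv] for lv in levels_neg], dtype=float)
    p_levels_neg /= p_levels_neg.sum()

    diseased = rng.random(n) < prevalence
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    z_pet = e1
    z_mri = rho * e1 + math_sqrt1m(rho) * e2
    u_pet = _stats.norm.cdf(z_pet)
    u_mri = _stats.norm.cdf(z_mri)
    sides = [Laterality.LEFT, Laterality.RIGHT]
    records = []
    for i in range(n):
        if diseased[i]:
            p_pet = spec.sens_by_modality["pet"]
            p_mri = spec.sens_by_modality["mri"]
            level = levels_pos[rng.choice(len(levels_pos), p=p_levels_pos)]
            pathology = Pathology.METASTATIC
        else:
            p_pet = 1 - spec.spec_by_modality["pet"]
            p_mri = 1 - spec.spec_by_modality["mri"]
            level = levels_neg[rng.choice(len(levels_neg), p=p_levels_neg)]
            pathology = Pathology.BENIGN
        records.append(NodeRecord(
            node_id=f"s-{i + 1:05d}",
            patient_id=f"ps-{i + 1:05d}",
            level=level,
            pathology=pathology,
            mri_score=_band_score(float(u_mri[i]), p_mri, spec),
            pet_score=_band_score(float(u_pet[i]), p_pet, spec),
            laterality=sides[i % 2],
        ))
    return records


def math_sqrt1m(rho: float) -> float:
    return float(np.sqrt(max(0.0, 1.0 - rho * rho)))


@dataclass(frozen=True)
class PairedCorrectnessSpec:
    """Target cells for the staging fixture: (PET correct?, MRI correct?)."""

    both_correct: int = 423
    a_only_correct: int = 40   # PET correct, MRI wrong
    b_only_correct: int = 21   # MRI correct, PET wrong
    both_incorrect: int = 19
    #: among exact-stage-wrong records, how many still land in the correct
    #: N0-1 vs N2-3 eligibility bin (drives eligibility-accuracy targets)
    pet_bin_correct_extra: int = 9
    mri_bin_correct_extra: int = 3

    def __post_init__(self) -> None:
        for name in ("both_correct", "a_only_correct", "b_only_correct",
                     "both_incorrect", "pet_bin_correct_extra", "mri_bin_correct_extra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.pet_bin_correct_extra > self.b_only_correct + self.both_incorrect:
            raise InfeasibleSpecError("pet_bin_correct_extra exceeds PET-wrong records")
        if self.mri_bin_correct_extra > self.a_only_correct + self.both_incorrect:
            raise InfeasibleSpecError("mri_bin_correct_extra exceeds MRI-wrong records")


def generate_staging_fixture_b(spec: PairedCorrectnessSpec) -> list[PatientStagingRecord]:
    """Patient-level staging fixture reproducing the paired-correctness
    cells exactly, with configurable counts of wrong-stage-but-correct-
    eligibility records per modality.

    True stages among concordantly-correct patients are split N0/N1/N2 in
    fixed shares (the published figure prints only the N0/N1 totals, so the
    upper categories are a free choice); all discordance is staged around
    the N1/N2 eligibility boundary, with N3 used for wrong-stage records
    whose eligibility bin must nevertheless match the truth.
    """
    records: list[PatientStagingRecord] = []

    def add(pet: NStage, mri: NStage, true: NStage, count: int) -> None:
        for _ in range(count):
            records.append(PatientStagingRecord(
                patient_id=f"b{len(records) + 1:04d}", mri_n=mri, pet_n=pet, true_n=true))

    # concordantly correct: truth split over N0/N1/N2 (shares are decorative)
    shares = largest_remainder({NStage.N0: 0.045, NStage.N1: 0.38, NStage.N2: 0.575},
                               spec.both_correct)
    for stage, count in shares.items():
        add(stage, stage, stage, count)

    # PET-only correct: MRI understages N2 disease
    x_mri = min(spec.mri_bin_correct_extra, spec.a_only_correct)
    add(NStage.N2, NStage.N3, NStage.N2, x_mri)          # MRI wrong but bin-correct
    add(NStage.N2, NStage.N1, NStage.N2, spec.a_only_correct - x_mri)

    # MRI-only correct: PET mis-stages N2 disease
    x_pet = min(spec.pet_bin_correct_extra, spec.b_only_correct)
    add(NStage.N3, NStage.N2, NStage.N2, x_pet)          # PET wrong but bin-correct
    add(NStage.N1, NStage.N2, NStage.N2, spec.b_only_correct - x_pet)

    # concordantly incorrect
    rem_pet = spec.pet_bin_correct_extra - x_pet
    rem_mri = spec.mri_bin_correct_extra - x_mri
    if rem_pet + rem_mri > spec.both_incorrect:
        raise InfeasibleSpecError(
            "bin-correct extras exceed capacity of concordantly-incorrect cell")
    add(NStage.N3, NStage.N1, NStage.N2, rem_pet)
    add(NStage.N1, NStage.N3, NStage.N2, rem_mri)
    add(NStage.N1, NStage.N1, NStage.N2,
        spec.both_incorrect - rem_pet - rem_mri)
    return records


# ---------------------------------------------------------------------------
# Cohort C fixture: per-oncologist decision transitions
# ---------------------------------------------------------------------------

DOSE_LABELS = [DoseCategory.LOW, DoseCategory.INTERMEDIATE, DoseCategory.RADICAL]
FIELD_LABELS = [Field.UPPER_NECK_ONLY, Field.WHOLE_NECK]


@dataclass(frozen=True)
class OncologistTransitions:
    """Before/after transition counts for one oncologist.

    ``dose`` maps pathology class to a 3x3 matrix (rows = dose before, in
    low/intermediate/radical order; cols = dose after); ``field`` is 2x2
    (upper-neck-only / whole-neck), counted over patients.
    """

    dose: Mapping[Pathology, Sequence[Sequence[int]]]
    field: Sequence[Sequence[int]]


def default_decision_transitions() -> dict[int, OncologistTransitions]:
    """Illustrative defaults reproducing the printed change rates: metastatic
    dose escalation up to 4/24, benign de-escalation 2/43 for every
    oncologist, benign escalation 3/0/5 of 43, and field expansion 4, 5 and
    7 of 62 patients (6.4%, 8.0%, 11.3%)."""
    return {
        1: OncologistTransitions(
            dose={
                Pathology.METASTATIC: [[1, 1, 1], [0, 4, 2], [0, 0, 15]],
                Pathology.BENIGN: [[0, 1, 0], [0, 1, 2], [0, 2, 37]],
            },
            field=[[5, 4], [0, 53]],
        ),
        2: OncologistTransitions(
            dose={
                Pathology.METASTATIC: [[2, 2, 0], [0, 6, 1], [0, 0, 13]],
                Pathology.BENIGN: [[20, 0, 0], [1, 10, 0], [0, 1, 11]],
            },
            field=[[25, 5], [0, 32]],
        ),
        3: OncologistTransitions(
            dose={
                Pathology.METASTATIC: [[1, 1, 0], [0, 3, 1], [0, 0, 18]],
                Pathology.BENIGN: [[12, 3, 0], [0, 12, 2], [1, 1, 12]],
            },
            field=[[45, 7], [0, 10]],
        ),
    }


def generate_decision_fixture_c(
    transition_specs: Mapping[int, OncologistTransitions] | None = None,
) -> list[DecisionRecord]:
    """Emit decision records reproducing the requested transition matrices
    exactly.

    Node pathology and the node-to-patient mapping are shared across
    oncologists (the same tumour board reviews the same patients); when
    there are more nodes than patients the surplus nodes are assigned as
    second nodes of the first patients. Field decisions are patient-level
    and identical across a patient's records.
    """
    specs = transition_specs if transition_specs is not None else default_decision_transitions()
    if not specs:
        raise ValueError("at least one oncologist required")

    def class_total(tr: OncologistTransitions, path: Pathology) -> int:
        return int(np.asarray(tr.dose[path]).sum())

    first = next(iter(specs.values()))
    n_by_class = {p: class_total(first, p) for p in Pathology}
    n_patients = int(np.asarray(first.field).sum())
    for onc, tr in specs.items():
        for p in Pathology:
            mat = np.asarray(tr.dose[p])
            if mat.shape != (3, 3) or (mat < 0).any():
                raise ValueError(f"oncologist {onc}: dose matrix for {p.value} invalid")
            if class_total(tr, p) != n_by_class[p]:
                raise ValueError(f"oncologist {onc}: class totals differ across oncologists")
        fmat = np.asarray(tr.field)
        if fmat.shape != (2, 2) or (fmat < 0).any():
            raise ValueError(f"oncologist {onc}: field matrix invalid")
        if int(fmat.sum()) != n_patients:
            raise ValueError(f"oncologist {onc}: patient totals differ across oncologists")

    n_nodes = sum(n_by_class.values())
    if n_patients > n_nodes:
        raise ValueError("more patients than nodes")
    # surplus nodes cycle back onto the first patients as second nodes
    node_patient = [f"c-p{(i % n_patients) + 1:03d}" for i in range(n_nodes)]
    node_pathology = ([Pathology.METASTATIC] * n_by_class[Pathology.METASTATIC]
                      + [Pathology.BENIGN] * n_by_class[Pathology.BENIGN])

    records: list[DecisionRecord] = []
    for onc in sorted(specs):
        tr = specs[onc]
        # per-class node dose assignments, expanded in fixed cell order
        dose_pairs: dict[Pathology, list[tuple[DoseCategory, DoseCategory]]] = {}
        for p in Pathology:
            pairs = []
            mat = np.asarray(tr.dose[p])
            for bi, before in enumerate(DOSE_LABELS):
                for ai, after in enumerate(DOSE_LABELS):
                    pairs.extend([(before, after)] * int(mat[bi, ai]))
            dose_pairs[p] = pairs
        field_pairs: list[tuple[Field, Field]] = []
        fmat = np.asarray(tr.field)
        for bi, before in enumerate(FIELD_LABELS):
            for ai, after in enumerate(FIELD_LABELS):
                field_pairs.extend([(before, after)] * int(fmat[bi, ai]))
        patient_field = {f"c-p{i + 1:03d}": field_pairs[i] for i in range(n_patients)}
        counters = {p: 0 for p in Pathology}
        for i in range(n_nodes):
            p = node_pathology[i]
            dose_before, dose_after = dose_pairs[p][counters[p]]
            counters[p] += 1
            fb, fa = patient_field[node_patient[i]]
            records.append(DecisionRecord(
                patient_id=node_patient[i],
                oncologist_id=onc,
                node_id=f"c-n{i + 1:03d}",
                node_pathology=p,
                dose_before=dose_before,
                dose_after=dose_after,
                field_before=fb,
                field_after=fa,
            ))
    return records
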