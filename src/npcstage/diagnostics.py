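"""Node-level paired diagnostic evaluation.

Two imaging modalities (MRI and FDG PET/CT) score the same biopsy-verified
lymph nodes on an ordinal 0–4 confidence scale; histopathology is the
reference standard. This module binarises the scores at a cutoff (>=2 by
default: moderate suspicion or higher counts as node-positive), derives
accuracy statistics with Wilson score confidence intervals, and runs the
three paired comparisons appropriate to a fully paired design:

* McNemar's test on discordant calls (sensitivity/specificity comparison
  and patient-level correctness comparison);
* a weighted generalized score (WGS) test for comparing the positive and
  negative predictive values of the two modalities on the same subjects;
* DeLong's test for correlated ROC areas built from the ordinal scores.

PPV and NPV depend on the prevalence of metastasis among tested nodes, so
values from an enriched biopsy cohort (80% metastatic here) understate
rule-out NPV in lower-prevalence populations; see
:func:`predictive_values_from_bayes` for the prevalence-adjusted view.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .types import NodeRecord, Pathology

SCORE_CUTOFF_DEFAULT = 2


class PairedMethod(str, enum.Enum):
    MCNEMAR_CC = "mcnemar_cc"
    MCNEMAR_PLAIN = "mcnemar_plain"
    WEIGHTED_GS_PPV = "weighted_gs_ppv"
    WEIGHTED_GS_NPV = "weighted_gs_npv"
    DELONG = "delong"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts of calls against pathology truth."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its two-sided 95% Wilson score interval."""

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy statistics; a metric with a zero denominator is None, never 0."""

    accuracy: Optional[MetricEstimate]
    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    method: PairedMethod
    #: signed estimate of the compared quantity's difference (a - b), where defined
    difference: Optional[float] = None


def confusion_at_cutoff(
    nodes: Sequence[NodeRecord], modality: str, cutoff: int = SCORE_CUTOFF_DEFAULT
) -> ConfusionCounts:
    """Binarise one modality's scores at ``cutoff`` (call positive iff score >= cutoff)."""
    if not 1 <= cutoff <= 4:
        raise ValueError(f"cutoff must be in 1..4, got {cutoff}")
    if len(nodes) == 0:
        raise ValueError("empty cohort")
    tp = fn = fp = tn = 0
    for node in nodes:
        positive = node.score(modality) >= cutoff
        if node.pathology is Pathology.METASTATIC:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def _metric(k: int, n: int, alpha: float = 0.05) -> Optional[MetricEstimate]:
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return MetricEstimate(k / n, float(lo), float(hi), k, n)


def diagnostic_metrics(conf: ConfusionCounts, ci_method: str = "wilson") -> DiagnosticMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV with Wilson 95% CIs."""
    if ci_method != "wilson":
        raise ValueError(f"unsupported ci_method {ci_method!r}")
    return DiagnosticMetrics(
        accuracy=_metric(conf.tp + conf.tn, conf.n),
        sensitivity=_metric(conf.tp, conf.n_diseased),
        specificity=_metric(conf.tn, conf.n_benign),
        ppv=_metric(conf.tp, conf.tp + conf.fp),
        npv=_metric(conf.tn, conf.tn + conf.fn),
    )


def predictive_values_from_bayes(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[Optional[float], Optional[float]]:
    """(PPV, NPV) implied by Bayes' rule at a given pre-test prevalence."""
    p_pos = prevalence * sensitivity + (1 - prevalence) * (1 - specificity)
    p_neg = 1 - p_pos
    ppv = prevalence * sensitivity / p_pos if p_pos > 0 else None
    npv = (1 - prevalence) * specificity / p_neg if p_neg > 0 else None
    return ppv, npv


def mcnemar_paired(
    n_a_only: int, n_b_only: int, correction: bool = True
) -> PairedTestResult:
    """McNemar's chi-square test on the two discordant-pair counts.

    With the continuity correction the statistic is
    ``(max(|b - c| - 1, 0))^2 / (b + c)``; the |b-c|-1 term is clamped at
    zero so equal discordant counts give p = 1 rather than a spurious
    positive statistic. With ``b + c = 0`` the test is vacuous (p = 1).
    """
    b, c = n_a_only, n_b_only
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    method = PairedMethod.MCNEMAR_CC if correction else PairedMethod.MCNEMAR_PLAIN
    if b + c == 0:
        return PairedTestResult(0.0, 1.0, method, difference=0.0)
    num = max(abs(b - c) - 1, 0) if correction else abs(b - c)
    statistic = num**2 / (b + c)
    p = float(stats.chi2.sf(statistic, df=1))
    return PairedTestResult(statistic, p, method, difference=float(b - c))


def _joint_calls(
    nodes: Sequence[NodeRecord], modality_a: str, modality_b: str, cutoff: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.array([n.pathology is Pathology.METASTATIC for n in nodes], dtype=float)
    xa = np.array([n.score(modality_a) >= cutoff for n in nodes], dtype=float)
    xb = np.array([n.score(modality_b) >= cutoff for n in nodes], dtype=float)
    return d, xa, xb


def compare_predictive_values(
    nodes: Sequence[NodeRecord],
    modality_a: str,
    modality_b: str,
    cutoff: int = SCORE_CUTOFF_DEFAULT,
    which: str = "ppv",
) -> PairedTestResult:
    """Weighted generalized score test comparing PPV (or NPV) of two paired tests.

    Construction: each subject contributes one observation per modality
    that called it positive (for PPV; negative for NPV), with the response
    being disease status (non-disease status for NPV). Under H0 the two
    predictive values share a common value estimated by pooling, and the
    score for the modality contrast — with the intercept profiled out using
    the marginal call-count weights — is assessed against its
    cluster-robust (subject-level) variance, giving a chi-square statistic
    on 1 df. Pairing is respected because a subject positive on both
    modalities contributes a single correlated cluster.
    """
    if which not in ("ppv", "npv"):
        raise ValueError(f"which must be 'ppv' or 'npv', got {which!r}")
    d, xa, xb = _joint_calls(nodes, modality_a, modality_b, cutoff)
    if which == "npv":
        # NPV comparison is the PPV construction on complemented calls/labels
        d, xa, xb = 1 - d, 1 - xa, 1 - xb
    method = PairedMethod.WEIGHTED_GS_PPV if which == "ppv" else PairedMethod.WEIGHTED_GS_NPV
    na, nb = xa.sum(), xb.sum()
    if na == 0 or nb == 0:
        raise ValueError(
            f"{which} comparison undefined: a modality made no "
            f"{'positive' if which == 'ppv' else 'negative'} calls"
        )
    pv_a = float((d * xa).sum() / na)
    pv_b = float((d * xb).sum() / nb)
    pooled = float((d * (xa + xb)).sum() / (na + nb))
    resid = d - pooled
    w = nb / (na + nb)
    # effective score per subject: modality-b contrast minus its projection
    # onto the intercept direction (weight w = share of calls made by b)
    u_i = resid * (xb - w * (xa + xb))
    u = float(u_i.sum())
    v = float((u_i**2).sum())
    if v == 0.0:
        # identical calls everywhere: no evidence of any difference
        return PairedTestResult(0.0, 1.0, method, difference=pv_a - pv_b)
    statistic = u**2 / v
    p = float(stats.chi2.sf(statistic, df=1))
    return PairedTestResult(statistic, p, method, difference=pv_a - pv_b)


def _auc_and_components(scores_pos: np.ndarray, scores_neg: np.ndarray):
    """Mann-Whitney AUC with tie handling plus DeLong structural components.

    V10[i] = P-hat(score of diseased i exceeds a random benign score), with
    ties counting one half; V01 analogously for benign subjects.
    """
    m, n = len(scores_pos), len(scores_neg)
    gt = scores_pos[:, None] > scores_neg[None, :]
    eq = scores_pos[:, None] == scores_neg[None, :]
    psi = gt + 0.5 * eq
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return auc, v10, v01


def delong_paired_auc(
    nodes: Sequence[NodeRecord], modality_a: str, modality_b: str
) -> tuple[PairedTestResult, float, float]:
    """DeLong's test for the difference of two correlated ROC areas.

    Returns ``(result, auc_a, auc_b)``. AUCs use the Mann-Whitney estimator
    on the ordinal 0–4 scores (ties count one half); the variance of the
    AUC difference comes from the empirical covariance of the DeLong
    structural components across the paired subjects.
    """
    pos = [n for n in nodes if n.pathology is Pathology.METASTATIC]
    neg = [n for n in nodes if n.pathology is Pathology.BENIGN]
    if not pos or not neg:
        raise ValueError("DeLong comparison requires both diseased and benign nodes")
    sa_pos = np.array([n.score(modality_a) for n in pos], dtype=float)
    sa_neg = np.array([n.score(modality_a) for n in neg], dtype=float)
    sb_pos = np.array([n.score(modality_b) for n in pos], dtype=float)
    sb_neg = np.array([n.score(modality_b) for n in neg], dtype=float)
    auc_a, v10_a, v01_a = _auc_and_components(sa_pos, sa_neg)
    auc_b, v10_b, v01_b = _auc_and_components(sb_pos, sb_neg)
    m, n = len(pos), len(neg)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z, p = 0.0, 1.0
        if abs(diff) > 0:
            z, p = math.inf, 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    result = PairedTestResult(float(z), p, PairedMethod.DELONG, difference=diff)
    return result, auc_a, auc_b
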