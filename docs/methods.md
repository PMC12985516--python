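# Methods

This note records the models, the defaults and the reasoning behind the
design choices, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Paired diagnostic evaluation

Each biopsied node carries two ordinal confidence scores (0 = definitely
benign … 4 = definitely metastatic), one per modality, binarised at a
cutoff; the default cutoff ≥ 2 is deliberately sensitive, reflecting that a
missed node under lower-neck sparing is costlier than overtreatment. All
five accuracy metrics get Wilson score intervals (via
`statsmodels.stats.proportion`): Wilson intervals behave well at the
extreme proportions this data produces (sensitivity near 96%) and
reproduce the printed intervals of the source tables, which never name
their CI method.

Three paired comparisons:

* **McNemar.** Implemented closed-form with the continuity-corrected
  statistic `(max(|b−c|−1, 0))² / (b+c)`. The clamp at zero keeps equal
  discordant counts at p = 1. Correction is ON by default: on the staging
  table's (40, 21) discordant cells the corrected statistic reproduces the
  published p = 0.021, the uncorrected one gives 0.015. Against the exact
  binomial oracle on b+c trials, the corrected p tracks the conventional
  exact p and the plain χ² tracks the mid-p — the test suite checks both
  correspondences.
* **Predictive values (WGS).** PPV/NPV of two tests applied to the same
  subjects are compared with a weighted generalized score test built from
  the GEE score construction: each subject contributes one response
  (disease status) per modality that called it positive (negative for
  NPV); under H0 the common predictive value is the pooled estimate, the
  intercept is profiled out with marginal call-count weights
  (w = n₂⁺/(n₁⁺+n₂⁺)), and the effective score is referred to its
  cluster-robust variance (χ²₁). No installed package provides this test,
  so it is implemented here and validated two ways: identical calls give
  p = 1 exactly, and on seeded synthetic cohorts the p-value agrees with a
  10,000-replicate cluster bootstrap of the predictive-value difference to
  within 0.02 (observed agreement ≈ 0.003).
* **DeLong.** AUC by the Mann–Whitney estimator with ties counting ½
  (appropriate for a 5-level ordinal scale, which is tie-heavy), variance
  and covariance of the paired AUCs from the empirical covariance of the
  DeLong structural components, two-sided z test on the difference. The
  estimator is checked against brute-force pair counting to 1e-12.

A zero-denominator metric (e.g. specificity of an all-metastatic fixture)
is reported as missing, never as 0, so degenerate fixtures cannot
masquerade as informative. PPV/NPV are prevalence-dependent; the package
exposes the Bayes-rule recomputation so users can translate the enriched
biopsy-cohort values (80% metastatic) to realistic pre-test probabilities —
NPV rises as prevalence falls, so enriched-cohort NPV is conservative for
rule-out use.

## N-stage rule engine and adjudication

N category follows the 8th-edition TNM logic for NPC: N0 with no positive
nodes; N3 for any node > 60 mm short axis or any positive node below the
caudal border of the cricoid; otherwise N2 for bilateral cervical
involvement; otherwise N1 (unilateral cervical and/or retropharyngeal —
retropharyngeal nodes, level VII here, do not trigger N2 even bilaterally).
The thresholds are module constants (`N3_SIZE_MM`, the retropharyngeal
level set) so a different edition can be configured. A positive cervical
node with unknown laterality raises rather than guesses, since it decides
N1 vs N2. The engine is monotone — adding a positive node never lowers the
category — verified by exhaustive enumeration.

"Correct N stage" means exact category equality against the
biopsy-adjudicated truth; that definition generates the paired-correctness
table whose discordant cells feed McNemar. The binned N0–1 vs N2–3
comparison — which is what decides upper-neck-only eligibility — is a
separate derived output (`exact=False`), not a redefinition of
correctness. Adjudication is applied symmetrically to every record,
including concordant-but-wrong pairs.

Decision-impact tabulation keeps the two denominators the data actually
has: dose decisions are per target node within a pathology class
(metastatic or benign), field decisions are per patient. A decision record
therefore carries an optional node id, and the per-patient field decision
must be consistent across a patient's records.

## Economic model

Strategy → decision tree → per-branch Markov trace:

* **Tree.** P(TP) = π·Se, P(FN) = π·(1−Se), P(TN) = (1−π)·Sp,
  P(FP) = (1−π)·(1−Sp). Positive calls get whole-neck irradiation,
  negative calls upper-neck-only. π defaults to 0.691 (reported pre-test
  probability of cervical nodal metastasis; tested range 0.632–0.796) —
  *not* the 80% prevalence of the enriched biopsy cohort.
* **States.** recurrence_free, regional_recurrence, post_salvage, dead.
  The source's appendix state list is unavailable; four states are the
  minimum supporting recurrence, salvage and death with distinct
  utilities/costs, and the transition structure is parameter-driven so a
  richer structure can replace it. Recurrence lasts one cycle (salvage
  happens within it), then moves to post-salvage or death.
* **Recurrence.** Entered as 3-year cumulative probabilities and converted
  per cycle by the constant-hazard identity p = 1 − (1 − p₃)^(c/3):
  0.2544 for undertreated missed metastases (the false-negative branch),
  0.04 baseline for everything else (regional failure after correct
  management is rare in the trial context motivating lower-neck sparing).
  The 0.2544 → 0.09322/cycle → 25.44% after three cycles round trip is a
  certified acceptance check.
* **Mortality.** Background 0.008/yr; 0.15 probability of dying in the
  recurrence/salvage cycle; +0.03/yr excess after salvage. Illustrative.
* **Utilities/costs.** Whole-neck irradiation carries a utility decrement
  (0.87 vs 0.92 recurrence-free) and a higher cost; false-positive harm is
  overtreatment toxicity, not excess mortality. Test costs default to
  US$1,700 (PET/CT) vs US$500 (MRI). All cost/utility defaults are
  **clearly-labelled illustrative placeholders**: the published appendix
  inputs are unavailable, so the published base-case costs/QALYs
  (US$27,228/US$25,596; 5.329/5.305), the deterministic flip thresholds
  and the 79.6% acceptability are *not* reproduction targets. What is
  certified: ICER algebra (the published pairs give US$68,000/QALY),
  probability conservation, discounting arithmetic, the recurrence round
  trip, and the structural property that equalising the false-negative
  recurrence penalty and the whole-neck utility decrement removes the
  higher-sensitivity strategy's QALY advantage entirely — the model
  attributes all benefit to avoided undertreatment and avoided toxicity,
  nothing else.
* **Mechanics.** 1-year cycles, 10-year horizon, 3%/yr discount on both
  costs and QALYs (source is silent; 3% is the conventional reference-case
  rate), discount factor (1+r)^(−t) at 1-based cycle index. Half-cycle
  correction ON by default (rewards on the mean of start- and end-of-cycle
  occupancy); the geometric-series unit test fixes it OFF to keep the
  closed form Σ 1.03^(−t) = 8.5302. Radiotherapy and test costs are
  charged undiscounted at cycle 0.
* **Tornado.** One-way re-evaluation at each range bound, all else at
  base; bars sorted by |ICER_high − ICER_low|. Under the shipped defaults
  the ICER stays below the US$100,000/QALY threshold across the prevalence
  range 0.632–0.796, and prevalence moves the ICER far less than the
  specificity/sensitivity parameters — checked as properties, not as value
  reproduction.
* **PSA.** Independent beta draws for probabilities/utilities and gamma
  draws for costs, moment-matched from (mean, 95% range) with
  sd = range/(2·1.96); 1000 iterations by default, fully seeded. The
  acceptability curve reports the fraction of iterations with
  NMB(PET) > NMB(MRI) per WTP point; when every iteration has ΔQALY > 0
  the curve is necessarily non-decreasing, which the suite asserts under
  cost-only uncertainty.

## Synthetic cohorts

* **Diagnostic fixture (cohort A analogue).** 555 metastatic / 139 benign
  nodes whose per-modality confusion counts at cutoff ≥ 2 are exact by
  construction: PET (533, 22, 50, 89), MRI (514, 41, 57, 82) — the integer
  counts implied by the printed class totals and accuracies, consistent
  with the printed 622/694 and 596/694 correct classifications. The joint
  (PET × MRI) cell allocation within each pathology class was never
  published, so it is a free parameter defaulting to maximal overlap;
  node-level p-values for the sensitivity/NPV comparisons therefore cannot
  be certified against the published ones. Scores within the positive band
  are 2/3/4 in 20/30/50 shares (only the binarised call matters for the
  metric tables; the bands exist for AUC exercises), levels follow the
  published per-class composition by largest-remainder apportionment, and
  everything is a deterministic function of the seed.
* **Stochastic generator.** Pathology ~ Bernoulli(prevalence); per node a
  bivariate standard-normal latent pair with correlation ρ (Gaussian
  copula) is thresholded at each modality's class-conditional
  positive-call probability, giving independent control of the marginals
  (Se/Sp exactly, in expectation) and of between-modality agreement, which
  published marginals do not constrain. Latent quantiles are banded to 0–4
  scores by monotone cutpoints. Calibration is tested at n = 10,000:
  marginals within 3 binomial SEs, and ρ = 0 passes a conditional
  independence χ² test.
* **Staging fixture (cohort B analogue).** Exactly reproduces the
  (423, 40, 21, 19) paired-correctness cells; additionally, configurable
  counts of wrong-stage-but-correct-eligibility records (defaults 9 for
  PET, 3 for MRI) reproduce the eligibility accuracies 472/503 and
  447/503. The full N-category distribution is unconstrained beyond the
  published N0/N1 totals, so the fixture's stage composition away from the
  N1/N2 boundary is decorative and not simultaneously matched to the
  published N0–1 totals — downstream tests use only the correctness and
  eligibility summaries, which are exact.
* **Decision fixture (cohort C analogue).** 67 nodes (24 metastatic, 43
  benign) over 62 patients; per-oncologist 3×3 dose and 2×2 field
  transition matrices are reproduced exactly. Defaults encode the
  published change rates (metastatic escalation up to 4/24, benign
  de-escalation 2/43 for all three oncologists, benign escalation 3/0/5,
  field expansion 4/5/7 of 62) with the unpublished cells filled
  plausibly.

**What passing tests show and do not show.** The fixtures certify the
*computations* — that the implemented statistics and rules return the
published summaries when fed cohorts with the published structure. They do
not certify reader behaviour, image interpretation, or any quantity whose
defining inputs (joint call cells, raw score distributions, appendix
economic inputs) were never published; those are covered by structural
properties instead. Synthetic nodes are exchangeable within their class —
real nodes cluster within patients and vary by level and size, which none
of the generators emulate beyond labels.

## Numerical choices and degenerate inputs

* Wilson intervals, two-sided, α = 0.05 everywhere; two-sided p-values
  everywhere.
* McNemar with b + c = 0 returns p = 1 (vacuous test) rather than an
  error; the WGS test with a modality making no positive (PPV) or negative
  (NPV) calls raises an undefined-comparison error.
* DeLong with a zero-variance difference returns p = 1 when the AUCs are
  equal and p = 0 otherwise.
* Largest-remainder apportionment breaks remainder ties by input order
  (stable argsort), making fixtures order-deterministic.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give identical cohorts, PSA draws and output files (byte-identical
  CSVs).
* Problem sizes used by the suite — 694/503/67-record fixtures, n = 10,000
  calibration draws, 10,000 bootstrap replicates, 150–1000 PSA iterations —
  keep the full test run around a few seconds while leaving Monte Carlo
  error well inside the asserted tolerances.

## Known limitations

* The WGS implementation is validated against a bootstrap oracle, not
  against the R reference implementation, which is not distributable here.
* The Markov structure is the minimal 4-state one; salvage is collapsed
  into a single recurrence cycle, and recurrence after salvage is not
  re-entered.
* PSA draws parameters independently; correlated uncertainty (e.g. between
  sensitivity and specificity of the same modality) is not modelled.
* The economic defaults are placeholders; any substantive use requires
  setting the `cea:` section of the run configuration to audited local
  costs and utilities.
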