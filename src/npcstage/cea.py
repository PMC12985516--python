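"""Decision-tree + Markov cohort cost-effectiveness engine.

Two staging strategies for nasopharyngeal carcinoma nodal disease are
compared: image first with MRI versus with FDG PET/CT, then irradiate the
whole neck for node-positive calls and spare the lower neck
(upper-neck-only) for node-negative calls. A decision tree splits the
cohort into the four diagnostic outcomes (TP/FN/TN/FP) from the strategy's
sensitivity/specificity and the pre-test probability of nodal metastasis;
each branch then runs a Markov cohort trace (1-year cycles, 10-year
horizon by default) over four states:

    recurrence_free -> regional_recurrence -> post_salvage -> dead

The false-negative branch — metastatic disease undertreated with
upper-neck-only irradiation — carries an elevated regional-recurrence
risk, entered as a cumulative 3-year probability and converted to a
per-cycle probability under a constant hazard. Whole-neck irradiation
(whether warranted or a false-positive overtreatment) costs more and
carries a toxicity-related utility decrement; it causes no excess
mortality in this model.

Costs and utilities shipped as defaults are illustrative placeholders in
plausible US$ ranges; they are configuration, not findings. The engine's
certified behaviour is structural: probability conservation, discounting
and half-cycle arithmetic, ICER algebra, and the round trip of the 3-year
recurrence input.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

WTP_DEFAULT = 100_000.0


class Arm(str, enum.Enum):
    UPPER_NECK_ONLY = "upper_neck_only"
    WHOLE_NECK = "whole_neck"


class State(enum.IntEnum):
    RECURRENCE_FREE = 0
    REGIONAL_RECURRENCE = 1
    POST_SALVAGE = 2
    DEAD = 3


@dataclass(frozen=True)
class CEAParameters:
    """All economic-model inputs. Flat so one-way and probabilistic
    sensitivity analyses can address any parameter by field name.

    Probabilities are per the unit stated; costs in US$; utilities per
    cycle in [0, 1].
    """

    # pre-test probability of cervical nodal metastasis
    prevalence: float = 0.691
    prevalence_low: float = 0.632
    prevalence_high: float = 0.796

    # strategy diagnostic accuracy (node-positive call for metastasis)
    pet_sensitivity: float = 0.960
    pet_specificity: float = 0.640
    mri_sensitivity: float = 0.926
    mri_specificity: float = 0.590

    # 3-year cumulative regional recurrence, converted to per-cycle internally
    p_recur_3yr_fn: float = 0.2544  # missed metastasis managed upper-neck-only
    p_recur_3yr_treated: float = 0.04  # correctly managed disease / benign baseline
    recurrence_horizon_years: float = 3.0

    # mortality (annual probabilities)
    mortality_annual_background: float = 0.008
    p_death_recurrence_cycle: float = 0.15  # during the recurrence/salvage cycle
    mortality_annual_post_salvage_excess: float = 0.03

    # per-cycle utilities
    utility_rf_upper: float = 0.92
    utility_rf_whole: float = 0.87  # whole-neck toxicity decrement
    utility_recurrence: float = 0.60
    utility_post_salvage: float = 0.75

    # costs (US$)
    cost_test_mri: float = 500.0
    cost_test_pet: float = 1700.0
    cost_rt_upper: float = 20_000.0
    cost_rt_whole: float = 24_000.0
    cost_recurrence_cycle: float = 35_000.0  # salvage management, charged in the RR cycle
    cost_followup_annual: float = 400.0
    cost_post_salvage_annual: float = 1200.0

    # model mechanics
    discount_rate: float = 0.03
    horizon_years: float = 10.0
    cycle_years: float = 1.0
    wtp: float = WTP_DEFAULT
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        probs = {
            "prevalence": self.prevalence,
            "pet_sensitivity": self.pet_sensitivity,
            "pet_specificity": self.pet_specificity,
            "mri_sensitivity": self.mri_sensitivity,
            "mri_specificity": self.mri_specificity,
            "p_recur_3yr_fn": self.p_recur_3yr_fn,
            "p_recur_3yr_treated": self.p_recur_3yr_treated,
            "mortality_annual_background": self.mortality_annual_background,
            "p_death_recurrence_cycle": self.p_death_recurrence_cycle,
            "mortality_annual_post_salvage_excess": self.mortality_annual_post_salvage_excess,
            "utility_rf_upper": self.utility_rf_upper,
            "utility_rf_whole": self.utility_rf_whole,
            "utility_recurrence": self.utility_recurrence,
            "utility_post_salvage": self.utility_post_salvage,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("cost_test_mri", "cost_test_pet", "cost_rt_upper", "cost_rt_whole",
                     "cost_recurrence_cycle", "cost_followup_annual",
                     "cost_post_salvage_annual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        n_cycles = self.horizon_years / self.cycle_years
        if self.horizon_years <= 0 or abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError("horizon_years must be a positive multiple of cycle_years")

    def sensitivity(self, strategy: str) -> float:
        return {"pet": self.pet_sensitivity, "mri": self.mri_sensitivity}[strategy]

    def specificity(self, strategy: str) -> float:
        return {"pet": self.pet_specificity, "mri": self.mri_specificity}[strategy]

    def test_cost(self, strategy: str) -> float:
        return {"pet": self.cost_test_pet, "mri": self.cost_test_mri}[strategy]

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years / self.cycle_years)


def prob_to_cycle(p_cum: float, years_cum: float, cycle_years: float) -> float:
    """Convert a cumulative probability over ``years_cum`` to a per-cycle
    probability under a constant hazard: ``1 - (1 - p)^(cycle/years)``."""
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"p_cum must be in [0, 1), got {p_cum}")
    if years_cum <= 0 or cycle_years <= 0:
        raise ValueError("durations must be positive")
    return 1.0 - (1.0 - p_cum) ** (cycle_years / years_cum)


@dataclass(frozen=True)
class Branch:
    """One decision-tree leaf: diagnostic outcome, its probability, and the arm."""

    label: str  # tp / fn / tn / fp
    probability: float
    arm: Arm
    diseased: bool


def build_decision_tree(params: CEAParameters, strategy: str) -> list[Branch]:
    """Four diagnostic-outcome branches; probabilities sum to one."""
    p = params.prevalence
    sens = params.sensitivity(strategy)
    spec = params.specificity(strategy)
    return [
        Branch("tp", p * sens, Arm.WHOLE_NECK, True),
        Branch("fn", p * (1 - sens), Arm.UPPER_NECK_ONLY, True),
        Branch("tn", (1 - p) * spec, Arm.UPPER_NECK_ONLY, False),
        Branch("fp", (1 - p) * (1 - spec), Arm.WHOLE_NECK, False),
    ]


@dataclass(frozen=True)
class MarkovTrace:
    """Cohort-fraction trajectory plus discounted rewards for one branch."""

    occupancy: np.ndarray  # shape (n_cycles + 1, 4); row 0 = initial cohort
    cumulative_recurrence: np.ndarray  # shape (n_cycles + 1,)
    discounted_cost: float  # includes the branch's upfront treatment cost
    discounted_qaly: float


def _transition_matrix(params: CEAParameters, p_recur_cycle: float) -> np.ndarray:
    m_bg = prob_to_cycle(
        params.mortality_annual_background, 1.0, params.cycle_years
    ) if params.mortality_annual_background < 1 else 1.0
    m_ps = m_bg + prob_to_cycle(
        params.mortality_annual_post_salvage_excess, 1.0, params.cycle_years
    ) if params.mortality_annual_post_salvage_excess < 1 else 1.0
    m_ps = min(m_ps, 1.0)
    m_rr = max(params.p_death_recurrence_cycle, m_bg)
    t = np.zeros((4, 4))
    t[State.RECURRENCE_FREE, State.DEAD] = m_bg
    t[State.RECURRENCE_FREE, State.REGIONAL_RECURRENCE] = (1 - m_bg) * p_recur_cycle
    t[State.RECURRENCE_FREE, State.RECURRENCE_FREE] = (1 - m_bg) * (1 - p_recur_cycle)
    t[State.REGIONAL_RECURRENCE, State.DEAD] = m_rr
    t[State.REGIONAL_RECURRENCE, State.POST_SALVAGE] = 1 - m_rr
    t[State.POST_SALVAGE, State.DEAD] = m_ps
    t[State.POST_SALVAGE, State.POST_SALVAGE] = 1 - m_ps
    t[State.DEAD, State.DEAD] = 1.0
    if not np.allclose(t.sum(axis=1), 1.0):
        raise ValueError("transition-matrix rows must sum to 1")
    return t


def run_markov_trace(branch: Branch, params: CEAParameters) -> MarkovTrace:
    """Advance a cohort (fully recurrence-free at cycle 0) through the horizon.

    Per-cycle rewards are discounted at ``(1 + discount_rate)^(-t)`` with
    ``t`` the 1-based cycle index. Without half-cycle correction, rewards
    accrue on end-of-cycle occupancy; with it, on the mean of start- and
    end-of-cycle occupancy (transitions treated as mid-cycle on average).
    The branch's radiotherapy cost is charged undiscounted at cycle 0.
    """
    elevated = branch.diseased and branch.arm is Arm.UPPER_NECK_ONLY
    p3 = params.p_recur_3yr_fn if elevated else params.p_recur_3yr_treated
    p_recur_cycle = prob_to_cycle(p3, params.recurrence_horizon_years, params.cycle_years)
    t = _transition_matrix(params, p_recur_cycle)

    u_rf = (
        params.utility_rf_upper if branch.arm is Arm.UPPER_NECK_ONLY
        else params.utility_rf_whole
    )
    utilities = np.array([u_rf, params.utility_recurrence, params.utility_post_salvage, 0.0])
    cycle_costs = np.array([
        params.cost_followup_annual,
        params.cost_recurrence_cycle,
        params.cost_post_salvage_annual,
        0.0,
    ])
    rt_cost = params.cost_rt_upper if branch.arm is Arm.UPPER_NECK_ONLY else params.cost_rt_whole

    n = params.n_cycles
    occ = np.zeros((n + 1, 4))
    occ[0, State.RECURRENCE_FREE] = 1.0
    cum_rec = np.zeros(n + 1)
    cost, qaly = float(rt_cost), 0.0
    for k in range(1, n + 1):
        occ[k] = occ[k - 1] @ t
        cum_rec[k] = cum_rec[k - 1] + occ[k - 1, State.RECURRENCE_FREE] * \
            t[State.RECURRENCE_FREE, State.REGIONAL_RECURRENCE]
        basis = 0.5 * (occ[k - 1] + occ[k]) if params.half_cycle_correction else occ[k]
        disc = (1.0 + params.discount_rate) ** (-k)
        qaly += disc * float(basis @ utilities) * params.cycle_years
        cost += disc * float(basis @ cycle_costs)
    return MarkovTrace(occ, cum_rec, cost, qaly)


@dataclass(frozen=True)
class StrategyOutcome:
    strategy: str
    cost: float
    qaly: float


@dataclass(frozen=True)
class CEAResult:
    """Per-strategy expectations and the PET-vs-MRI incremental comparison."""

    outcomes: Mapping[str, StrategyOutcome]
    incremental_cost: float  # pet - mri
    incremental_qaly: float
    icer: Optional[float]  # None when incremental QALYs are zero
    dominant: Optional[str]  # strategy that is cheaper AND more effective, if any

    def nmb(self, strategy: str, wtp: float) -> float:
        o = self.outcomes[strategy]
        return wtp * o.qaly - o.cost


def icer_from_pairs(
    cost_a: float, cost_b: float, qaly_a: float, qaly_b: float
) -> Optional[float]:
    """Incremental cost-effectiveness ratio (a vs b); None when ΔQALY = 0."""
    dq = qaly_a - qaly_b
    if dq == 0:
        return None
    return (cost_a - cost_b) / dq


def evaluate_strategy(params: CEAParameters, strategy: str) -> StrategyOutcome:
    cost = params.test_cost(strategy)
    qaly = 0.0
    for branch in build_decision_tree(params, strategy):
        trace = run_markov_trace(branch, params)
        cost += branch.probability * trace.discounted_cost
        qaly += branch.probability * trace.discounted_qaly
    return StrategyOutcome(strategy, cost, qaly)


def evaluate_strategies(params: CEAParameters) -> CEAResult:
    outcomes = {s: evaluate_strategy(params, s) for s in ("mri", "pet")}
    d_cost = outcomes["pet"].cost - outcomes["mri"].cost
    d_qaly = outcomes["pet"].qaly - outcomes["mri"].qaly
    dominant = None
    if d_qaly > 0 and d_cost < 0:
        dominant = "pet"
    elif d_qaly < 0 and d_cost > 0:
        dominant = "mri"
    return CEAResult(
        outcomes=outcomes,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer_from_pairs(
            outcomes["pet"].cost, outcomes["mri"].cost,
            outcomes["pet"].qaly, outcomes["mri"].qaly,
        ),
        dominant=dominant,
    )


# ---------------------------------------------------------------------------
# deterministic (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

DEFAULT_TORNADO_RANGES: dict[str, tuple[float, float]] = {
    "prevalence": (0.632, 0.796),
    "pet_sensitivity": (0.941, 0.974),
    "mri_sensitivity": (0.901, 0.945),
    "pet_specificity": (0.558, 0.715),
    "mri_specificity": (0.507, 0.668),
    "p_recur_3yr_fn": (0.15, 0.40),
    "cost_test_pet": (1000.0, 2500.0),
}


def _replace(params: CEAParameters, name: str, value: float) -> CEAParameters:
    if not hasattr(params, name):
        raise ValueError(f"unknown parameter {name!r}")
    return dataclasses.replace(params, **{name: value})


def tornado(
    params: CEAParameters,
    param_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One-way sensitivity of the ICER to each parameter over its range.

    Each parameter is set to its low then high bound with everything else
    at base; rows are sorted by descending bar width |ICER_high - ICER_low|.
    Ranges must bracket the base value.
    """
    ranges = dict(param_ranges) if param_ranges is not None else dict(DEFAULT_TORNADO_RANGES)
    base = evaluate_strategies(params)
    rows = []
    for name, (lo, hi) in ranges.items():
        base_val = getattr(params, name)
        if not (lo <= base_val <= hi):
            raise ValueError(
                f"range ({lo}, {hi}) for {name!r} does not bracket base {base_val}"
            )
        icer_lo = evaluate_strategies(_replace(params, name, lo)).icer
        icer_hi = evaluate_strategies(_replace(params, name, hi)).icer
        width = (
            abs(icer_hi - icer_lo)
            if icer_lo is not None and icer_hi is not None
            else math.inf
        )
        rows.append(dict(parameter=name, low=lo, high=hi,
                         icer_at_low=icer_lo, icer_at_high=icer_hi, bar_width=width))
    df = pd.DataFrame(rows).sort_values("bar_width", ascending=False, kind="mergesort")
    df.attrs["base_icer"] = base.icer
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDistribution:
    """Sampling distribution for one parameter, moment-matched from a mean
    and a two-sided 95% range (sd = range width / (2 * 1.96))."""

    family: str  # "beta" for probabilities/utilities, "gamma" for costs
    mean: float
    low: float
    high: float

    @property
    def sd(self) -> float:
        return (self.high - self.low) / (2 * 1.959963984540054)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        m, s = self.mean, self.sd
        if s == 0:
            return np.full(size, m)
        if self.family == "beta":
            if not 0 < m < 1:
                raise ValueError(f"beta mean must be in (0,1), got {m}")
            nu = m * (1 - m) / s**2 - 1
            if nu <= 0:
                raise ValueError(f"beta variance {s**2} too large for mean {m}")
            return rng.beta(m * nu, (1 - m) * nu, size=size)
        if self.family == "gamma":
            if m <= 0:
                raise ValueError("gamma mean must be positive")
            shape = (m / s) ** 2
            return rng.gamma(shape, s**2 / m, size=size)
        raise ValueError(f"unknown distribution family {self.family!r}")


def default_psa_distributions(params: CEAParameters) -> dict[str, ParamDistribution]:
    """Beta draws for probabilities/utilities, gamma for costs, centred on
    the base case with 95% ranges of +/-10% of the mean (clipped to [0,1]
    for probabilities via the beta parameterisation)."""
    def beta(name: str, lo: float | None = None, hi: float | None = None):
        m = getattr(params, name)
        lo = lo if lo is not None else max(m * 0.9, 1e-6)
        hi = hi if hi is not None else min(m * 1.1, 1 - 1e-6)
        return ParamDistribution("beta", m, lo, hi)

    def gamma(name: str):
        m = getattr(params, name)
        return ParamDistribution("gamma", m, m * 0.9, m * 1.1)

    return {
        "prevalence": beta("prevalence", params.prevalence_low, params.prevalence_high),
        "pet_sensitivity": beta("pet_sensitivity", 0.941, 0.974),
        "pet_specificity": beta("pet_specificity", 0.558, 0.715),
        "mri_sensitivity": beta("mri_sensitivity", 0.901, 0.945),
        "mri_specificity": beta("mri_specificity", 0.507, 0.668),
        "p_recur_3yr_fn": beta("p_recur_3yr_fn", 0.15, 0.40),
        "p_recur_3yr_treated": beta("p_recur_3yr_treated", 0.02, 0.08),
        "utility_rf_upper": beta("utility_rf_upper"),
        "utility_rf_whole": beta("utility_rf_whole"),
        "utility_recurrence": beta("utility_recurrence"),
        "utility_post_salvage": beta("utility_post_salvage"),
        "cost_test_pet": gamma("cost_test_pet"),
        "cost_test_mri": gamma("cost_test_mri"),
        "cost_rt_upper": gamma("cost_rt_upper"),
        "cost_rt_whole": gamma("cost_rt_whole"),
        "cost_recurrence_cycle": gamma("cost_recurrence_cycle"),
    }


@dataclass(frozen=True)
class PSAResult:
    draws: pd.DataFrame  # iteration, strategy cost/qaly columns, incrementals
    acceptability: pd.DataFrame  # wtp, p_pet_cost_effective
    seed: int
    n_iter: int

    @property
    def p_pet_cost_effective_at(self) -> Mapping[float, float]:
        return dict(zip(self.acceptability["wtp"], self.acceptability["p_pet_cost_effective"]))


def psa(
    params: CEAParameters,
    distributions: Mapping[str, ParamDistribution] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    wtp_grid: Sequence[float] | None = None,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Draws every distributed parameter jointly (independently across
    parameters) ``n_iter`` times, re-evaluates both strategies per draw,
    and reports the cost-effectiveness acceptability curve: the fraction
    of iterations in which the PET/CT-first strategy has the higher net
    monetary benefit at each willingness-to-pay point.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    dists = distributions if distributions is not None else default_psa_distributions(params)
    for name, dist in dists.items():
        if not hasattr(params, name):
            raise ValueError(f"distribution given for unknown parameter {name!r}")
        if dist.family == "beta" and not (0 <= dist.low <= dist.high <= 1):
            raise ValueError(f"beta range for {name!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    samples = {name: dist.sample(rng, n_iter) for name, dist in sorted(dists.items())}
    rows = []
    for i in range(n_iter):
        p_i = dataclasses.replace(params, **{k: float(v[i]) for k, v in samples.items()})
        res = evaluate_strategies(p_i)
        rows.append(dict(
            iteration=i,
            cost_mri=res.outcomes["mri"].cost, qaly_mri=res.outcomes["mri"].qaly,
            cost_pet=res.outcomes["pet"].cost, qaly_pet=res.outcomes["pet"].qaly,
            incremental_cost=res.incremental_cost, incremental_qaly=res.incremental_qaly,
        ))
    draws = pd.DataFrame(rows)
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 5_000.0)
    acc_rows = []
    for wtp in wtp_grid:
        nmb_diff = wtp * draws["incremental_qaly"] - draws["incremental_cost"]
        acc_rows.append(dict(wtp=float(wtp), p_pet_cost_effective=float((nmb_diff > 0).mean())))
    return PSAResult(
        draws=draws,
        acceptability=pd.DataFrame(acc_rows),
        seed=seed,
        n_iter=n_iter,
    )
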