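"""Decision tree and lifetime Markov cohort engine.

Each treatment strategy is a two-branch decision tree: after neoadjuvant
therapy a fraction of the cohort (the regimen's pCR rate) achieves pathologic
complete response and receives the pCR-branch adjuvant regimen; the remainder
has residual disease and receives the residual-branch regimen.  Each branch
then enters a Markov cohort model over nine health states — recurrence free,
local recurrence, distant recurrence, AML, CHF, and four absorbing death
states — cycled annually from the cohort start age to the model horizon.

Cycle conventions
-----------------
State rewards (utilities and annual costs) use the mean of beginning- and
end-of-cycle occupancy, i.e. the standard half-cycle correction in which
transitions are treated as occurring mid-cycle; accordingly rewards for cycle
``k`` are discounted at ``(1 + r)**-(k + 0.5)``.  One-off rewards attached to
transitions (first-year local-recurrence premium, initial CHF treatment,
lifetime AML cost) are charged to the transition flow at the same mid-cycle
discount point.  Upfront treatment costs are charged at time 0 undiscounted.
The fraction leaving distant recurrence for death in a cycle is credited the
terminal-year utility (0.16 by default) for that cycle in place of its
half-cycle distant-recurrence credit, and — for consistency with that "last
full year with distant recurrence" reading — a full rather than half year of
distant-recurrence care cost for that cycle.  Treatment-related AML and CHF
are entered from the recurrence-free state; by default their 1-year incidence
probabilities recur every cycle (the state-transition structure treats them
as ongoing competing risks for chemotherapy-exposed patients), with a
``toxicity_mode="first_cycle"`` setting restricting them to the treatment
year.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazards import (
    apply_rr,
    median_survival_to_annual_prob,
    multiyear_prob_to_annual,
    normalize_competing,
)
from .parameters import ModelSettings, ParameterSet, StrategySpec

__all__ = [
    "HealthState",
    "LifeTable",
    "Branch",
    "MarkovTrace",
    "StrategyResult",
    "build_branches",
    "toxicity_probs",
    "transition_matrix",
    "run_branch",
    "evaluate_strategy",
    "evaluate_strategies",
]


class HealthState(enum.IntEnum):
    RECURRENCE_FREE = 0
    LOCAL_RECURRENCE = 1
    DISTANT_RECURRENCE = 2
    AML = 3
    CHF = 4
    DEATH_BC = 5
    DEATH_AML = 6
    DEATH_CHF = 7
    DEATH_OTHER = 8


N_STATES = len(HealthState)
ALIVE = tuple(s for s in HealthState if s < HealthState.DEATH_BC)
DEAD = tuple(s for s in HealthState if s >= HealthState.DEATH_BC)


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause female death probability q(age) on integer ages."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.shape != qx.shape:
            raise ValueError("ages and qx must have equal length")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life-table probabilities must lie in [0, 1]")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be consecutive integers")

    def q(self, age: float) -> float:
        """Death probability for the year of age containing ``age``."""
        idx = int(np.floor(age)) - int(self.ages[0])
        if idx < 0 or idx >= len(self.ages):
            raise ValueError(f"age {age} outside life-table coverage "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(self.qx[idx])

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())


@dataclass(frozen=True)
class Branch:
    """One decision-tree branch: a cohort stratum with fixed annual risks."""

    strategy_id: int
    response: str  # "pcr" | "residual"
    weight: float
    upfront_cost: float
    p_dr_annual: float
    p_lr_annual: float
    toxicity_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"branch weight {self.weight} outside [0, 1]")
        if self.upfront_cost < 0:
            raise ValueError("upfront cost must be nonnegative")


def build_branches(s: StrategySpec, p: ParameterSet) -> tuple[Branch, Branch]:
    """Expand a strategy into its pCR and residual-disease branches."""
    s.validate_against(p)
    p_dr_ref = multiyear_prob_to_annual(p.dr3y_ref, 3.0)
    p_lr_ref = multiyear_prob_to_annual(p.lr3y_ref, 3.0)
    pcr_weight = p.pcr_prob[s.neoadjuvant]
    neo_cost = p.cost_neoadjuvant[s.neoadjuvant]

    pcr = Branch(
        strategy_id=s.id,
        response="pcr",
        weight=pcr_weight,
        upfront_cost=neo_cost + p.cost_adjuvant[s.pcr_adjuvant] + s.pcr_cost_increment,
        p_dr_annual=apply_rr(p_dr_ref, p.rr_dr["H_PCR"]),
        p_lr_annual=apply_rr(p_lr_ref, p.rr_lr),
        toxicity_class=s.pcr_toxicity,
    )
    residual_rr_lr = 1.0 if s.residual_lr_reference else p.rr_lr
    residual = Branch(
        strategy_id=s.id,
        response="residual",
        weight=1.0 - pcr_weight,
        upfront_cost=neo_cost + p.cost_adjuvant[s.residual_adjuvant],
        p_dr_annual=apply_rr(p_dr_ref, p.rr_dr[s.residual_rr_dr]),
        p_lr_annual=apply_rr(p_lr_ref, residual_rr_lr),
        toxicity_class=s.residual_toxicity,
    )
    return pcr, residual


def toxicity_probs(toxicity_class: str, p: ParameterSet) -> tuple[float, float]:
    """First-year (CHF, AML) probabilities for a treatment exposure class."""
    if toxicity_class == "ac":
        return apply_rr(p.chf1y_ref, p.rr_chf_ac), apply_rr(p.aml1y_ref, p.rr_aml_ac)
    if toxicity_class == "non_ac":
        return p.chf1y_ref, apply_rr(p.aml1y_ref, p.rr_aml_nonac)
    if toxicity_class == "no_chemo":
        return 0.0, p.aml1y_ref
    raise ValueError(f"unknown toxicity class {toxicity_class!r}")


def transition_matrix(
    b: Branch,
    p: ParameterSet,
    lt: LifeTable,
    age: float,
    cycle_index: int,
    toxicity_mode: str = "lifetime",
) -> np.ndarray:
    """Row-stochastic transition matrix for one cycle of one branch."""
    q = lt.q(age)
    if toxicity_mode not in ("lifetime", "first_cycle"):
        raise ValueError(f"unknown toxicity_mode {toxicity_mode!r}")
    tox_on = toxicity_mode == "lifetime" or cycle_index == 0
    p_chf, p_aml = toxicity_probs(b.toxicity_class, p) if tox_on else (0.0, 0.0)
    p_lr_to_dr = multiyear_prob_to_annual(p.p_dr_after_lr_10y, 10.0)
    p_dr_death = median_survival_to_annual_prob(p.median_surv_dr_months)
    p_aml_death = median_survival_to_annual_prob(p.median_surv_aml_months)

    M = np.zeros((N_STATES, N_STATES))
    exits = {
        HealthState.RECURRENCE_FREE: (
            (HealthState.LOCAL_RECURRENCE, b.p_lr_annual),
            (HealthState.DISTANT_RECURRENCE, b.p_dr_annual),
            (HealthState.AML, p_aml),
            (HealthState.CHF, p_chf),
            (HealthState.DEATH_OTHER, q),
        ),
        HealthState.LOCAL_RECURRENCE: (
            (HealthState.DISTANT_RECURRENCE, p_lr_to_dr),
            (HealthState.DEATH_OTHER, q),
        ),
        HealthState.DISTANT_RECURRENCE: (
            (HealthState.DEATH_BC, p_dr_death),
            (HealthState.DEATH_OTHER, q),
        ),
        HealthState.AML: (
            (HealthState.DEATH_AML, p_aml_death),
            (HealthState.DEATH_OTHER, q),
        ),
        HealthState.CHF: (
            (HealthState.DEATH_CHF, p.p_chf_death_annual),
            (HealthState.DEATH_OTHER, q),
        ),
    }
    for state, targets in exits.items():
        probs = normalize_competing([pr for _, pr in targets])
        for (target, _), pr in zip(targets, probs):
            M[state, target] = pr
        M[state, state] = 1.0 - sum(probs)
    for state in DEAD:
        M[state, state] = 1.0
    if np.any(M < -1e-12) or np.any(M > 1 + 1e-12):
        raise ValueError("transition probabilities out of range after composition")
    return M


@dataclass
class MarkovTrace:
    """Per-cycle occupancy and reward increments for one branch."""

    ages: np.ndarray          # cycle start ages, length n_cycles
    occupancy: np.ndarray     # (n_cycles + 1, N_STATES), row k = start of cycle k
    qaly: np.ndarray          # undiscounted QALY increment per cycle
    qaly_disc: np.ndarray
    cost: np.ndarray          # undiscounted cost increment per cycle (incl. upfront in cycle 0)
    cost_disc: np.ndarray

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy[:-1], columns=[s.name.lower() for s in HealthState]
        )
        df.insert(0, "age", self.ages)
        df["qaly"] = self.qaly
        df["qaly_disc"] = self.qaly_disc
        df["cost"] = self.cost
        df["cost_disc"] = self.cost_disc
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_branch(
    b: Branch,
    p: ParameterSet,
    settings: ModelSettings,
    lt: LifeTable,
) -> MarkovTrace:
    """Iterate the cohort from the start age to the horizon for one branch."""
    n = settings.n_cycles
    if n < 1:
        raise ValueError("model horizon must cover at least one cycle")
    dt = settings.cycle_length
    r = settings.discount_rate

    occ = np.zeros((n + 1, N_STATES))
    occ[0, HealthState.RECURRENCE_FREE] = 1.0
    ages = settings.start_age + dt * np.arange(n)
    qaly = np.zeros(n)
    qaly_d = np.zeros(n)
    cost = np.zeros(n)
    cost_d = np.zeros(n)

    RF, LR, DR = (HealthState.RECURRENCE_FREE, HealthState.LOCAL_RECURRENCE,
                  HealthState.DISTANT_RECURRENCE)
    AML, CHF = HealthState.AML, HealthState.CHF

    for k in range(n):
        M = transition_matrix(b, p, lt, ages[k], k, settings.toxicity_mode)
        x = occ[k]
        x_next = x @ M
        occ[k + 1] = x_next
        avg = 0.5 * (x + x_next)

        u_rf = p.u_rf_first_year if k == 0 else p.u_rf
        uq = (avg[RF] * u_rf + avg[LR] * p.u_lr + avg[DR] * p.u_dr
              + avg[AML] * p.u_aml + avg[CHF] * p.u_chf)
        # dying-from-DR fraction: full-cycle terminal utility replaces its
        # half-cycle DR credit
        d_dr = x[DR] * (M[DR, HealthState.DEATH_BC] + M[DR, HealthState.DEATH_OTHER])
        uq += d_dr * (p.u_dr_terminal - 0.5 * p.u_dr)

        c = (avg[LR] * p.cost_lr_subsequent + avg[DR] * p.cost_dr_annual
             + avg[CHF] * p.cost_chf_annual)
        c += x[RF] * M[RF, LR] * (p.cost_lr_first_year - p.cost_lr_subsequent)
        c += x[RF] * M[RF, CHF] * p.cost_chf_initial
        c += x[RF] * M[RF, AML] * p.cost_aml_lifetime
        # dying-from-DR fraction accrues its full terminal year of DR care
        c += d_dr * 0.5 * p.cost_dr_annual

        disc = (1.0 + r) ** (-(k + 0.5) * dt)
        qaly[k] = uq * dt
        qaly_d[k] = uq * dt * disc
        cost[k] = c * dt
        cost_d[k] = c * dt * disc

    cost[0] += b.upfront_cost
    cost_d[0] += b.upfront_cost  # charged at time 0, undiscounted
    return MarkovTrace(ages=ages, occupancy=occ, qaly=qaly, qaly_disc=qaly_d,
                       cost=cost, cost_disc=cost_d)


@dataclass(frozen=True)
class StrategyResult:
    """Expected discounted totals for one strategy."""

    strategy_id: int
    name: str
    cost: float
    qalys: float


def evaluate_strategy(
    s: StrategySpec,
    p: ParameterSet,
    settings: ModelSettings,
    lt: LifeTable,
) -> StrategyResult:
    """Weight-average the two branch traces of a strategy."""
    cost = 0.0
    qalys = 0.0
    for branch in build_branches(s, p):
        if branch.weight == 0.0:
            continue
        trace = run_branch(branch, p, settings, lt)
        cost += branch.weight * trace.total_cost
        qalys += branch.weight * trace.total_qalys
    return StrategyResult(strategy_id=s.id, name=s.name, cost=cost, qalys=qalys)


def evaluate_strategies(
    strategies: list[StrategySpec],
    p: ParameterSet,
    settings: ModelSettings,
    lt: LifeTable,
) -> list[StrategyResult]:
    return [evaluate_strategy(s, p, settings, lt) for s in strategies]
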