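"""Synthetic fixtures: parametric life table, microsimulation oracle,
parameter perturbation.

The Gompertz-Makeham life table stands in for a published all-cause female
life table so the package runs with no external downloads; its default
parameters approximate recent US female mortality (annual hazard
``lambda + b * exp(theta * age)``).  The microsimulation oracle re-derives
the per-cycle transition probabilities and reward rules directly from their
definitions — independently of the cohort engine — and estimates each
branch's expected discounted cost and QALYs by simulating individual
patient trajectories, providing a cross-check on the deterministic cohort
model.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .cohort_model import Branch, HealthState, LifeTable, N_STATES
from .parameters import GompertzMakehamParams, ModelSettings, ParameterSet

__all__ = [
    "GompertzMakehamParams",
    "make_life_table",
    "life_expectancy",
    "microsim_oracle",
    "perturb_parameters",
]


def make_life_table(
    params: GompertzMakehamParams | None = None,
    age_range: tuple[int, int] = (0, 120),
) -> LifeTable:
    """Tabulate annual death probabilities from a Gompertz-Makeham hazard."""
    gm = params or GompertzMakehamParams()
    ages = np.arange(age_range[0], age_range[1] + 1)
    hazard = gm.makeham + gm.scale * np.exp(gm.shape * ages)
    qx = np.minimum(1.0 - np.exp(-hazard), 1.0)
    if np.any(qx >= 1.0):
        warnings.warn("life-table death probability saturates at 1 before the "
                      "oldest tabulated age")
    return LifeTable(ages=ages, qx=qx)


def life_expectancy(lt: LifeTable, age: int) -> float:
    """Undiscounted residual life expectancy at ``age`` (half-year convention)."""
    i0 = int(age) - int(lt.ages[0])
    surv = np.cumprod(1.0 - lt.qx[i0:])
    # each year lived in full plus half of the year of death
    prev = np.concatenate([[1.0], surv[:-1]])
    return float(np.sum(0.5 * (prev + surv)))


def _annual_from_multiyear(p: float, years: float) -> float:
    return 1.0 - (1.0 - p) ** (1.0 / years)


def _annual_from_median_months(m: float) -> float:
    return 1.0 - 2.0 ** (-12.0 / m)


def _feasible(probs: list[float]) -> list[float]:
    total = sum(probs)
    if total <= 1.0:
        return probs
    rates = [-math.log(1.0 - p) for p in probs]
    rate_sum = sum(rates)
    exit_total = 1.0 - math.exp(-rate_sum)
    return [exit_total * r / rate_sum for r in rates]


def microsim_oracle(
    branch: Branch,
    p: ParameterSet,
    settings: ModelSettings,
    lt: LifeTable,
    n_patients: int,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Individual-level estimate of a branch's expected discounted rewards.

    Returns ``(mean_cost, mean_qalys, se_cost, se_qalys)`` over ``n_patients``
    simulated trajectories.  Transitions are drawn per patient-year from
    probabilities assembled here from their definitions; rewards follow the
    mid-cycle convention (a transitioning patient accrues half a cycle in each
    state, entry lump sums at the transition, terminal-year utility for the
    cycle of death from distant recurrence).
    """
    if n_patients < 1:
        raise ValueError("need at least one simulated patient")
    n_cycles = settings.n_cycles
    r = settings.discount_rate
    dt = settings.cycle_length

    if branch.toxicity_class == "ac":
        p_chf = min(p.chf1y_ref * p.rr_chf_ac, 1.0)
        p_aml = min(p.aml1y_ref * p.rr_aml_ac, 1.0)
    elif branch.toxicity_class == "non_ac":
        p_chf = p.chf1y_ref
        p_aml = min(p.aml1y_ref * p.rr_aml_nonac, 1.0)
    else:
        p_chf, p_aml = 0.0, p.aml1y_ref

    p_lr_dr = _annual_from_multiyear(p.p_dr_after_lr_10y, 10.0)
    p_dr_death = _annual_from_median_months(p.median_surv_dr_months)
    p_aml_death = _annual_from_median_months(p.median_surv_aml_months)

    RF, LR, DR = (int(HealthState.RECURRENCE_FREE), int(HealthState.LOCAL_RECURRENCE),
                  int(HealthState.DISTANT_RECURRENCE))
    AML, CHF = int(HealthState.AML), int(HealthState.CHF)
    D_BC, D_AML = int(HealthState.DEATH_BC), int(HealthState.DEATH_AML)
    D_CHF, D_OTH = int(HealthState.DEATH_CHF), int(HealthState.DEATH_OTHER)

    annual_cost = np.zeros(N_STATES)
    annual_cost[LR] = p.cost_lr_subsequent
    annual_cost[DR] = p.cost_dr_annual
    annual_cost[CHF] = p.cost_chf_annual
    utility = np.zeros(N_STATES)
    utility[LR], utility[DR] = p.u_lr, p.u_dr
    utility[AML], utility[CHF] = p.u_aml, p.u_chf

    states = np.full(n_patients, RF, dtype=np.int8)
    cost_acc = np.full(n_patients, branch.upfront_cost)
    qaly_acc = np.zeros(n_patients)

    for k in range(n_cycles):
        age = settings.start_age + k * dt
        q = lt.q(age)
        disc = (1.0 + r) ** (-(k + 0.5) * dt)
        u_rf = p.u_rf_first_year if k == 0 else p.u_rf
        utility[RF] = u_rf

        # per-state (targets, cumulative probabilities) for this cycle
        tox_on = settings.toxicity_mode == "lifetime" or k == 0
        chf_k, aml_k = (p_chf, p_aml) if tox_on else (0.0, 0.0)
        spec = {
            RF: ([LR, DR, AML, CHF, D_OTH],
                 _feasible([branch.p_lr_annual, branch.p_dr_annual, aml_k, chf_k, q])),
            LR: ([DR, D_OTH], _feasible([p_lr_dr, q])),
            DR: ([D_BC, D_OTH], _feasible([p_dr_death, q])),
            AML: ([D_AML, D_OTH], _feasible([p_aml_death, q])),
            CHF: ([D_CHF, D_OTH], _feasible([p.p_chf_death_annual, q])),
        }

        new_states = states.copy()
        alive = states < D_BC
        if not alive.any():
            break
        u = rng.random(n_patients)
        for s, (targets, probs) in spec.items():
            mask = states == s
            if not mask.any():
                continue
            edges = np.cumsum(probs)
            dest = np.searchsorted(edges, u[mask], side="right")
            moved = np.where(dest < len(targets),
                             np.asarray(targets + [s])[np.minimum(dest, len(targets))],
                             s)
            new_states[mask] = moved.astype(np.int8)

        stay = alive & (new_states == states)
        move = alive & (new_states != states)

        dq = np.zeros(n_patients)
        dq[stay] = utility[states[stay]]
        dq[move] = 0.5 * (utility[states[move]] + utility[new_states[move]])
        dying_dr = move & (states == DR)
        dq[dying_dr] = p.u_dr_terminal

        dc = np.zeros(n_patients)
        dc[stay] = annual_cost[states[stay]]
        dc[move] = 0.5 * (annual_cost[states[move]] + annual_cost[new_states[move]])
        dc[dying_dr] = annual_cost[DR]  # full terminal year of DR care
        dc[move & (new_states == LR)] += p.cost_lr_first_year - p.cost_lr_subsequent
        dc[move & (new_states == CHF)] += p.cost_chf_initial
        dc[move & (new_states == AML)] += p.cost_aml_lifetime

        qaly_acc += dq * dt * disc
        cost_acc += dc * dt * disc
        states = new_states

    return (
        float(cost_acc.mean()),
        float(qaly_acc.mean()),
        float(cost_acc.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        float(qaly_acc.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
    )


def perturb_parameters(
    base: ParameterSet, relative_spread: float, rng: np.random.Generator
) -> ParameterSet:
    """Multiply every numeric field by an independent factor in
    ``[1 - spread, 1 + spread]``, clamping each result to its invariant range.

    A property-test input generator: perturbed sets exercise the model away
    from the base case while remaining valid.
    """
    if not 0.0 <= relative_spread < 1.0:
        raise ValueError("relative_spread must lie in [0, 1)")
    out = base.copy()
    for path in sorted(base.iter_paths()):
        factor = 1.0 + relative_spread * (2.0 * rng.random() - 1.0)
        v = base.get(path) * factor
        leaf = path.split(".")[0]
        if leaf.startswith("cost_"):
            v = max(v, 0.0)
        elif leaf.startswith("rr_") or leaf.startswith("median_surv"):
            v = max(v, 1e-9)
        else:
            v = min(max(v, 0.0), 1.0)
        parts = path.split(".")
        if len(parts) == 1:
            setattr(out, parts[0], v)
        else:
            getattr(out, parts[0])[parts[1]] = v
    out.validate()
    return out
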