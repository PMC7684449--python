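"""Probabilistic, one-way, scenario, and subgroup analyses.

``run_psa`` propagates the parameter distributions through the full model
with a common random parameter draw per iteration across strategies;
``run_owsa`` sweeps influential parameters one at a time over printed or
±30% ranges; ``run_scenario`` ships the named scenario variants (adjuvant
pertuzumab added for pCR patients, cohort start age 64, alternative
distant-recurrence relative risk for the residual DDAC + T-DM1 branch);
``run_subgroup`` re-parameterizes the model for an estrogen-receptor-status
subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cea import CEATable, build_cea_table
from .cohort_model import LifeTable, StrategyResult, evaluate_strategies
from .parameters import (
    ConfigError,
    ModelSettings,
    ParameterSet,
    StrategySpec,
    sample_parameter_set,
)

__all__ = [
    "PSAResultSet",
    "OWSARange",
    "DEFAULT_OWSA_RANGES",
    "SCENARIOS",
    "SUBGROUP_RR_DR_TDM1",
    "run_psa",
    "run_owsa",
    "run_scenario",
    "run_subgroup",
]


@dataclass
class PSAResultSet:
    """Per-iteration strategy results of a probabilistic analysis."""

    strategy_ids: list[int]
    costs: np.ndarray   # (n_iterations, n_strategies)
    qalys: np.ndarray
    seed: int
    n_iterations: int
    generator: str = "numpy.random.PCG64"

    def to_dataframe(self) -> pd.DataFrame:
        n_iter, n_strat = self.costs.shape
        return pd.DataFrame({
            "iteration": np.repeat(np.arange(n_iter), n_strat),
            "strategy_id": np.tile(self.strategy_ids, n_iter),
            "cost": self.costs.ravel(),
            "qalys": self.qalys.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def mean_results(self) -> list[StrategyResult]:
        return [
            StrategyResult(sid, f"strategy_{sid}",
                           float(self.costs[:, j].mean()),
                           float(self.qalys[:, j].mean()))
            for j, sid in enumerate(self.strategy_ids)
        ]


def run_psa(
    base: ParameterSet,
    settings: ModelSettings,
    strategies: list[StrategySpec],
    lt: LifeTable,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> PSAResultSet:
    """Monte Carlo propagation of parameter uncertainty.

    One parameter draw per iteration, shared by all strategies (common random
    parameters), then a full deterministic model evaluation per strategy.
    Reproducible from the seed: parameters are consumed from a single stream
    in sorted-path order.
    """
    n_iter = int(n_iterations if n_iterations is not None else settings.psa_iterations)
    if n_iter < 1:
        raise ValueError("psa_iterations must be at least 1")
    seed = int(seed if seed is not None else settings.rng_seed)
    rng = np.random.default_rng(seed)

    ids = [s.id for s in strategies]
    costs = np.empty((n_iter, len(strategies)))
    qalys = np.empty((n_iter, len(strategies)))
    for i in range(n_iter):
        try:
            draw = sample_parameter_set(base, rng)
            results = evaluate_strategies(strategies, draw, settings, lt)
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        for j, res in enumerate(results):
            costs[i, j] = res.cost
            qalys[i, j] = res.qalys
    return PSAResultSet(strategy_ids=ids, costs=costs, qalys=qalys,
                        seed=seed, n_iterations=n_iter)


@dataclass(frozen=True)
class OWSARange:
    """One-way sensitivity range for a dotted parameter path."""

    path: str
    low: float
    high: float
    n_points: int = 13

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.path}: OWSA range requires low < high")

    def grid(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_points)


def _pm30(base: ParameterSet, path: str, cap: float | None = None) -> OWSARange:
    v = base.get(path)
    hi = 1.3 * v if cap is None else min(1.3 * v, cap)
    return OWSARange(path, 0.7 * v, hi)


def DEFAULT_OWSA_RANGES(base: ParameterSet) -> list[OWSARange]:
    """The shipped sweep set: printed ranges plus ±30% for the influential
    parameters (pCR rates, recurrence risks, toxicity probabilities, distant-
    recurrence cost)."""
    return [
        OWSARange("pcr_prob.THP", 0.32, 0.59),
        _pm30(base, "pcr_prob.HP", cap=1.0),
        _pm30(base, "pcr_prob.DDAC_THP", cap=1.0),
        _pm30(base, "pcr_prob.TCHP", cap=1.0),
        _pm30(base, "dr3y_ref", cap=1.0),
        _pm30(base, "rr_dr.TDM1"),
        _pm30(base, "rr_dr.DDACTHP_TDM1"),
        OWSARange("rr_dr.DDAC_TDM1", 0.28, 0.55),
        _pm30(base, "chf1y_ref", cap=1.0),
        _pm30(base, "aml1y_ref", cap=1.0),
        OWSARange("cost_dr_annual", 97_434.0, 180_948.0),
    ]


def run_owsa(
    base: ParameterSet,
    settings: ModelSettings,
    strategies: list[StrategySpec],
    lt: LifeTable,
    ranges: list[OWSARange] | None = None,
) -> pd.DataFrame:
    """One-way sweeps: all other parameters held at base.

    Returns a tidy table with one row per (parameter, grid point, strategy)
    carrying cost/QALYs, plus per-point columns naming the optimal strategy
    (if any) and the cost-effective strategy at each WTP threshold.
    """
    if ranges is None:
        ranges = DEFAULT_OWSA_RANGES(base)
    rows = []
    for rng_spec in ranges:
        for value in rng_spec.grid():
            params = base.with_value(rng_spec.path, float(value))
            results = evaluate_strategies(strategies, params, settings, lt)
            cea_tab = build_cea_table(results, settings.wtp_thresholds)
            for res in results:
                row = {
                    "parameter": rng_spec.path,
                    "value": float(value),
                    "strategy_id": res.strategy_id,
                    "cost": res.cost,
                    "qalys": res.qalys,
                    "optimal": cea_tab.optimal,
                }
                for wtp, sid in cea_tab.cost_effective.items():
                    row[f"cost_effective_at_{wtp:.0f}"] = sid
                rows.append(row)
    return pd.DataFrame(rows)


#: relative risk of distant recurrence for adjuvant T-DM1 by ER status
SUBGROUP_RR_DR_TDM1 = {"positive": 0.48, "negative": 0.50}

SCENARIOS = ("adjuvant_hp", "age64", "rr_ddac_tdm1")


def run_scenario(
    name: str,
    base: ParameterSet,
    settings: ModelSettings,
    strategies: list[StrategySpec],
    lt: LifeTable,
    overrides: dict[str, float] | None = None,
) -> CEATable:
    """Evaluate one of the shipped scenario analyses.

    ``adjuvant_hp``
        Adds adjuvant pertuzumab to the pCR-branch adjuvant trastuzumab.
        Requires ``overrides["pertuzumab_cost_increment"]`` (USD added to each
        pCR-branch adjuvant cost); treatment effects are unchanged.
    ``age64``
        Cohort start age moved to 64 years.
    ``rr_ddac_tdm1``
        Overrides the distant-recurrence relative risk of the residual
        DDAC + T-DM1 branch with ``overrides["rr_dr"]``.
    """
    overrides = dict(overrides or {})
    params = base
    if name == "adjuvant_hp":
        if "pertuzumab_cost_increment" not in overrides:
            raise ConfigError(
                "scenario 'adjuvant_hp' requires overrides['pertuzumab_cost_increment'] "
                "(the annual-course cost added to pCR-branch adjuvant trastuzumab)"
            )
        increment = float(overrides.pop("pertuzumab_cost_increment"))
        # charged to the pCR branch only: the adjuvant-H cost key is shared
        # with strategy 1's residual branch, which is unaffected
        strategies = [replace(s, pcr_cost_increment=increment) for s in strategies]
    elif name == "age64":
        settings = ModelSettings(
            start_age=64.0,
            cycle_length=settings.cycle_length,
            horizon_age=settings.horizon_age,
            discount_rate=settings.discount_rate,
            wtp_thresholds=settings.wtp_thresholds,
            wtp_grid=settings.wtp_grid,
            psa_iterations=settings.psa_iterations,
            rng_seed=settings.rng_seed,
        )
    elif name == "rr_ddac_tdm1":
        if "rr_dr" not in overrides:
            raise ConfigError("scenario 'rr_ddac_tdm1' requires overrides['rr_dr']")
        params = base.with_value("rr_dr.DDAC_TDM1", float(overrides.pop("rr_dr")))
    else:
        raise ConfigError(f"unknown scenario {name!r}; shipped scenarios: {SCENARIOS}")

    for path, value in overrides.items():
        params = params.with_value(path, value)
    results = evaluate_strategies(strategies, params, settings, lt)
    return build_cea_table(results, settings.wtp_thresholds)


def run_subgroup(
    er_status: str,
    base: ParameterSet,
    settings: ModelSettings,
    strategies: list[StrategySpec],
    lt: LifeTable,
    pcr_prob: dict[str, float] | None = None,
    dr3y_ref: float | None = None,
    rr_dr_tdm1: float | None = None,
) -> CEATable:
    """Cost-effectiveness table for an estrogen-receptor-status subgroup.

    ER-specific pCR rates per neoadjuvant regimen must be supplied by the
    user (``pcr_prob``); they are not published in the main analysis tables.
    The T-DM1 distant-recurrence relative risk defaults to the ER-specific
    trial estimates (0.48 ER-positive, 0.50 ER-negative) and is applied to
    the branches whose residual-disease adjuvant effect is that of T-DM1.
    """
    if er_status not in SUBGROUP_RR_DR_TDM1:
        raise ConfigError("er_status must be 'positive' or 'negative'")
    if pcr_prob is None:
        raise ConfigError(
            "ER-subgroup analysis requires ER-specific pCR rates per neoadjuvant "
            "regimen; pass pcr_prob={'HP': ..., 'THP': ..., 'DDAC_THP': ..., "
            "'TCHP': ...} or supply them in a subgroup configuration file"
        )
    params = base.copy()
    for regimen, rate in pcr_prob.items():
        if regimen not in params.pcr_prob:
            raise ConfigError(f"unknown neoadjuvant regimen {regimen!r} in subgroup pCR rates")
        params.pcr_prob[regimen] = float(rate)
    if dr3y_ref is not None:
        params.dr3y_ref = float(dr3y_ref)
    params.rr_dr["TDM1"] = float(
        rr_dr_tdm1 if rr_dr_tdm1 is not None else SUBGROUP_RR_DR_TDM1[er_status]
    )
    params.validate()
    results = evaluate_strategies(strategies, params, settings, lt)
    return build_cea_table(results, settings.wtp_thresholds)
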