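"""Cost-effectiveness statistics.

Implements the incremental cost-effectiveness ratio (ICER) ladder with strong
and extended dominance, net monetary benefit (NMB = WTP * QALYs - cost),
cost-effectiveness acceptability curves (CEAC), and the acceptability
frontier.  A strategy with strictly the most QALYs at strictly the lowest
cost is *optimal* (dominant over all alternatives); otherwise the frontier
strategy with the highest ICER at or below a willingness-to-pay threshold is
*cost-effective* at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import StrategyResult

__all__ = ["DOMINATED", "EXTENDED_DOMINATED", "icer", "nmb",
           "CEATable", "build_cea_table", "CEACResult", "ceac"]

DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended-dominated"


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """ICER of one alternative against a comparator.

    Returns a USD/QALY ratio when the alternative buys QALYs at a cost,
    ``"dominated"`` when it costs more for no gain, and ``"dominant"`` when it
    saves money without losing QALYs.  Both deltas exactly zero is undefined.
    """
    if delta_cost == 0.0 and delta_qaly == 0.0:
        raise ValueError("ICER undefined: both incremental cost and QALYs are zero")
    if delta_qaly <= 0.0 and delta_cost > 0.0:
        return DOMINATED
    if delta_qaly >= 0.0 and delta_cost <= 0.0:
        return "dominant"
    return delta_cost / delta_qaly


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit of a strategy at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * result.qalys - result.cost


@dataclass
class CEATable:
    """ICER ladder over a strategy set, sorted by ascending cost.

    ``table`` has one row per strategy with incremental cost/QALYs and ICER
    computed against the next least-costly non-dominated comparator; ``label``
    holds the dominance classification.  ``cost_effective`` maps each WTP
    threshold to the id of the cost-effective strategy at that threshold;
    ``optimal`` is the id of a strategy dominating all others, if one exists.
    """

    table: pd.DataFrame
    cost_effective: dict[float, int] = field(default_factory=dict)
    optimal: int | None = None

    @property
    def frontier_ids(self) -> list[int]:
        return list(self.table.loc[self.table["on_frontier"], "strategy_id"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "cost_effective": {f"{w:g}": s for w, s in self.cost_effective.items()},
            "optimal": self.optimal,
        }


def build_cea_table(
    results: list[StrategyResult],
    wtp_thresholds: tuple[float, ...] = (50_000.0, 100_000.0, 150_000.0),
) -> CEATable:
    """Rank strategies by cost and classify dominance along the frontier."""
    if len(results) < 2:
        raise ValueError("need at least two strategies to compare")
    ids = [r.strategy_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicated strategy ids: {ids}")

    ordered = sorted(results, key=lambda r: (r.cost, -r.qalys))
    labels: dict[int, str] = {}

    # strong dominance: another strategy is at least as cheap and at least as
    # effective, and better on one margin
    for r in ordered:
        for other in ordered:
            if other is r:
                continue
            if (other.cost <= r.cost and other.qalys >= r.qalys
                    and (other.cost < r.cost or other.qalys > r.qalys)):
                labels[r.strategy_id] = DOMINATED
                break

    # extended dominance: drop frontier candidates until ICERs strictly increase
    frontier = [r for r in ordered if r.strategy_id not in labels]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_mid = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_hi = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_mid >= icer_hi:
                labels[mid.strategy_id] = EXTENDED_DOMINATED
                frontier.pop(i)
                changed = True
                break

    frontier_icers: dict[int, float] = {}
    for prev, cur in zip(frontier, frontier[1:]):
        frontier_icers[cur.strategy_id] = (cur.cost - prev.cost) / (cur.qalys - prev.qalys)

    best = max(results, key=lambda r: r.qalys)
    cheapest = min(results, key=lambda r: r.cost)
    optimal = None
    if best.strategy_id == cheapest.strategy_id and all(
        (r.qalys < best.qalys and r.cost > best.cost)
        for r in results if r.strategy_id != best.strategy_id
    ):
        optimal = best.strategy_id

    cost_effective: dict[float, int] = {}
    for wtp in wtp_thresholds:
        choice = frontier[0].strategy_id
        for r in frontier[1:]:
            if frontier_icers[r.strategy_id] <= wtp:
                choice = r.strategy_id
        cost_effective[float(wtp)] = choice

    rows = []
    prev_frontier: StrategyResult | None = None
    for r in ordered:
        on_frontier = r.strategy_id not in labels
        if r.strategy_id == frontier[0].strategy_id:
            inc_cost = inc_qaly = icer_val = np.nan
            label = "optimal" if optimal == r.strategy_id else "reference"
        elif on_frontier:
            inc_cost = r.cost - prev_frontier.cost
            inc_qaly = r.qalys - prev_frontier.qalys
            icer_val = frontier_icers[r.strategy_id]
            label = f"{icer_val:.0f}"
        else:
            comparator = prev_frontier if prev_frontier is not None else frontier[0]
            inc_cost = r.cost - comparator.cost
            inc_qaly = r.qalys - comparator.qalys
            icer_val = np.nan
            label = labels[r.strategy_id]
        if on_frontier:
            prev_frontier = r
        rows.append({
            "strategy_id": r.strategy_id,
            "name": r.name,
            "cost": r.cost,
            "qalys": r.qalys,
            "inc_cost": inc_cost,
            "inc_qalys": inc_qaly,
            "icer": icer_val,
            "label": label,
            "on_frontier": on_frontier,
        })
    return CEATable(table=pd.DataFrame(rows), cost_effective=cost_effective,
                    optimal=optimal)


@dataclass
class CEACResult:
    """Acceptability curves over a willingness-to-pay grid.

    ``prob`` has shape (len(wtp_grid), n_strategies): the fraction of PSA
    iterations in which each strategy attains the maximum NMB (ties split
    equally).  ``frontier`` follows, at each WTP, the strategy with the
    highest mean NMB.
    """

    wtp_grid: np.ndarray
    strategy_ids: list[int]
    prob: np.ndarray
    frontier_strategy: np.ndarray
    frontier: np.ndarray

    def curve(self, strategy_id: int) -> np.ndarray:
        return self.prob[:, self.strategy_ids.index(strategy_id)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.prob, columns=[f"strategy_{i}" for i in self.strategy_ids])
        df.insert(0, "wtp", self.wtp_grid)
        df["frontier_strategy"] = self.frontier_strategy
        df["frontier"] = self.frontier
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ceac(
    psa_costs: np.ndarray,
    psa_qalys: np.ndarray,
    strategy_ids: list[int],
    wtp_grid: np.ndarray,
) -> CEACResult:
    """Acceptability curves and frontier from per-iteration PSA results.

    ``psa_costs``/``psa_qalys`` have shape (n_iterations, n_strategies) with
    columns in ``strategy_ids`` order.
    """
    costs = np.atleast_2d(np.asarray(psa_costs, dtype=float))
    qalys = np.atleast_2d(np.asarray(psa_qalys, dtype=float))
    if costs.shape[0] < 1:
        raise ValueError("PSA result set is empty")
    if costs.shape != qalys.shape or costs.shape[1] != len(strategy_ids):
        raise ValueError("PSA cost/QALY arrays and strategy ids are inconsistent")
    wtp = np.asarray(wtp_grid, dtype=float)

    # nmb: (n_wtp, n_iter, n_strat)
    nmb_arr = wtp[:, None, None] * qalys[None, :, :] - costs[None, :, :]
    best = nmb_arr.max(axis=2, keepdims=True)
    winners = nmb_arr == best
    shares = winners / winners.sum(axis=2, keepdims=True)  # split ties equally
    prob = shares.mean(axis=1)

    mean_nmb = nmb_arr.mean(axis=1)
    front_idx = mean_nmb.argmax(axis=1)
    frontier = prob[np.arange(len(wtp)), front_idx]
    frontier_strategy = np.asarray([strategy_ids[i] for i in front_idx])
    return CEACResult(wtp_grid=wtp, strategy_ids=list(strategy_ids), prob=prob,
                      frontier_strategy=frontier_strategy, frontier=frontier)
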