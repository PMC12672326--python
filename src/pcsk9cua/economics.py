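"""Discounted costs and QALYs per strategy, ICURs, and the dominance frontier.

Costs and utilities accrue per cycle on half-cycle-corrected occupancy (the
average of start- and end-of-cycle state fractions) and are discounted at
the annual rates in the cohort settings. One-off event payoffs — the
terminal CV-death cost and the revascularization cost/disutility — apply to
the incremental mass experiencing the event that cycle and are discounted
mid-cycle. Dominance follows the standard frontier construction: strictly
dominated strategies (costlier, no more effective) are removed first, then
extended dominance iteratively removes strategies whose incremental
cost-utility ratio exceeds that of a more effective alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CohortTrace, run_cohort
from .parameters import ParameterSet, RegimenSpec
from .states import ALIVE, HealthState as S

__all__ = ["StrategyOutcome", "FrontierResult", "discount_factor",
           "accumulate_outcomes", "evaluate_strategy", "evaluate_all",
           "icur", "frontier"]

_ALIVE_IDX = np.array([int(s) for s in ALIVE])


def discount_factor(cycle: int, rate: float, cycle_length: float = 1.0) -> float:
    """Present-value factor for a flow at model cycle ``cycle``: (1+r)^(-k*t)."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + rate) ** (-cycle * cycle_length)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted and undiscounted lifetime totals for one strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    cost_breakdown: dict[str, float]


def _state_cost_vector(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """(MI-pathway, IS-pathway) annual state-cost vectors over the 11 states."""
    c = params.costs
    mi = np.zeros(len(S))
    is_ = np.zeros(len(S))
    mi[[S.MI_Y1, S.MI2_Y1]] = c.mi_year1
    mi[[S.POST_MI, S.POST_MI2]] = c.mi_subsequent_annual
    is_[[S.IS_Y1, S.IS2_Y1]] = c.is_year1
    is_[[S.POST_IS, S.POST_IS2]] = c.is_subsequent_annual
    return mi, is_


def _utility_vector(params: ParameterSet) -> np.ndarray:
    u = params.utilities
    vec = np.zeros(len(S))
    vec[S.NO_CVD] = u.baseline
    vec[S.MI_Y1] = u.mi_year1
    vec[S.POST_MI] = u.mi_post
    vec[S.MI2_Y1] = u.mi2_year1
    vec[S.POST_MI2] = u.mi2_post
    vec[S.IS_Y1] = u.is_year1
    vec[S.POST_IS] = u.is_post
    vec[S.IS2_Y1] = u.is2_year1
    vec[S.POST_IS2] = u.is2_post
    return vec


def accumulate_outcomes(trace: CohortTrace, params: ParameterSet,
                        regimen: RegimenSpec) -> StrategyOutcome:
    """Fold a cohort trace into discounted lifetime cost and QALY totals.

    Per cycle: state costs (first-year and long-term post-event care), the
    background statin cost on all alive person-time, the regimen's drug cost
    (pens x per-pen price x administrations, with the year-1 schedule),
    revascularization and CV-death event costs; utilities weighted by state
    occupancy, the annual injection disutility on injectable arms, and the
    one-off revascularization disutility.
    """
    settings = params.settings
    n = settings.n_cycles
    if trace.n_cycles != n:
        raise ValueError("trace horizon does not match parameter settings")
    t = settings.cycle_length
    occ = trace.occupancy
    hc = settings.half_cycle_correction
    occ_flow = (occ[:-1] + occ[1:]) / 2.0 if hc else occ[:-1]

    mi_cost_vec, is_cost_vec = _state_cost_vector(params)
    u_vec = _utility_vector(params)
    alive = occ_flow[:, _ALIVE_IDX].sum(axis=1)
    cv_death_entry = np.diff(occ[:, S.CV_DEATH])

    k = np.arange(n)
    dc = (1.0 + settings.discount_rate_costs) ** (-k * t)
    do = (1.0 + settings.discount_rate_outcomes) ** (-k * t)
    k_mid = k + 0.5 if hc else k.astype(float)
    dc_mid = (1.0 + settings.discount_rate_costs) ** (-k_mid * t)
    do_mid = (1.0 + settings.discount_rate_outcomes) ** (-k_mid * t)

    drug_annual = np.array([regimen.annual_drug_cost(int(i)) for i in k])

    statin = params.costs.statin_annual * alive * t
    pcsk9 = drug_annual * alive * t
    mi_states = occ_flow @ mi_cost_vec * t
    is_states = occ_flow @ is_cost_vec * t
    revasc = trace.revasc_events * params.costs.revascularization
    cv_death = cv_death_entry * params.costs.cv_death

    qaly_states = occ_flow @ u_vec * t
    qaly_inject = (params.utilities.disutility_injection * alive * t
                   if regimen.is_injectable else np.zeros(n))
    qaly_revasc = trace.revasc_events * params.utilities.disutility_revasc

    state_cost = statin + pcsk9 + mi_states + is_states
    breakdown = {
        "statin": float(statin @ dc),
        "pcsk9_drug": float(pcsk9 @ dc),
        "mi_states": float(mi_states @ dc),
        "is_states": float(is_states @ dc),
        "revascularization": float(revasc @ dc_mid),
        "cv_death": float(cv_death @ dc_mid),
    }
    total_cost = sum(breakdown.values())
    total_qaly = float((qaly_states + qaly_inject) @ do + qaly_revasc @ do_mid)
    undisc_cost = float(state_cost.sum() + revasc.sum() + cv_death.sum())
    undisc_qaly = float((qaly_states + qaly_inject + qaly_revasc).sum())
    return StrategyOutcome(regimen.name, total_cost, total_qaly,
                           undisc_cost, undisc_qaly, breakdown)


def evaluate_strategy(params: ParameterSet, regimen: RegimenSpec) -> StrategyOutcome:
    """Run the cohort for one regimen and fold it into lifetime outcomes."""
    return accumulate_outcomes(run_cohort(params, regimen), params, regimen)


def evaluate_all(params: ParameterSet) -> list[StrategyOutcome]:
    """Evaluate every regimen in the parameter set."""
    return [evaluate_strategy(params, r) for r in params.regimens]


def icur(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Incremental cost-utility ratio of ``b`` versus ``a`` (USD/QALY).

    Uses full-precision totals; a zero QALY difference is signalled as an
    error rather than returned as an infinity.
    """
    dq = b.total_qaly - a.total_qaly
    if dq == 0:
        raise ValueError(
            f"strategies '{a.strategy}' and '{b.strategy}' have equal QALYs; "
            "ICUR undefined")
    return (b.total_cost - a.total_cost) / dq


@dataclass(frozen=True)
class FrontierResult:
    """Dominance classification and ICURs across strategies.

    ``outcomes`` are sorted by ascending cost; ``status`` maps each strategy
    to ``frontier``, ``dominated`` or ``extended_dominated``;
    ``icur_vs_reference`` holds each strategy's pairwise ICUR against the
    reference arm (NaN where the QALY difference is zero or for the
    reference itself); ``icur_frontier`` the ICUR of each frontier strategy
    against the previous (less costly) frontier strategy.
    """

    outcomes: tuple[StrategyOutcome, ...]
    status: dict[str, str]
    icur_vs_reference: dict[str, float]
    icur_frontier: dict[str, float]

    def to_frame(self, reference: str) -> pd.DataFrame:
        ref = next(o for o in self.outcomes if o.strategy == reference)
        rows = []
        for o in self.outcomes:
            rows.append({
                "strategy": o.strategy,
                "total_cost": o.total_cost,
                "total_qaly": o.total_qaly,
                "delta_cost": o.total_cost - ref.total_cost,
                "delta_qaly": o.total_qaly - ref.total_qaly,
                "icur_vs_reference": self.icur_vs_reference.get(o.strategy,
                                                                math.nan),
                "icur_frontier": self.icur_frontier.get(o.strategy, math.nan),
                "status": self.status[o.strategy],
            })
        return pd.DataFrame(rows)


def frontier(outcomes: list[StrategyOutcome], reference: str) -> FrontierResult:
    """Classify strategies into frontier / dominated / extended-dominated.

    A strategy is dominated if some alternative costs no more and yields at
    least as many QALYs (strictly better on one axis; exact ties are broken
    lexically). Extended dominance then iteratively removes strategies whose
    frontier ICUR exceeds that of the next, more effective frontier option,
    leaving a frontier with non-decreasing incremental ratios.
    """
    names = [o.strategy for o in outcomes]
    if len(names) != len(set(names)):
        raise ValueError("duplicate strategy labels")
    if len(outcomes) < 2:
        raise ValueError("frontier needs at least two strategies")
    if reference not in names:
        raise ValueError(f"reference strategy '{reference}' not present")

    ordered = sorted(outcomes, key=lambda o: (o.total_cost, -o.total_qaly,
                                              o.strategy))
    status: dict[str, str] = {}
    for o in ordered:
        for p in ordered:
            if p is o:
                continue
            better = (p.total_cost < o.total_cost
                      or p.total_qaly > o.total_qaly
                      or (p.total_cost == o.total_cost
                          and p.total_qaly == o.total_qaly
                          and p.strategy < o.strategy))
            if (p.total_cost <= o.total_cost and p.total_qaly >= o.total_qaly
                    and better):
                status[o.strategy] = "dominated"
                break
        else:
            status[o.strategy] = "frontier"

    live = [o for o in ordered if status[o.strategy] == "frontier"]
    while len(live) > 2:
        removed = False
        for i in range(1, len(live) - 1):
            if icur(live[i - 1], live[i]) > icur(live[i], live[i + 1]):
                status[live[i].strategy] = "extended_dominated"
                del live[i]
                removed = True
                break
        if not removed:
            break

    ref = next(o for o in outcomes if o.strategy == reference)
    icur_vs_ref = {}
    for o in outcomes:
        if o.strategy == reference or o.total_qaly == ref.total_qaly:
            icur_vs_ref[o.strategy] = math.nan
        else:
            icur_vs_ref[o.strategy] = icur(ref, o)
    icur_front = {live[0].strategy: math.nan}
    for prev, cur in zip(live, live[1:]):
        icur_front[cur.strategy] = icur(prev, cur)
    return FrontierResult(tuple(ordered), status, icur_vs_ref, icur_front)
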