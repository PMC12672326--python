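"""Sensitivity and scenario analyses around the base case.

Covers one-way (tornado) sensitivity analysis, probabilistic sensitivity
analysis (PSA) with cost-effectiveness acceptability curves (CEAC),
time-horizon scenarios, and the value-based price-threshold analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import evaluate_all, evaluate_strategy, icur
from .parameters import ParameterSet, sample_parameters

logger = logging.getLogger(__name__)

__all__ = ["TornadoEntry", "PSAResult", "CEACurve", "one_way_sa",
           "default_tornado_parameters", "run_psa", "prob_cost_effective",
           "ceac", "default_wtp_grid", "scenario_horizons", "price_threshold"]


# ---------------------------------------------------------------------------
# one-way sensitivity (tornado)

@dataclass(frozen=True)
class TornadoEntry:
    """ICUR of target vs reference at one parameter's low and high bound.

    ``flagged`` marks bounds at which the target is dominated (non-positive
    incremental QALYs), where an ICUR is not meaningful; the corresponding
    ICUR is NaN and the spread is computed over the finite bounds only.
    """

    parameter: str
    low_input: float
    high_input: float
    icur_at_low: float
    icur_at_high: float
    spread: float
    flagged: bool = False


def default_tornado_parameters(params: ParameterSet) -> list[str]:
    """Every non-fixed registered parameter, plus the discount rate and the
    background statin cost (varied +/-20% for lack of a published interval)."""
    names = [n for n, d in params.distributions.items() if d.family != "fixed"]
    return ["settings.discount_rate", "costs.statin_annual"] + names


def _bounds(params: ParameterSet, name: str) -> tuple[float, float]:
    if name == "settings.discount_rate":
        return 0.0, 0.08
    base = params.value(name)
    dist = params.distributions.get(name)
    if dist is not None and dist.range[0] != dist.range[1]:
        return dist.range
    lo, hi = base * 0.8, base * 1.2  # +/-20% fallback when no CI is published
    return (hi, lo) if lo > hi else (lo, hi)


def _pairwise_icur(params: ParameterSet, target: str, reference: str) -> float:
    out_t = evaluate_strategy(params, params.regimen(target))
    out_r = evaluate_strategy(params, params.regimen(reference))
    if out_t.total_qaly <= out_r.total_qaly:
        return math.nan
    return icur(out_r, out_t)


def one_way_sa(params: ParameterSet, target: str, reference: str,
               parameter_list: list[str] | None = None) -> list[TornadoEntry]:
    """Tornado analysis: rerun the deterministic pipeline at each parameter's
    bounds (95% interval, +/-20%, or 0-8% for the discount rate) and record
    the pairwise ICUR of ``target`` versus ``reference``.

    Entries are sorted by descending ICUR spread.
    """
    if parameter_list is None:
        parameter_list = default_tornado_parameters(params)
    entries = []
    for name in parameter_list:
        lo, hi = _bounds(params, name)
        icur_lo = _pairwise_icur(params.replace_value(name, lo),
                                 target, reference)
        icur_hi = _pairwise_icur(params.replace_value(name, hi),
                                 target, reference)
        flagged = math.isnan(icur_lo) or math.isnan(icur_hi)
        if flagged:
            logger.warning("tornado: '%s' bound leaves %s dominated", name,
                           target)
            finite = [x for x in (icur_lo, icur_hi) if not math.isnan(x)]
            spread = 0.0 if len(finite) < 2 else abs(finite[1] - finite[0])
        else:
            spread = abs(icur_hi - icur_lo)
        entries.append(TornadoEntry(name, lo, hi, icur_lo, icur_hi, spread,
                                    flagged))
    entries.sort(key=lambda e: -e.spread)
    return entries


def tornado_to_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass(frozen=True)
class PSAResult:
    """Per-draw (cost, QALY) pairs for every strategy."""

    draws: tuple[dict[str, tuple[float, float]], ...]
    n: int
    seed: int
    strategies: tuple[str, ...]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(costs, qalys) arrays of shape (n_draws, n_strategies)."""
        costs = np.array([[d[s][0] for s in self.strategies]
                          for d in self.draws])
        qalys = np.array([[d[s][1] for s in self.strategies]
                          for d in self.draws])
        return costs, qalys

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.draws):
            for s in self.strategies:
                rows.append({"draw": i, "strategy": s,
                             "cost": d[s][0], "qaly": d[s][1]})
        return pd.DataFrame(rows)


def run_psa(params: ParameterSet, n: int = 1000, seed: int = 0) -> PSAResult:
    """Monte-Carlo propagation of joint parameter uncertainty.

    Each draw jointly resamples every non-fixed parameter and reruns the
    full pipeline for every strategy. Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    strategies = tuple(r.name for r in params.regimens)
    draws = []
    for i in range(n):
        try:
            drawn = sample_parameters(params, int(seeds[i]))
            outcomes = evaluate_all(drawn)
        except ValueError as exc:
            raise ValueError(f"PSA draw {i} failed: {exc}") from exc
        draws.append({o.strategy: (o.total_cost, o.total_qaly)
                      for o in outcomes})
    return PSAResult(tuple(draws), n, seed, strategies)


def prob_cost_effective(psa: PSAResult, target: str, reference: str,
                        wtp: float) -> float:
    """Fraction of draws in which ``target`` beats ``reference`` in net
    monetary benefit at willingness-to-pay ``wtp`` (i.e. pairwise ICUR below
    the threshold when the target is more effective)."""
    costs, qalys = psa.arrays()
    it, ir = psa.strategies.index(target), psa.strategies.index(reference)
    nmb_gain = wtp * (qalys[:, it] - qalys[:, ir]) - (costs[:, it] - costs[:, ir])
    return float(np.mean(nmb_gain > 0))


@dataclass(frozen=True)
class CEACurve:
    """Probability of being the optimal strategy across a WTP grid."""

    wtp_grid: np.ndarray
    prob_cost_effective: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wtp": self.wtp_grid})
        for s, p in self.prob_cost_effective.items():
            df[s] = p
        return df


def default_wtp_grid(params: ParameterSet, n: int = 100) -> np.ndarray:
    """0 to the upper WTP threshold in ``n`` steps, plus both named thresholds."""
    grid = np.linspace(0.0, params.settings.wtp_high, n)
    return np.unique(np.concatenate(
        [grid, [params.settings.wtp_low, params.settings.wtp_high]]))


def ceac(psa: PSAResult, wtp_grid: np.ndarray) -> CEACurve:
    """Cost-effectiveness acceptability curves under the highest-NMB rule.

    Per draw and WTP value, the optimal strategy maximizes net monetary
    benefit ``wtp * QALY - cost``; exact ties are broken towards the lower
    cost, then lexically (and logged). Probabilities across strategies sum
    to 1 at every grid point.
    """
    if psa.n == 0 or len(psa.draws) == 0:
        raise ValueError("PSA result is empty")
    costs, qalys = psa.arrays()
    m = len(psa.strategies)
    probs = {s: np.zeros(len(wtp_grid)) for s in psa.strategies}
    for j, wtp in enumerate(np.asarray(wtp_grid, dtype=float)):
        nmb = wtp * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb == best
        winners = np.argmax(is_best, axis=1)
        ties = np.nonzero(is_best.sum(axis=1) > 1)[0]
        for i in ties:
            cands = [k for k in range(m) if is_best[i, k]]
            winners[i] = min(cands,
                             key=lambda k: (costs[i, k], psa.strategies[k]))
        if ties.size:
            logger.info("CEAC: %d tied draws at WTP %.1f broken by cost",
                        ties.size, wtp)
        counts = np.bincount(winners, minlength=m)
        for k, s in enumerate(psa.strategies):
            probs[s][j] = counts[k] / len(psa.draws)
    return CEACurve(np.asarray(wtp_grid, dtype=float), probs)


# ---------------------------------------------------------------------------
# scenario and price-threshold analyses

def scenario_horizons(params: ParameterSet,
                      horizons: list[float]) -> pd.DataFrame:
    """Rerun the deterministic pipeline truncated at each horizon.

    Returns one row per (horizon, strategy) with discounted cost, QALYs and
    the pairwise ICUR versus the comparator arm.
    """
    reference = params.comparator.name
    rows = []
    for h in horizons:
        if not params.life_table.covers(params.settings.start_age, h):
            raise ValueError(f"horizon {h} exceeds life-table coverage")
        p = replace(params, settings=replace(params.settings, horizon=float(h)))
        outcomes = {o.strategy: o for o in evaluate_all(p)}
        ref = outcomes[reference]
        for name, o in outcomes.items():
            dq = o.total_qaly - ref.total_qaly
            rows.append({
                "horizon": h, "strategy": name,
                "total_cost": o.total_cost, "total_qaly": o.total_qaly,
                "delta_cost": o.total_cost - ref.total_cost,
                "delta_qaly": dq,
                "icur_vs_reference": (math.nan if dq == 0
                                      else icur(ref, o)),
            })
    return pd.DataFrame(rows)


def price_threshold(params: ParameterSet, target: str, reference: str,
                    wtp: float, method: str = "closed_form") -> float:
    """Maximum per-pen price at which ``target``'s ICUR vs ``reference``
    equals ``wtp``.

    Lifetime cost is affine in the per-pen price while QALYs are
    price-invariant, so the threshold has the closed form
    ``p* = p0 + (wtp * dQALY - dCost(p0)) / W`` with ``W`` the discounted
    administration weight (drug-cost component divided by the current
    price). ``method="bisect"`` solves the same root by bisection on the
    full pipeline instead, as an independent cross-check. A threshold above
    the current price means no price reduction is needed.
    """
    regimen = params.regimen(target)
    if not regimen.is_injectable or regimen.price_per_pen <= 0:
        raise ValueError(f"'{target}' has no positive per-pen price to solve for")
    out_ref = evaluate_strategy(params, params.regimen(reference))
    out_t = evaluate_strategy(params, regimen)
    dq = out_t.total_qaly - out_ref.total_qaly
    if dq <= 0:
        raise ValueError(f"'{target}' gains no QALYs over '{reference}'; "
                         "no finite price threshold")
    p0 = regimen.price_per_pen
    weight = out_t.cost_breakdown["pcsk9_drug"] / p0
    dcost = out_t.total_cost - out_ref.total_cost
    p_star = p0 + (wtp * dq - dcost) / weight
    if method == "closed_form":
        return p_star
    if method != "bisect":
        raise ValueError(f"unknown method '{method}'")

    path = f"price_per_pen.{regimen.agent}"

    def excess(p: float) -> float:
        repriced = params.replace_value(path, p)
        out = evaluate_strategy(repriced, repriced.regimen(target))
        return (out.total_cost - out_ref.total_cost) - wtp * dq

    lo, hi = 0.0, max(2 * p0, 2 * abs(p_star), 1.0)
    while excess(hi) < 0:
        hi *= 2
    if excess(lo) > 0:
        raise ValueError("no positive price satisfies the threshold")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-7 * max(1.0, abs(hi)):
            break
    return 0.5 * (lo + hi)
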