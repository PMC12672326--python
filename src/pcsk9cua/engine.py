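"""Markov cohort engine: transition probabilities and the cohort trace.

Rates are combined multiplicatively — baseline event rate x age/LDL-C
calibration x treatment effect (rate ratio per mmol/L raised to the
regimen's LDL-C reduction) x post-event history multipliers — then converted
to per-cycle probabilities. Competing exits from a state are resolved
jointly under the constant-rate (exponential) assumption: the total exit
probability is ``1 - exp(-sum of rates)``, apportioned across causes in
proportion to their rates, which guarantees row-stochastic matrices and
reduces to the single-cause formula when only one exit competes.

Structure: one cardiovascular event at most per cycle; first-year post-event
tunnel states drain into their long-term states after one cycle;
cardiovascular and non-cardiovascular death are absorbing. Revascularization
is an expected-event overlay on alive states (costs and a one-off
disutility), never a state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import EffectPerMmol, ParameterSet, RegimenSpec, RiskMultipliers
from .states import (ABSORBING, ALIVE, HealthState as S, IS_PATHWAY,
                     MI_PATHWAY, N_STATES, TUNNEL_EXIT, TUNNELS)

logger = logging.getLogger(__name__)

__all__ = ["TransitionMatrix", "CohortTrace", "rate_to_prob", "prob_to_rate",
           "adjust_baseline_rate", "treated_rate", "mortality_rates",
           "build_transition_matrix", "run_cohort"]


def rate_to_prob(rate: float, t: float = 1.0) -> float:
    """Convert a constant event rate to the probability of >=1 event in time ``t``.

    ``P = 1 - exp(-rate * t)``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if t <= 0:
        raise ValueError("t must be positive")
    return -math.expm1(-rate * t)


def prob_to_rate(prob: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_prob`: ``r = -ln(1 - P) / t``."""
    if not 0 <= prob < 1:
        raise ValueError("prob must lie in [0, 1)")
    return -math.log1p(-prob) / t


def adjust_baseline_rate(r0: float, hr_age: float, delta_age: float,
                         rr: float, delta_ldl: float) -> float:
    """Calibrate a baseline event rate to the modelled cohort.

    ``ra = r0 * hr_age**delta_age * rr**delta_ldl`` where ``delta_age`` and
    ``delta_ldl`` are the age and LDL-C differences between the modelled
    cohort and the cohort the rate was observed in. Identity when both
    deltas are zero.
    """
    if r0 < 0:
        raise ValueError("r0 must be non-negative")
    if hr_age <= 0 or rr <= 0:
        raise ValueError("hr_age and rr must be positive")
    return r0 * hr_age ** delta_age * rr ** delta_ldl


def treated_rate(r0: float, rr: float, delta_ldl: float) -> float:
    """Event rate on treatment: ``r0 * rr**delta_ldl``.

    ``rr`` is the rate ratio per 1 mmol/L LDL-C reduction and ``delta_ldl``
    the regimen's absolute reduction; equals ``r0`` for the comparator arm
    (``delta_ldl = 0``).
    """
    if r0 < 0:
        raise ValueError("r0 must be non-negative")
    if not 0 < rr <= 1:
        raise ValueError("rr must lie in (0, 1]")
    if delta_ldl < 0:
        raise ValueError("delta_ldl must be non-negative")
    return r0 * rr ** delta_ldl


def mortality_rates(life_table: LifeTable, age: float, delta_ldl: float,
                    effects: EffectPerMmol, post_event_year1: bool,
                    multipliers: RiskMultipliers) -> tuple[float, float]:
    """Background (CV, non-CV) death rates at ``age`` for a treated cohort.

    The CV rate is scaled by the vascular-death rate ratio per mmol/L of
    LDL-C lowering, and by the post-event CV-death relative risk during the
    first year after an event. Non-CV mortality (all-cause minus CV) is
    treatment-invariant.
    """
    cv = life_table.cv(age) * effects.rr_vascular_death ** delta_ldl
    if post_event_year1:
        cv *= multipliers.cv_death_post_event
    non_cv = life_table.all_cause(age) - life_table.cv(age)
    return cv, non_cv


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 11x11 one-cycle transition matrix."""

    cycle_index: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}")
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition-matrix rows must sum to 1")


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over cycles plus the revascularization overlay.

    ``occupancy`` has ``n_cycles + 1`` rows (row 0 is the initial cohort);
    ``revasc_events[k]`` is the expected number of revascularizations per
    person during cycle ``k``.
    """

    occupancy: np.ndarray
    revasc_events: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        rv = np.asarray(self.revasc_events, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "revasc_events", rv)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"occupancy must have {N_STATES} columns")
        if rv.shape != (occ.shape[0] - 1,):
            raise ValueError("revasc_events must have one entry per cycle")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("occupancy rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self, start_age: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in S])
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["revasc_events"] = np.append(self.revasc_events, np.nan)
        if start_age is not None:
            df["age"] = start_age + df["cycle"]
        return df


# ---------------------------------------------------------------------------
# per-regimen rate structure (cycle-invariant parts)

def _adjusted_baseline(params: ParameterSet, rr: float, r0: float) -> float:
    adj = params.age_adjustment
    return adjust_baseline_rate(
        r0, adj.hr_age_per_year,
        params.settings.start_age - adj.reference_age,
        rr, params.settings.baseline_ldl - adj.reference_ldl)


def _event_structure(params: ParameterSet, regimen: RegimenSpec):
    """Per-state MI/IS rates (treated, history-adjusted) and destinations."""
    eff, mult = params.effects, params.multipliers
    dldl = regimen.ldl_reduction_mean

    # population calibration (identity at the default zero deltas), then the
    # regimen's proportional risk reduction
    r_mi0 = _adjusted_baseline(params, eff.rr_any_major_vascular,
                               params.baseline_rates.nonfatal_mi)
    r_is0 = _adjusted_baseline(params, eff.rr_any_major_vascular,
                               params.baseline_rates.nonfatal_stroke)
    r_rv0 = _adjusted_baseline(params, eff.rr_any_major_vascular,
                               params.baseline_rates.revascularization)
    r_mi = treated_rate(r_mi0, eff.rr_mi, dldl)
    r_is = treated_rate(r_is0, eff.rr_stroke, dldl)
    r_rv = treated_rate(r_rv0, eff.rr_revasc, dldl)

    recent = mult.any_cv_event_past_year  # any CV event in the past year
    mi_mult = np.zeros(N_STATES)
    is_mult = np.zeros(N_STATES)
    mi_mult[[S.NO_CVD, S.POST_IS, S.POST_IS2]] = 1.0
    mi_mult[S.POST_MI] = mult.recurrent_mi
    mi_mult[S.POST_MI2] = mult.mi_2plus
    mi_mult[S.MI_Y1] = mult.recurrent_mi * recent
    mi_mult[S.MI2_Y1] = mult.mi_2plus * recent
    mi_mult[[S.IS_Y1, S.IS2_Y1]] = recent
    is_mult[[S.NO_CVD, S.POST_MI, S.POST_MI2]] = 1.0
    is_mult[S.POST_IS] = mult.recurrent_stroke
    is_mult[S.POST_IS2] = mult.stroke_2plus
    is_mult[S.IS_Y1] = mult.recurrent_stroke * recent
    is_mult[S.IS2_Y1] = mult.stroke_2plus * recent
    is_mult[[S.MI_Y1, S.MI2_Y1]] = recent

    # destinations: recurrences count per event type; a first event of the
    # other type enters that type's first-year tunnel
    mi_dest = np.full(N_STATES, -1, dtype=int)
    is_dest = np.full(N_STATES, -1, dtype=int)
    for s in ALIVE:
        mi_dest[s] = S.MI2_Y1 if s in MI_PATHWAY else S.MI_Y1
        is_dest[s] = S.IS2_Y1 if s in IS_PATHWAY else S.IS_Y1

    return r_mi * mi_mult, r_is * is_mult, r_rv, mi_dest, is_dest


def _matrix(params: ParameterSet, regimen: RegimenSpec, cycle: int,
            structure) -> np.ndarray:
    mi_rates, is_rates, _, mi_dest, is_dest = structure
    settings = params.settings
    age = settings.start_age + cycle * settings.cycle_length
    t = settings.cycle_length
    dldl = regimen.ldl_reduction_mean

    P = np.zeros((N_STATES, N_STATES))
    for s in ABSORBING:
        P[s, s] = 1.0

    for s in ALIVE:
        cv, non_cv = mortality_rates(params.life_table, age, dldl,
                                     params.effects, s in TUNNELS,
                                     params.multipliers)
        rates = np.array([mi_rates[s], is_rates[s], cv, non_cv])
        dests = np.array([mi_dest[s], is_dest[s], S.CV_DEATH, S.NON_CV_DEATH])
        total = rates.sum()
        exit_p = rate_to_prob(total, t)
        if exit_p > 0:
            np.add.at(P[s], dests, rates / total * exit_p)
        stay = S(TUNNEL_EXIT.get(S(s), S(s)))
        P[s, stay] += 1.0 - exit_p
    return P


def build_transition_matrix(params: ParameterSet, regimen: RegimenSpec,
                            cycle: int) -> TransitionMatrix:
    """One-cycle transition matrix for ``regimen`` at model cycle ``cycle``.

    Within each alive state the competing exits (MI, IS, CV death, non-CV
    death) share the joint exit probability proportionally to their rates;
    the residual stays put, or drains tunnel states into their long-term
    post-event states.
    """
    if not 0 <= cycle < params.settings.n_cycles:
        raise ValueError(f"cycle {cycle} outside horizon")
    structure = _event_structure(params, regimen)
    return TransitionMatrix(cycle, _matrix(params, regimen, cycle, structure))


def run_cohort(params: ParameterSet, regimen: RegimenSpec) -> CohortTrace:
    """Propagate the cohort from the no-CVD state over the whole horizon.

    Returns the occupancy trace plus the expected revascularization events
    per cycle (treated revascularization rate applied to start-of-cycle
    alive occupancy).
    """
    settings = params.settings
    if not params.life_table.covers(settings.start_age, settings.horizon):
        logger.warning("life table does not span the full horizon; "
                       "last row is reused for older ages")
    n = settings.n_cycles
    structure = _event_structure(params, regimen)
    rv_prob = rate_to_prob(structure[2], settings.cycle_length)
    alive_idx = np.array([int(s) for s in ALIVE])

    occ = np.zeros((n + 1, N_STATES))
    occ[0, S.NO_CVD] = 1.0
    rv = np.zeros(n)
    for k in range(n):
        P = _matrix(params, regimen, k, structure)
        rv[k] = occ[k, alive_idx].sum() * rv_prob
        occ[k + 1] = occ[k] @ P
    return CohortTrace(occ, rv)
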