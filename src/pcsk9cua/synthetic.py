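"""Synthetic inputs: life tables and test parameter sets.

The national yearbook mortality table behind the base case is not
redistributable, so background mortality is emulated with a Gompertz-Makeham
hazard — an age-independent accident floor plus an exponentially rising
senescent component — with a cardiovascular share of deaths that grows
linearly with age. The generator reproduces the statistical structure the
model relies on (smoothly increasing all-cause mortality, CV fraction below
1 and rising with age) without claiming any particular country's values; a
real table can be substituted through the standard CSV path.

``make_test_parameters`` builds three tiers of parameter sets for testing:
``degenerate`` (no events, constant mortality — analytically solvable),
``simple`` (tiny randomized sets for brute-force oracles and property
sweeps), and ``paper_like`` (the built-in base case).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .lifetable import LifeTable
from .parameters import (AgeAdjustment, BaselineEventRates, CohortSettings,
                         CostInputs, EffectPerMmol, ParameterSet, RegimenSpec,
                         RiskMultipliers, UtilityInputs, base_case)

__all__ = ["LifeTableSpec", "make_life_table", "default_life_table",
           "make_test_parameters"]


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz-Makeham life-table generator settings.

    ``all_cause(age) = makeham + gompertz_a * exp(gompertz_b * age)``;
    the CV fraction of deaths interpolates linearly from
    ``cv_fraction_young`` at the first age to ``cv_fraction_old`` at the
    last. Defaults put the 60-year-old all-cause rate near 0.007/year,
    within the range typical of published East-Asian life tables
    (illustrative, not authoritative).
    """

    makeham: float = 0.001
    gompertz_a: float = 2e-5
    gompertz_b: float = 0.095
    cv_fraction_young: float = 0.20
    cv_fraction_old: float = 0.45
    age_range: tuple[int, int] = (40, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.makeham, self.gompertz_a, self.gompertz_b) < 0:
            raise ValueError("life-table hazard parameters must be >= 0")
        for f in (self.cv_fraction_young, self.cv_fraction_old):
            if not 0 < f < 1:
                raise ValueError("cv fractions must lie in (0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be an increasing pair")


def make_life_table(spec: LifeTableSpec) -> LifeTable:
    """Deterministically generate a life table from a Gompertz-Makeham spec."""
    lo, hi = spec.age_range
    ages = np.arange(lo, hi + 1)
    all_cause = spec.makeham + spec.gompertz_a * np.exp(spec.gompertz_b * ages)
    frac = np.interp(ages, [lo, hi],
                     [spec.cv_fraction_young, spec.cv_fraction_old])
    return LifeTable(ages, all_cause, all_cause * frac)


@functools.lru_cache(maxsize=1)
def default_life_table() -> LifeTable:
    """The synthetic life table used by the built-in base case."""
    return make_life_table(LifeTableSpec())


def _flat_life_table(rate: float, cv_fraction: float,
                     age_range=(40, 100)) -> LifeTable:
    ages = np.arange(age_range[0], age_range[1] + 1)
    all_cause = np.full(len(ages), rate)
    return LifeTable(ages, all_cause, all_cause * cv_fraction)


def make_test_parameters(seed: int = 0,
                         difficulty: str = "simple") -> ParameterSet:
    """Deterministic parameter sets for testing, by difficulty tier.

    ``degenerate``
        Zero event rates and constant background mortality: the trace is a
        pure geometric survival decay and QALYs reduce to a closed-form
        annuity of the baseline utility.
    ``simple``
        Two or three strategies, a 3-cycle horizon, and event rates/prices
        jittered by ``seed`` — small enough for hand/brute-force oracles,
        varied enough for property sweeps.
    ``paper_like``
        The built-in base case (all Table-style inputs) with the synthetic
        life table.
    """
    if difficulty == "paper_like":
        return base_case()

    statins = RegimenSpec(name="Statins alone", agent="Statins",
                          ldl_reduction_mean=0.0)
    if difficulty == "degenerate":
        settings = CohortSettings(start_age=60.0, horizon=30.0)
        return ParameterSet(
            settings=settings,
            baseline_rates=BaselineEventRates(0.0, 0.0, 0.0),
            age_adjustment=AgeAdjustment(reference_age=settings.start_age,
                                         reference_ldl=settings.baseline_ldl),
            multipliers=RiskMultipliers(),
            effects=EffectPerMmol(),
            regimens=(statins,),
            costs=CostInputs(),
            utilities=UtilityInputs(),
            distributions={},
            life_table=_flat_life_table(0.02, 0.3),
        )
    if difficulty != "simple":
        raise ValueError(f"unknown difficulty '{difficulty}'")

    rng = np.random.default_rng(seed)
    u = lambda lo, hi: float(rng.uniform(lo, hi))
    settings = CohortSettings(start_age=u(55.0, 70.0), horizon=3.0,
                              discount_rate_costs=u(0.0, 0.08),
                              discount_rate_outcomes=u(0.0, 0.08))
    arm_a = RegimenSpec(name="Drug A Q2W", agent="DrugA",
                        ldl_reduction_mean=u(0.5, 2.0),
                        price_per_pen=u(10.0, 60.0),
                        pens_per_administration=1,
                        administrations_year1=26, administrations_subsequent=26,
                        is_injectable=True)
    arm_b = RegimenSpec(name="Drug B Q4W", agent="DrugB",
                        ldl_reduction_mean=u(0.5, 2.0),
                        price_per_pen=u(40.0, 200.0),
                        pens_per_administration=2,
                        administrations_year1=u(10.0, 14.0),
                        administrations_subsequent=13,
                        is_injectable=True)
    return ParameterSet(
        settings=settings,
        baseline_rates=BaselineEventRates(
            nonfatal_mi=u(0.0, 0.08), nonfatal_stroke=u(0.0, 0.05),
            revascularization=u(0.0, 0.05)),
        age_adjustment=AgeAdjustment(reference_age=settings.start_age,
                                     reference_ldl=settings.baseline_ldl),
        multipliers=RiskMultipliers(
            recurrent_mi=u(1.0, 1.5), recurrent_stroke=u(1.0, 1.5),
            any_cv_event_past_year=u(1.0, 2.0), mi_2plus=u(1.0, 1.6),
            stroke_2plus=u(1.0, 2.0), cv_death_post_event=u(1.0, 1.6)),
        effects=EffectPerMmol(
            rr_mi=u(0.6, 0.95), rr_stroke=u(0.6, 0.95),
            rr_revasc=u(0.6, 0.95), rr_vascular_death=u(0.7, 0.95),
            rr_any_death=u(0.8, 0.99), rr_any_major_vascular=u(0.7, 0.95)),
        regimens=(statins, arm_a, arm_b),
        costs=CostInputs(
            statin_annual=u(500.0, 1200.0), mi_year1=u(2000.0, 5000.0),
            mi_subsequent_annual=u(1000.0, 2500.0),
            is_year1=u(1000.0, 2000.0), is_subsequent_annual=u(800.0, 1500.0),
            revascularization=u(8000.0, 20000.0), cv_death=u(1500.0, 3500.0)),
        utilities=UtilityInputs(),
        distributions={},
        life_table=_flat_life_table(u(0.005, 0.04), u(0.2, 0.5)),
    )
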