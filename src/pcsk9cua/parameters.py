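"""Model inputs: typed parameter containers, config I/O, and PSA sampling.

The parameter set bundles everything the Markov engine and the economic
layer need for one analysis: cohort settings, baseline cardiovascular event
rates, post-event risk multipliers, LDL-C effect translations, regimen
definitions (dose schedule and per-pen price), costs, utilities, the
uncertainty registry (distribution family + 95% range per sampled
parameter), and the background-mortality life table.

Conventions
-----------
* Event rates are stored per person-year; the config file lists them per
  100 patient-years (the usual reporting unit) and the loader divides by 100.
* Monetary values are 2024 USD; utilities are on the 0-1 EQ-5D scale;
  disutilities are negative decrements.
* Distribution registry keys are dotted paths (``costs.mi_year1``,
  ``ldl_reduction.<regimen name>``, ``price_per_pen.<agent>``) resolved by
  :meth:`ParameterSet.replace_value`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import yaml

from .lifetable import LifeTable, read_life_table

__all__ = [
    "CohortSettings", "BaselineEventRates", "AgeAdjustment",
    "RiskMultipliers", "EffectPerMmol", "RegimenSpec", "CostInputs",
    "UtilityInputs", "ParameterDistribution", "ParameterSet",
    "load_parameters", "write_parameters", "base_case", "sample_parameters",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CohortSettings:
    """Cohort, horizon, discounting and willingness-to-pay settings."""

    start_age: float = 60.6
    baseline_ldl: float = 3.13
    cycle_length: float = 1.0
    horizon: float = 30.0
    discount_rate_costs: float = 0.05
    discount_rate_outcomes: float = 0.05
    half_cycle_correction: bool = True
    wtp_low: float = 13291.7
    wtp_high: float = 39875.0

    def __post_init__(self) -> None:
        _require(self.start_age > 0, "settings.start_age must be positive")
        _require(0 < self.cycle_length <= self.horizon,
                 "settings.cycle_length must satisfy 0 < cycle_length <= horizon")
        for f in ("discount_rate_costs", "discount_rate_outcomes"):
            _require(0 <= getattr(self, f) <= 1,
                     f"settings.{f} must lie in [0, 1]")
        _require(self.wtp_low <= self.wtp_high,
                 "settings.wtp_low must not exceed settings.wtp_high")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))


@dataclass(frozen=True)
class BaselineEventRates:
    """First-event rates per person-year in the statin-treated reference cohort."""

    nonfatal_mi: float = 0.009
    nonfatal_stroke: float = 0.004
    revascularization: float = 0.012

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) >= 0,
                     f"baseline_rates.{f.name} must be non-negative")


@dataclass(frozen=True)
class AgeAdjustment:
    """Baseline-rate calibration from the source cohort to the target cohort.

    ``hr_age_per_year`` scales event rates per year of age difference between
    the modelled cohort and the cohort the baseline rates came from;
    ``reference_ldl`` plays the same role for the LDL-C difference. With the
    defaults both deltas are zero and the adjustment is the identity.
    """

    hr_age_per_year: float = 1.0
    reference_age: float = 60.6
    reference_ldl: float = 3.13

    def __post_init__(self) -> None:
        _require(self.hr_age_per_year > 0,
                 "age_adjustment.hr_age_per_year must be positive")


@dataclass(frozen=True)
class RiskMultipliers:
    """Hazard ratios applied after prior events, plus the post-event CV-death RR."""

    recurrent_mi: float = 1.13
    recurrent_stroke: float = 1.13
    any_cv_event_past_year: float = 1.50
    mi_2plus: float = 1.19
    stroke_2plus: float = 1.36
    cv_death_post_event: float = 1.31

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) > 0,
                     f"multipliers.{f.name} must be positive")


@dataclass(frozen=True)
class EffectPerMmol:
    """Rate ratios per 1 mmol/L LDL-C reduction (the effect-translation anchor)."""

    rr_mi: float = 0.74
    rr_stroke: float = 0.80
    rr_revasc: float = 0.76
    rr_vascular_death: float = 0.86
    rr_any_death: float = 0.90
    rr_any_major_vascular: float = 0.78

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            _require(0 < v <= 1, f"effects.{f.name} must lie in (0, 1]")


@dataclass(frozen=True)
class RegimenSpec:
    """One treatment strategy: LDL-C effect, dosing schedule, per-pen price.

    The statins-alone comparator is a regimen with zero LDL-C reduction and
    zero PCSK9 drug cost, so a single code path serves every arm.
    """

    name: str
    agent: str
    ldl_reduction_mean: float
    ldl_reduction_ci: tuple[float, float] = (0.0, 0.0)
    price_per_pen: float = 0.0
    pens_per_administration: float = 0.0
    administrations_year1: float = 0.0
    administrations_subsequent: float = 0.0
    is_injectable: bool = False

    def __post_init__(self) -> None:
        _require(self.ldl_reduction_mean >= 0,
                 f"regimen '{self.name}': ldl_reduction_mean must be >= 0")
        _require(self.price_per_pen >= 0,
                 f"regimen '{self.name}': price_per_pen must be >= 0")
        if self.is_injectable:
            _require(self.administrations_year1 > 0
                     and self.administrations_subsequent > 0,
                     f"regimen '{self.name}': administration counts must be "
                     "positive for active regimens")

    def administrations(self, cycle: int) -> float:
        """Administrations in model year ``cycle`` (0-based; year 1 may load)."""
        return (self.administrations_year1 if cycle == 0
                else self.administrations_subsequent)

    def annual_drug_cost(self, cycle: int) -> float:
        """PCSK9 drug cost per fully-adherent person-year in ``cycle``."""
        return (self.price_per_pen * self.pens_per_administration
                * self.administrations(cycle))


@dataclass(frozen=True)
class CostInputs:
    """Direct medical costs (USD): background statin, event and state costs."""

    statin_annual: float = 846.1
    mi_year1: float = 3275.0
    mi_subsequent_annual: float = 1893.9
    is_year1: float = 1390.4
    is_subsequent_annual: float = 1141.1
    revascularization: float = 16543.2
    cv_death: float = 2332.7
    non_cv_death: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) >= 0,
                     f"costs.{f.name} must be non-negative")


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and one-off/annual disutilities."""

    baseline: float = 0.964
    mi_year1: float = 0.866
    mi_post: float = 0.950
    mi2_year1: float = 0.819
    mi2_post: float = 0.940
    is_year1: float = 0.510
    is_post: float = 0.750
    is2_year1: float = 0.340
    is2_post: float = 0.420
    disutility_injection: float = -0.0003
    disutility_revasc: float = -0.007

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("disutility_"):
                _require(v <= 0, f"utilities.{f.name} must be <= 0")
            else:
                _require(0 <= v <= 1,
                         f"utilities.{f.name} must lie in [0, 1]")


Family = Literal["gamma", "lognormal", "normal", "beta", "fixed"]


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty description of one parameter: family, base value, 95% range.

    Distributions are parameterized by method of moments: the mean is the
    base value and the standard deviation is ``(high - low) / (2 * 1.96)``,
    except the lognormal, whose median is fixed at the base value with
    ``sigma = (ln high - ln low) / (2 * 1.96)``. Negative-valued parameters
    (disutilities) with a gamma family are sampled on the magnitude and
    negated.
    """

    family: Family
    mean: float
    range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        lo, hi = self.range
        _require(lo <= hi, "distribution range must be ordered (low, high)")
        if self.family != "fixed":
            _require(lo <= self.mean <= hi or lo == hi,
                     "distribution base value must lie inside its range")

    @property
    def sd(self) -> float:
        lo, hi = self.range
        return (hi - lo) / (2 * 1.96)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution (scalar by default, vector with ``size``)."""
        if self.family == "fixed" or self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size=size)
        if self.family == "lognormal":
            lo, hi = self.range
            _require(lo > 0 and self.mean > 0,
                     "lognormal requires a positive base value and range")
            sigma = (math.log(hi) - math.log(lo)) / (2 * 1.96)
            return rng.lognormal(math.log(self.mean), sigma, size=size)
        if self.family == "gamma":
            sign = -1.0 if self.mean < 0 else 1.0
            m, sd = abs(self.mean), self.sd
            var = sd * sd
            shape, scale = m * m / var, var / m
            return sign * rng.gamma(shape, scale, size=size)
        if self.family == "beta":
            m, var = self.mean, self.sd ** 2
            _require(0 < m < 1, "beta requires a base value in (0, 1)")
            _require(var < m * (1 - m),
                     "beta moment fit infeasible: variance too large for mean")
            nu = m * (1 - m) / var - 1
            return rng.beta(m * nu, (1 - m) * nu, size=size)
        raise ValueError(f"unknown distribution family '{self.family}'")


_SECTIONS = ("settings", "baseline_rates", "age_adjustment", "multipliers",
             "effects", "costs", "utilities")


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated input set for one model run."""

    settings: CohortSettings
    baseline_rates: BaselineEventRates
    age_adjustment: AgeAdjustment
    multipliers: RiskMultipliers
    effects: EffectPerMmol
    regimens: tuple[RegimenSpec, ...]
    costs: CostInputs
    utilities: UtilityInputs
    distributions: Mapping[str, ParameterDistribution]
    life_table: LifeTable

    def __post_init__(self) -> None:
        names = [r.name for r in self.regimens]
        _require(len(names) == len(set(names)), "regimen names must be unique")
        object.__setattr__(self, "regimens", tuple(self.regimens))
        object.__setattr__(self, "distributions", dict(self.distributions))
        for key in self.distributions:
            self._resolve(key)  # raises on dangling registry entries

    def regimen(self, name: str) -> RegimenSpec:
        for r in self.regimens:
            if r.name == name:
                return r
        raise KeyError(f"unknown regimen '{name}'")

    @property
    def active_regimens(self) -> tuple[RegimenSpec, ...]:
        return tuple(r for r in self.regimens if r.is_injectable)

    @property
    def comparator(self) -> RegimenSpec:
        """The (unique) non-injectable arm — statins alone."""
        inactive = [r for r in self.regimens if not r.is_injectable]
        _require(len(inactive) == 1,
                 "parameter set must contain exactly one comparator arm")
        return inactive[0]

    # -- dotted-path access ------------------------------------------------

    def _resolve(self, path: str) -> float:
        section, _, fieldname = path.partition(".")
        if section in _SECTIONS:
            if path == "settings.discount_rate":
                return self.settings.discount_rate_costs
            try:
                return getattr(getattr(self, section), fieldname)
            except AttributeError:
                raise KeyError(f"unknown parameter '{path}'") from None
        if section == "ldl_reduction":
            return self.regimen(fieldname).ldl_reduction_mean
        if section == "price_per_pen":
            for r in self.regimens:
                if r.agent == fieldname:
                    return r.price_per_pen
            raise KeyError(f"unknown agent '{fieldname}' in '{path}'")
        raise KeyError(f"unknown parameter '{path}'")

    def value(self, path: str) -> float:
        """Current value of the parameter addressed by a dotted path."""
        return self._resolve(path)

    def replace_value(self, path: str, value: float) -> "ParameterSet":
        """Return a copy with one parameter replaced (validates on construction).

        ``settings.discount_rate`` is a joint alias setting both the cost and
        outcome discount rates at once.
        """
        section, _, fieldname = path.partition(".")
        if path == "settings.discount_rate":
            new = replace(self.settings, discount_rate_costs=value,
                          discount_rate_outcomes=value)
            return replace(self, settings=new)
        if section in _SECTIONS:
            self._resolve(path)
            attr = {"age_adjustment": "age_adjustment"}.get(section, section)
            return replace(self, **{attr: replace(getattr(self, attr),
                                                  **{fieldname: value})})
        if section == "ldl_reduction":
            self.regimen(fieldname)
            regs = tuple(replace(r, ldl_reduction_mean=value)
                         if r.name == fieldname else r for r in self.regimens)
            return replace(self, regimens=regs)
        if section == "price_per_pen":
            self._resolve(path)
            regs = tuple(replace(r, price_per_pen=value)
                         if r.agent == fieldname else r for r in self.regimens)
            return replace(self, regimens=regs)
        raise KeyError(f"unknown parameter '{path}'")


# ---------------------------------------------------------------------------
# config I/O

def _dist_from_dict(name: str, mean: float, d: dict) -> ParameterDistribution:
    try:
        return ParameterDistribution(family=d["family"], mean=mean,
                                     range=tuple(float(x) for x in d["range"]))
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"distribution entry '{name}': {exc}") from exc


def _build(doc: dict, life_table: LifeTable) -> ParameterSet:
    def section(cls, key):
        raw = doc.get(key, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{key}: unknown fields {sorted(unknown)}")
        return cls(**raw)

    settings = section(CohortSettings, "settings")
    rates_raw = doc.get("baseline_rates", {}) or {}
    # config lists rates per 100 patient-years; the model uses per person-year
    rates = BaselineEventRates(**{k: v / 100.0 for k, v in rates_raw.items()})
    age_adj = section(AgeAdjustment, "age_adjustment")
    multipliers = section(RiskMultipliers, "multipliers")
    effects = section(EffectPerMmol, "effects")
    costs = section(CostInputs, "costs")
    utilities = section(UtilityInputs, "utilities")
    regimens = tuple(
        RegimenSpec(**{**r, "ldl_reduction_ci":
                       tuple(r.get("ldl_reduction_ci", (0.0, 0.0)))})
        for r in doc.get("regimens", []))

    partial = ParameterSet(settings, rates, age_adj, multipliers, effects,
                           regimens, costs, utilities, {}, life_table)
    dists = {
        name: _dist_from_dict(name, partial.value(name), spec)
        for name, spec in (doc.get("distributions", {}) or {}).items()
    }
    return replace(partial, distributions=dists)


def load_parameters(path) -> ParameterSet:
    """Load and validate a parameter config (YAML) into a :class:`ParameterSet`.

    The optional ``life_table`` key names a CSV (columns age, all_cause_rate,
    cv_rate; rates per person-year) resolved relative to the config file; if
    null or absent, the built-in synthetic life table is used.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse parameter file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"parameter file {path} is not a mapping")
    lt_ref = doc.get("life_table")
    if lt_ref:
        life_table = read_life_table((path.parent / lt_ref).resolve())
    else:
        from .synthetic import default_life_table
        life_table = default_life_table()
    return _build(doc, life_table)


def write_parameters(params: ParameterSet, path, life_table_csv=None) -> None:
    """Write a parameter set back to YAML (plus a life-table CSV alongside).

    Together with :func:`load_parameters` this round-trips every value
    bit-identically.
    """
    path = Path(path)
    if life_table_csv is None:
        life_table_csv = path.with_suffix("").name + "_life_table.csv"
    params.life_table.to_csv(path.parent / life_table_csv)

    def as_dict(obj):
        return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}

    doc = {
        "settings": as_dict(params.settings),
        "baseline_rates": {k: v * 100.0
                           for k, v in as_dict(params.baseline_rates).items()},
        "age_adjustment": as_dict(params.age_adjustment),
        "multipliers": as_dict(params.multipliers),
        "effects": as_dict(params.effects),
        "costs": as_dict(params.costs),
        "utilities": as_dict(params.utilities),
        "regimens": [{**as_dict(r),
                      "ldl_reduction_ci": list(r.ldl_reduction_ci)}
                     for r in params.regimens],
        "distributions": {name: {"family": d.family, "range": list(d.range)}
                          for name, d in params.distributions.items()},
        "life_table": str(life_table_csv),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def base_case(life_table: LifeTable | None = None) -> ParameterSet:
    """The built-in base-case parameter set (packaged config file).

    By default the synthetic Gompertz-Makeham life table stands in for the
    national yearbook mortality table; pass ``life_table`` to substitute a
    real one loaded via :func:`~pcsk9cua.lifetable.read_life_table`.
    """
    with resources.as_file(
            resources.files("pcsk9cua.data") / "base_case.yaml") as p:
        params = load_parameters(p)
    if life_table is not None:
        params = replace(params, life_table=life_table)
    return params


def sample_parameters(base: ParameterSet, seed: int) -> ParameterSet:
    """One joint probabilistic draw of every non-fixed parameter.

    Parameters are drawn independently from their registered families
    (method-of-moments fits around the base value and 95% range), in sorted
    registry order so a given seed always yields the same draw. Draws that
    would leave the type invariants (LDL-C reduction >= 0, rate ratios <= 1)
    are truncated at the boundary; under the registered ranges this has
    negligible probability.
    """
    rng = np.random.default_rng(seed)
    out = base
    for name in sorted(base.distributions):
        dist = base.distributions[name]
        if dist.family == "fixed":
            continue
        try:
            value = float(dist.sample(rng))
        except ValueError as exc:
            raise ValueError(f"sampling '{name}': {exc}") from exc
        if name.startswith("ldl_reduction."):
            value = max(value, 0.0)
        if name.startswith("effects."):
            value = min(value, 1.0)
        out = out.replace_value(name, value)
    return out
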