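"""Domain types and parameter bundle for the screening cost-effectiveness model.

Every quantity the model consumes lives here as a small validated type:
the diagnostic test, the screening cascade, age/sex-stratified fracture
incidence and relative risks, post-fracture mortality, drug profiles with
persistence and effect waning, costs, utilities, prevalence, and the
economic settings (discounting, horizon, willingness-to-pay).

Validation is data, not exceptions: :func:`validate` returns a list of
human-readable violations, and :func:`~osteoscreen.config.load_config`
refuses to hand out a bundle that does not validate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Sex",
    "FractureSite",
    "AgeBand",
    "AGE_BANDS",
    "HORIZON_AGE",
    "ScreeningTest",
    "CascadeParams",
    "IncidenceTable",
    "TscoreRiskTable",
    "SubsequentFractureModel",
    "LifeTable",
    "PostFractureMortality",
    "DrugProfile",
    "TreatmentMix",
    "CostParams",
    "UtilityParams",
    "PrevalenceSpec",
    "EconSettings",
    "ModelParams",
    "rate_to_prob",
    "baseline_utility",
    "discount_factor",
    "validate",
]


class Sex(IntEnum):
    """Biological sex as modelled (two strata throughout)."""

    FEMALE = 0
    MALE = 1


class FractureSite(IntEnum):
    """Modelled fracture sites, ordered by clinical severity (hip worst).

    ``NHNV`` (non-hip non-vertebral) aggregates proximal humerus, distal
    wrist and pelvis.
    """

    HIP = 0
    VERTEBRAL = 1
    NHNV = 2


HORIZON_AGE = 105


@dataclass(frozen=True)
class AgeBand:
    """Half-open age interval [lower, upper) in whole years."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"age band requires lower < upper, got [{self.lower}, {self.upper})")

    def __contains__(self, age: float) -> bool:
        return self.lower <= age < self.upper

    def label(self) -> str:
        if self.upper >= HORIZON_AGE:
            return f"{self.lower}+"
        return f"{self.lower}-{self.upper - 1}"


#: Incidence / relative-risk bands: 10-year bands with an open-ended 80+.
AGE_BANDS: tuple[AgeBand, ...] = (
    AgeBand(50, 60),
    AgeBand(60, 70),
    AgeBand(70, 80),
    AgeBand(80, HORIZON_AGE),
)

#: Coarser bands used by age-specific prevalence (50-59, 60-69, 70+).
PREVALENCE_BANDS: tuple[AgeBand, ...] = (
    AgeBand(50, 60),
    AgeBand(60, 70),
    AgeBand(70, HORIZON_AGE),
)


def band_index(age: float, bands: Sequence[AgeBand] = AGE_BANDS) -> int:
    for i, b in enumerate(bands):
        if age in b:
            return i
    raise ValueError(f"age {age} outside modelled range [50, {HORIZON_AGE})")


@dataclass(frozen=True)
class ScreeningTest:
    """Diagnostic performance and unit cost of the AI radiograph read."""

    sensitivity: float
    specificity: float
    unit_cost: float  # KRW per screened person


@dataclass(frozen=True)
class CascadeParams:
    """Care-cascade probabilities downstream of a positive AI flag."""

    p_dxa_uptake: float  # flagged -> DXA confirmation attendance
    p_treat_init: float  # DXA-confirmed -> starts pharmacotherapy
    dxa_cost: float  # KRW per confirmatory DXA


@dataclass(frozen=True)
class IncidenceTable:
    """Annual fracture incidence rates (events/person-year) by sex, site, age band.

    ``values[sex, site, band]``; bands follow :data:`AGE_BANDS`.
    """

    values: np.ndarray  # shape (2, 3, len(AGE_BANDS))
    bands: tuple[AgeBand, ...] = AGE_BANDS

    def rate(self, sex: Sex, site: FractureSite, age: float) -> float:
        return float(self.values[sex, site, band_index(age, self.bands)])


@dataclass(frozen=True)
class TscoreRiskTable:
    """Relative fracture risk for BMD T-score <= -2.5 vs the general population."""

    values: np.ndarray  # shape (2, 3, len(AGE_BANDS))
    bands: tuple[AgeBand, ...] = AGE_BANDS

    def rr(self, sex: Sex, site: FractureSite, age: float) -> float:
        return float(self.values[sex, site, band_index(age, self.bands)])


@dataclass(frozen=True)
class SubsequentFractureModel:
    """Relative risk of a further fracture given fracture history.

    Piecewise-constant in time since the last fracture, with an additive
    premium per prior fracture beyond the first and an overall cap.
    ``multiplier(t, 0) == 1`` always: no history, no excess.
    """

    recent_rr: float = 2.0  # years_since_last <= recent_years
    mid_rr: float = 1.5  # recent_years < t <= mid_years
    late_rr: float = 1.2  # t > mid_years
    recent_years: int = 2
    mid_years: int = 5
    per_extra_fracture: float = 0.2
    cap: float = 4.0
    source: str = "synthetic stand-in"

    def multiplier(self, years_since_last: float, n_prior: int) -> float:
        if n_prior <= 0:
            return 1.0
        if years_since_last <= self.recent_years:
            base = self.recent_rr
        elif years_since_last <= self.mid_years:
            base = self.mid_rr
        else:
            base = self.late_rr
        return float(min(self.cap, base + self.per_extra_fracture * (n_prior - 1)))

    def multiplier_vec(self, years_since_last: np.ndarray, n_prior: np.ndarray) -> np.ndarray:
        base = np.select(
            [years_since_last <= self.recent_years, years_since_last <= self.mid_years],
            [self.recent_rr, self.mid_rr],
            default=self.late_rr,
        )
        out = np.minimum(self.cap, base + self.per_extra_fracture * np.maximum(n_prior - 1, 0))
        return np.where(n_prior <= 0, 1.0, out)


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx for integer ages ``start_age .. HORIZON_AGE``.

    ``qx[age - start_age]``; the entry at the horizon age is forced to 1.
    """

    sex: Sex
    qx: np.ndarray
    start_age: int = 50
    source: str = "synthetic stand-in"

    def q(self, age: int) -> float:
        return float(self.qx[int(age) - self.start_age])

    def life_expectancy(self, from_age: int = 50) -> float:
        """Expected further years of life, crediting half a year in the year of death."""
        q = self.qx[int(from_age) - self.start_age : HORIZON_AGE - self.start_age]
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])[:-1]
        return float(np.sum(surv * (1.0 - 0.5 * q)))


@dataclass(frozen=True)
class PostFractureMortality:
    """Excess mortality after hip and vertebral fractures.

    First post-fracture year: an additive excess death probability by sex and
    site. Later years: a hazard ratio on background qx that decays linearly
    back to 1 over ``longterm_decay_years``. Both contributions are scaled by
    the ``attribution`` fraction — the share of post-fracture deaths causally
    ascribed to the fracture itself. NHNV fractures carry no excess.
    """

    first_year_excess: np.ndarray  # shape (2 sexes, 2 sites: hip, vertebral)
    longterm_hr0: float = 1.8
    longterm_decay_years: float = 10.0
    attribution: float = 0.25
    source: str = "synthetic stand-in"

    def longterm_excess_rr(self, sex: Sex, years_since_fracture: float) -> float:
        if self.longterm_decay_years <= 0:
            return 1.0
        frac = max(0.0, 1.0 - years_since_fracture / self.longterm_decay_years)
        return float(1.0 + (self.longterm_hr0 - 1.0) * frac)

    def longterm_excess_rr_vec(self, years_since: np.ndarray) -> np.ndarray:
        if self.longterm_decay_years <= 0:
            return np.ones_like(years_since, dtype=float)
        frac = np.clip(1.0 - years_since / self.longterm_decay_years, 0.0, 1.0)
        return 1.0 + (self.longterm_hr0 - 1.0) * frac


class WaningKind(IntEnum):
    """How residual drug effect declines after discontinuation."""

    LINEAR_OVER_TREATMENT_DURATION = 0
    LINEAR_OVER_ONE_YEAR = 1
    STEP_AT_ONE_YEAR = 2


@dataclass(frozen=True)
class DrugProfile:
    """One anti-osteoporotic drug: efficacy, cost, persistence, monitoring, AEs."""

    name: str
    rr: np.ndarray  # per-site relative risk on treatment, shape (3,)
    annual_cost: float  # KRW per treated year
    persistence: np.ndarray  # proportion still on drug at end of years 1..5
    waning: WaningKind
    physician_visits_per_year: float = 0.0
    pharmacy_visits_per_year: float = 0.0
    dxa_per_year: float = 0.0
    ae_gp_visits_first_6mo: float = 0.0
    ae_gp_visits_per_subsequent_6mo: float = 0.0
    ae_ppi_cost_per_episode: float = 0.0

    def discontinuation_hazard(self, year: int) -> float:
        """Conditional probability of stopping at the end of treatment year ``year``.

        ``1 - S(k)/S(k-1)`` with ``S(0) = 1``; zero beyond the table.
        """
        s = np.concatenate([[1.0], self.persistence])
        if year < 1 or year >= len(s):
            return 0.0
        if s[year - 1] <= 0:
            return 1.0
        return float(1.0 - s[year] / s[year - 1])


@dataclass(frozen=True)
class TreatmentMix:
    """Drug shares at initiation and the maximum treatment duration."""

    shares: dict[str, float]
    max_duration_years: int = 5


@dataclass(frozen=True)
class CostParams:
    """Direct medical costs (KRW 2025), healthcare-payer perspective."""

    fracture_first_year: np.ndarray  # shape (2 sexes, 3 sites)
    male_uplift: float = 1.13  # provenance only: male costs already pre-applied
    nursing_home_prob_after_hip: float = 0.10
    nursing_home_daily_cost: float = 8103.0
    physician_visit_cost: float = 17942.0
    pharmacy_visit_cost: float = 8748.0
    dxa_cost: float = 50000.0


@dataclass(frozen=True)
class UtilityParams:
    """Age-dependent baseline utility plus post-fracture multipliers.

    ``post_fracture_multiplier[site, phase]`` with phase 0 = first year after
    the event, phase 1 = every later year. Optional 95% CIs (same shape plus a
    trailing low/high axis) feed the probabilistic sensitivity analysis.
    """

    baseline_knots: dict[int, float]
    post_fracture_multiplier: np.ndarray  # shape (3, 2)
    multiplier_ci: Optional[np.ndarray] = None  # shape (3, 2, 2): (lo, hi)


@dataclass(frozen=True)
class PrevalenceSpec:
    """Osteoporosis prevalence: one overall figure per sex, or by age band."""

    mode: str  # "fixed" | "age_specific"
    fixed: dict[Sex, float]
    age_specific: dict[Sex, tuple[float, float, float]]  # bands: PREVALENCE_BANDS

    def prob(self, sex: Sex, age: float) -> float:
        if self.mode == "fixed":
            return self.fixed[Sex(sex)]
        return self.age_specific[Sex(sex)][band_index(age, PREVALENCE_BANDS)]


@dataclass(frozen=True)
class EconSettings:
    discount_rate: float = 0.045
    horizon_age: int = HORIZON_AGE
    cycle_length: float = 1.0
    wtp_thresholds: tuple[float, ...] = (30_000_000.0, 50_000_000.0)


@dataclass(frozen=True)
class PopulationSpec:
    """Roster generation: sex shares and 5-year age-band weights."""

    sex_shares: dict[Sex, float]
    age_band_weights: dict[int, float]  # keyed by band lower edge (50, 55, ... 100)
    source: str = "synthetic stand-in"


@dataclass(frozen=True)
class ModelParams:
    """The full, validated parameter bundle consumed by every module."""

    test: ScreeningTest
    cascade: CascadeParams
    incidence: IncidenceTable
    tscore_rr: TscoreRiskTable
    subsequent: SubsequentFractureModel
    life_tables: dict[Sex, LifeTable]
    post_fracture_mortality: PostFractureMortality
    drugs: dict[str, DrugProfile]
    mix: TreatmentMix
    costs: CostParams
    utilities: UtilityParams
    prevalence: PrevalenceSpec
    econ: EconSettings
    population: PopulationSpec
    standins: tuple[str, ...] = ()

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# scalar utilities

def rate_to_prob(rate: float, dt: float = 1.0) -> float:
    """Convert an event rate (events/person-year) to a probability over ``dt`` years.

    Assumes a constant hazard within the interval: ``1 - exp(-rate * dt)``.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return -math.expm1(-rate * dt)


def baseline_utility(age: float, utilities: UtilityParams) -> float:
    """Baseline (pre-fracture) utility at ``age``.

    Linear interpolation between the tabulated knots; the value at the last
    knot is held constant for older ages.
    """
    knots = sorted(utilities.baseline_knots.items())
    ages = np.array([a for a, _ in knots], dtype=float)
    vals = np.array([v for _, v in knots], dtype=float)
    if age < ages[0]:
        raise ValueError(f"age {age} below first utility knot {ages[0]:.0f}")
    return float(np.interp(age, ages, vals))


def baseline_utility_by_age(utilities: UtilityParams, start_age: int = 50,
                            horizon_age: int = HORIZON_AGE) -> np.ndarray:
    """Baseline utility tabulated at integer ages ``start_age .. horizon_age``."""
    ages = np.arange(start_age, horizon_age + 1, dtype=float)
    knots = sorted(utilities.baseline_knots.items())
    xs = np.array([a for a, _ in knots], dtype=float)
    ys = np.array([v for _, v in knots], dtype=float)
    return np.interp(ages, xs, ys)


def discount_factor(years_from_start: float, settings: EconSettings) -> float:
    """Present-value factor ``(1 + r)^(-t)`` for a flow ``t`` years after entry."""
    if years_from_start < 0:
        raise ValueError("years_from_start must be non-negative")
    return float((1.0 + settings.discount_rate) ** (-years_from_start))


# ---------------------------------------------------------------------------
# validation

def _check_table(name: str, values: np.ndarray, out: list[str], *, minimum: float) -> None:
    if values.shape != (2, 3, len(AGE_BANDS)):
        out.append(f"{name}: expected shape (2, 3, {len(AGE_BANDS)}), got {values.shape}")
        return
    if np.any(values < minimum):
        out.append(f"{name}: entries must be >= {minimum}")


def validate(params: ModelParams) -> list[str]:
    """Check every type invariant; return a (possibly empty) list of violations."""
    v: list[str] = []
    t = params.test
    if not 0.0 <= t.sensitivity <= 1.0:
        v.append(f"test.sensitivity: must be in [0,1], got {t.sensitivity}")
    if not 0.0 <= t.specificity <= 1.0:
        v.append(f"test.specificity: must be in [0,1], got {t.specificity}")
    if t.unit_cost < 0:
        v.append("test.unit_cost: must be >= 0")

    c = params.cascade
    for fname in ("p_dxa_uptake", "p_treat_init"):
        val = getattr(c, fname)
        if not 0.0 <= val <= 1.0:
            v.append(f"cascade.{fname}: must be in [0,1], got {val}")
    if c.dxa_cost < 0:
        v.append("cascade.dxa_cost: must be >= 0")

    _check_table("incidence", params.incidence.values, v, minimum=0.0)
    if params.incidence.values.shape == (2, 3, len(AGE_BANDS)):
        for sex in Sex:
            for site in (FractureSite.HIP, FractureSite.VERTEBRAL):
                row = params.incidence.values[sex, site]
                if np.any(np.diff(row) < 0):
                    v.append(f"incidence[{sex.name}, {site.name}]: must be non-decreasing with age")
    _check_table("tscore_rr", params.tscore_rr.values, v, minimum=1.0)

    sub = params.subsequent
    if abs(sub.multiplier(1.0, 0) - 1.0) > 1e-12:
        v.append("subsequent: multiplier with no prior fractures must be 1")
    for n_prior in (1, 2, 5):
        ms = [sub.multiplier(t_, n_prior) for t_ in (0, 1, 2, 3, 5, 6, 20)]
        if any(m < 1.0 for m in ms):
            v.append("subsequent: multiplier must be >= 1")
            break
        if any(b > a + 1e-12 for a, b in zip(ms, ms[1:])):
            v.append("subsequent: multiplier must be non-increasing in years since fracture")
            break

    for sex, lt in params.life_tables.items():
        name = f"life_tables[{Sex(sex).name}]"
        if lt.qx.shape[0] != HORIZON_AGE - lt.start_age + 1:
            v.append(f"{name}: must cover ages {lt.start_age}..{HORIZON_AGE}")
            continue
        if np.any((lt.qx < 0) | (lt.qx > 1)):
            v.append(f"{name}: qx must be in [0,1]")
        if abs(lt.qx[-1] - 1.0) > 1e-12:
            v.append(f"{name}: qx at horizon age must be 1")
        if np.any(np.diff(lt.qx[:-1]) < -1e-12):
            v.append(f"{name}: qx must be non-decreasing above age 50")

    pfm = params.post_fracture_mortality
    if not 0.0 <= pfm.attribution <= 1.0:
        v.append(f"post_fracture_mortality.attribution: must be in [0,1], got {pfm.attribution}")
    if pfm.first_year_excess.shape != (2, 2):
        v.append("post_fracture_mortality.first_year_excess: expected shape (2, 2)")
    elif np.any((pfm.first_year_excess < 0) | (pfm.first_year_excess > 1)):
        v.append("post_fracture_mortality.first_year_excess: must be in [0,1]")
    if pfm.longterm_hr0 < 1.0:
        v.append("post_fracture_mortality.longterm_hr0: must be >= 1")

    for name, d in params.drugs.items():
        if np.any((d.rr <= 0) | (d.rr > 1)):
            v.append(f"drugs[{name}].rr: must be in (0,1]")
        if d.annual_cost < 0:
            v.append(f"drugs[{name}].annual_cost: must be >= 0")
        if np.any(np.diff(d.persistence) > 1e-12):
            v.append(f"drugs[{name}].persistence: must be non-increasing")
        if np.any((d.persistence < 0) | (d.persistence > 1)):
            v.append(f"drugs[{name}].persistence: must be in [0,1]")
        for fname in ("physician_visits_per_year", "pharmacy_visits_per_year", "dxa_per_year",
                      "ae_gp_visits_first_6mo", "ae_gp_visits_per_subsequent_6mo",
                      "ae_ppi_cost_per_episode"):
            if getattr(d, fname) < 0:
                v.append(f"drugs[{name}].{fname}: must be >= 0")

    m = params.mix
    if abs(sum(m.shares.values()) - 1.0) > 1e-9:
        v.append(f"mix.shares: must sum to 1, got {sum(m.shares.values()):.6f}")
    if set(m.shares) - set(params.drugs):
        v.append(f"mix.shares: unknown drugs {sorted(set(m.shares) - set(params.drugs))}")
    if m.max_duration_years < 1:
        v.append("mix.max_duration_years: must be >= 1")

    cp = params.costs
    if cp.fracture_first_year.shape != (2, 3):
        v.append("costs.fracture_first_year: expected shape (2, 3)")
    elif np.any(cp.fracture_first_year < 0):
        v.append("costs.fracture_first_year: must be >= 0")
    if not 0.0 <= cp.nursing_home_prob_after_hip <= 1.0:
        v.append("costs.nursing_home_prob_after_hip: must be in [0,1]")
    for fname in ("nursing_home_daily_cost", "physician_visit_cost", "pharmacy_visit_cost",
                  "dxa_cost"):
        if getattr(cp, fname) < 0:
            v.append(f"costs.{fname}: must be >= 0")

    u = params.utilities
    for age, val in u.baseline_knots.items():
        if not 0.0 <= val <= 1.0:
            v.append(f"utilities.baseline[{age}]: must be in [0,1], got {val}")
    if u.post_fracture_multiplier.shape != (3, 2):
        v.append("utilities.post_fracture_multiplier: expected shape (3, 2)")
    elif np.any((u.post_fracture_multiplier <= 0) | (u.post_fracture_multiplier > 1.1)):
        v.append("utilities.post_fracture_multiplier: must be in (0, 1.1]")

    p = params.prevalence
    if p.mode not in ("fixed", "age_specific"):
        v.append(f"prevalence.mode: must be 'fixed' or 'age_specific', got {p.mode!r}")
    for sex, val in p.fixed.items():
        if not 0.0 <= val <= 1.0:
            v.append(f"prevalence.fixed[{Sex(sex).name}]: must be in [0,1]")
    for sex, vals in p.age_specific.items():
        if any(not 0.0 <= x <= 1.0 for x in vals):
            v.append(f"prevalence.age_specific[{Sex(sex).name}]: must be in [0,1]")

    e = params.econ
    if e.discount_rate < 0:
        v.append("econ.discount_rate: must be >= 0")
    if e.horizon_age != HORIZON_AGE:
        v.append(f"econ.horizon_age: model is built for horizon {HORIZON_AGE}")
    if e.cycle_length != 1.0:
        v.append("econ.cycle_length: annual cycles only")

    pop = params.population
    if abs(sum(pop.sex_shares.values()) - 1.0) > 1e-9:
        v.append("population.sex_shares: must sum to 1")
    if any(w < 0 for w in pop.age_band_weights.values()):
        v.append("population.age_band_weights: must be >= 0")
    if sum(pop.age_band_weights.values()) <= 0:
        v.append("population.age_band_weights: must have positive total weight")

    return v
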