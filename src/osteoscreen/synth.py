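"""Synthetic stand-ins for model inputs that are not published as tables.

National life tables, the age/sex population structure, post-fracture excess
mortality and subsequent-fracture risk multipliers enter the model from
external statistical sources that ship no machine-readable values. This
module generates plausible, clearly flagged substitutes so the entire
pipeline builds and tests offline:

* life tables from a Gompertz–Makeham hazard, calibrated so that remaining
  life expectancy at 50 is ~36 y (women) and ~31 y (men);
* a population roster sampled from 5-year age-band weights that skew toward
  50–69, as in an aging society;
* osteoporosis flags drawn from the configured prevalence;
* post-fracture excess mortality and time-since-fracture risk multipliers
  with configurable, order-of-magnitude-plausible defaults.

Every output carries ``source = "synthetic stand-in"`` provenance so run
manifests can distinguish them from tabulated inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    HORIZON_AGE,
    LifeTable,
    PopulationSpec,
    PostFractureMortality,
    PrevalenceSpec,
    Sex,
    SubsequentFractureModel,
    rate_to_prob,
)
from .rng import rng_for

__all__ = [
    "GompertzMakehamParams",
    "PopulationRoster",
    "make_life_table",
    "make_population",
    "assign_osteoporosis",
    "default_post_fracture_mortality",
    "default_subsequent_multipliers",
    "DEFAULT_GM",
]


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Gompertz–Makeham mortality hazard: ``A + B * exp(c * (age - ref))``."""

    makeham: float  # age-independent hazard A (per year)
    gompertz_scale: float  # hazard B at the reference age (per year)
    gompertz_shape: float  # log-hazard slope c (per year)
    reference_age: float = 50.0


# Calibrated so life expectancy at 50 is ~36 y (women) / ~31 y (men),
# in line with recent South Korean period life tables.
DEFAULT_GM: dict[Sex, GompertzMakehamParams] = {
    Sex.FEMALE: GompertzMakehamParams(makeham=3.0e-4, gompertz_scale=1.474e-3,
                                      gompertz_shape=0.105),
    Sex.MALE: GompertzMakehamParams(makeham=6.0e-4, gompertz_scale=3.239e-3,
                                    gompertz_shape=0.095),
}


@dataclass(frozen=True)
class PopulationRoster:
    """Entry cohort: age at entry and sex per simulated person."""

    ages: np.ndarray  # integer years, in [50, HORIZON_AGE)
    sexes: np.ndarray  # Sex codes

    @property
    def n(self) -> int:
        return int(self.ages.shape[0])

    def subset(self, mask: np.ndarray) -> "PopulationRoster":
        return PopulationRoster(ages=self.ages[mask], sexes=self.sexes[mask])


def make_life_table(sex: Sex, gm: GompertzMakehamParams,
                    horizon_age: int = HORIZON_AGE, start_age: int = 50) -> LifeTable:
    """Build a life table from a Gompertz–Makeham hazard.

    qx at each integer age is the one-year probability implied by the hazard;
    qx at the horizon age is forced to 1 (everyone dies by the horizon).
    """
    ages = np.arange(start_age, horizon_age + 1, dtype=float)
    rate = gm.makeham + gm.gompertz_scale * np.exp(gm.gompertz_shape * (ages - gm.reference_age))
    qx = 1.0 - np.exp(-rate)
    qx[-1] = 1.0
    return LifeTable(sex=sex, qx=qx, start_age=start_age, source="synthetic stand-in")


# 5-year band weights, 50-54 .. 100-104, loosely shaped like the 50+ age
# pyramid of an aging East Asian population (mass in 50-69, thin tail 90+).
DEFAULT_AGE_BAND_WEIGHTS: dict[int, float] = {
    50: 0.170, 55: 0.165, 60: 0.160, 65: 0.145, 70: 0.115, 75: 0.090,
    80: 0.080, 85: 0.050, 90: 0.018, 95: 0.006, 100: 0.001,
}

DEFAULT_POPULATION = PopulationSpec(
    sex_shares={Sex.FEMALE: 0.53, Sex.MALE: 0.47},
    age_band_weights=dict(DEFAULT_AGE_BAND_WEIGHTS),
)


def make_population(n: int, pop: PopulationSpec = DEFAULT_POPULATION,
                    seed: int = 0) -> PopulationRoster:
    """Sample ``n`` entrants by sex share and 5-year age-band weight.

    Ages are drawn uniformly within the sampled band. Deterministic given
    (``seed``, ``pop``).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    weights = np.array([pop.age_band_weights[k] for k in sorted(pop.age_band_weights)])
    lowers = np.array(sorted(pop.age_band_weights))
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("age band weights must be non-negative with positive total")
    if n == 0:
        return PopulationRoster(ages=np.empty(0, dtype=np.int64),
                                sexes=np.empty(0, dtype=np.int64))
    rng = rng_for(seed, "population")
    p_female = pop.sex_shares.get(Sex.FEMALE, 0.0)
    sexes = np.where(rng.random(n) < p_female, int(Sex.FEMALE), int(Sex.MALE))
    band = rng.choice(len(weights), size=n, p=weights / weights.sum())
    within = rng.integers(0, 5, size=n)
    ages = np.minimum(lowers[band] + within, HORIZON_AGE - 1)
    return PopulationRoster(ages=ages.astype(np.int64), sexes=sexes.astype(np.int64))


def assign_osteoporosis(roster: PopulationRoster, prev: PrevalenceSpec,
                        seed: int = 0) -> np.ndarray:
    """Bernoulli osteoporosis flag per roster member from the prevalence spec."""
    rng = rng_for(seed, "osteoporosis")
    u = rng.random(roster.n)
    p = np.array([prev.prob(Sex(s), a) for s, a in zip(roster.sexes, roster.ages)])
    return u < p


def default_post_fracture_mortality() -> PostFractureMortality:
    """Stand-in post-fracture excess mortality.

    First-year excess death probabilities (before attribution scaling):
    hip 0.10 (women) / 0.15 (men); vertebral 0.04 / 0.06. Long-term hazard
    ratio declines linearly from 1.8 to 1.0 over 10 years. Only 25% of the
    excess is attributed to the fracture; NHNV fractures carry none.
    """
    fy = np.array([
        [0.10, 0.04],  # women: hip, vertebral
        [0.15, 0.06],  # men: hip, vertebral
    ])
    return PostFractureMortality(first_year_excess=fy, longterm_hr0=1.8,
                                 longterm_decay_years=10.0, attribution=0.25,
                                 source="synthetic stand-in")


def default_subsequent_multipliers() -> SubsequentFractureModel:
    """Stand-in time-since-fracture risk multipliers.

    RR 2.0 within 2 years of the last fracture, 1.5 in years 3-5, 1.2
    beyond, plus +0.2 per prior fracture beyond the first, capped at 4.0.
    """
    return SubsequentFractureModel()
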