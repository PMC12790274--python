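"""Decision tree from AI chest-radiograph flag to treatment initiation.

The screened person's pathway: the AI read flags suspected osteoporosis
(sensitivity/specificity of the deep-learning tool), a fraction of flagged
people attend confirmatory DXA, DXA acts as a perfect reference (so false
positives are never confirmed), and a fraction of confirmed cases start
drug treatment, assigned a drug by the market-share mix.

Both a stochastic per-individual version (used by the microsimulation,
driven by pre-drawn uniforms so arms can share random streams) and the exact
closed-form pathway probabilities (the analytic oracle) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import CascadeParams, ScreeningTest, TreatmentMix

__all__ = ["CascadeResult", "CascadeArrays", "screen_individual", "screen_cohort",
           "expected_cascade", "NO_SCREENING_RESULT"]


@dataclass(frozen=True)
class CascadeResult:
    """One person's pathway through the screening decision tree."""

    flagged: bool
    dxa_done: bool
    confirmed: bool
    treated: bool
    drug: Optional[str]
    upfront_cost: float  # KRW at model entry (AI read + DXA if performed)


#: Pathway of a person in the no-screening arm.
NO_SCREENING_RESULT = CascadeResult(False, False, False, False, None, 0.0)


@dataclass(frozen=True)
class CascadeArrays:
    """Vectorised cascade outcome for a cohort."""

    flagged: np.ndarray
    dxa_done: np.ndarray
    confirmed: np.ndarray
    treated: np.ndarray
    drug: np.ndarray  # drug index into the sorted mix, -1 if untreated
    upfront_cost: np.ndarray


def _drug_order(mix: TreatmentMix) -> list[str]:
    return list(mix.shares)


def screen_cohort(has_osteoporosis: np.ndarray, test: ScreeningTest,
                  cascade: CascadeParams, mix: TreatmentMix,
                  u: np.ndarray) -> CascadeArrays:
    """Run the decision tree for a cohort from pre-drawn uniforms.

    ``u`` has shape (4, n): flag, DXA-attendance, initiation and drug-choice
    uniforms. Keeping the draws explicit lets the two strategy arms share the
    same random streams (common random numbers).
    """
    dis = np.asarray(has_osteoporosis, dtype=bool)
    p_flag = np.where(dis, test.sensitivity, 1.0 - test.specificity)
    flagged = u[0] < p_flag
    dxa_done = flagged & (u[1] < cascade.p_dxa_uptake)
    confirmed = dxa_done & dis  # DXA as perfect reference
    treated = confirmed & (u[2] < cascade.p_treat_init)
    names = _drug_order(mix)
    cum = np.cumsum([mix.shares[n] for n in names])
    drug = np.where(treated, np.searchsorted(cum, u[3], side="right"), -1)
    drug = np.minimum(drug, len(names) - 1)
    upfront = test.unit_cost + np.where(dxa_done, cascade.dxa_cost, 0.0)
    return CascadeArrays(flagged=flagged, dxa_done=dxa_done, confirmed=confirmed,
                         treated=treated, drug=drug.astype(np.int64),
                         upfront_cost=upfront)


def screen_individual(has_osteoporosis: bool, test: ScreeningTest,
                      cascade: CascadeParams, mix: TreatmentMix,
                      rng: np.random.Generator) -> CascadeResult:
    """Sample one person's screening pathway.

    Always consumes exactly four uniforms so that pathways stay aligned
    across paired simulations regardless of branch outcomes.
    """
    u = rng.random(4).reshape(4, 1)
    arr = screen_cohort(np.array([has_osteoporosis]), test, cascade, mix, u)
    names = _drug_order(mix)
    return CascadeResult(
        flagged=bool(arr.flagged[0]), dxa_done=bool(arr.dxa_done[0]),
        confirmed=bool(arr.confirmed[0]), treated=bool(arr.treated[0]),
        drug=names[arr.drug[0]] if arr.treated[0] else None,
        upfront_cost=float(arr.upfront_cost[0]),
    )


def expected_cascade(prevalence: float, test: ScreeningTest,
                     cascade: CascadeParams, mix: TreatmentMix) -> dict[str, float]:
    """Exact pathway probabilities and expected upfront cost per screened person.

    Closed forms for a population with the given osteoporosis prevalence:
    ``P(flag) = prev*sens + (1-prev)*(1-spec)``, DXA attendance and treatment
    initiation multiply on, and DXA (perfect reference) confirms only true
    positives.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0,1]")
    p_tp_flag = prevalence * test.sensitivity
    p_flag = p_tp_flag + (1.0 - prevalence) * (1.0 - test.specificity)
    p_dxa = p_flag * cascade.p_dxa_uptake
    p_confirmed = p_tp_flag * cascade.p_dxa_uptake
    p_treated = p_confirmed * cascade.p_treat_init
    out = {
        "p_flag": p_flag,
        "p_dxa": p_dxa,
        "p_confirmed": p_confirmed,
        "p_treated": p_treated,
        "expected_upfront_cost": test.unit_cost + p_dxa * cascade.dxa_cost,
    }
    for name, share in mix.shares.items():
        out[f"p_treated_{name}"] = p_treated * share
    return out
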