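"""Deterministic expected-value recursion used to cross-check the microsimulation.

Under a *history-independent* restriction of the model — subsequent-fracture
multipliers identically 1, excess mortality off, and persistence tables that
keep everyone on drug until the forced stop — expected discounted costs,
QALYs, life-years and fracture counts can be computed exactly by a forward
cohort recursion over age, because fracture events then influence neither
future fracture risk nor mortality. Utility still depends on fracture
history (first-year vs subsequent-year multipliers keyed to the most severe
site), which the recursion tracks as a small Markov chain over
(most-severe-site-so-far, event-this-cycle).

This module exists for testing only; it is independent of the simulation
loop in :mod:`~osteoscreen.engine`.
"""

from __future__ import annotations

import numpy as np

from .engine import _NO_SITE, _ParamArrays
from .params import HORIZON_AGE, ModelParams, Sex, WaningKind, band_index
from .synth import PopulationRoster

__all__ = ["cohort_expected_value"]


def _require_history_independent(params: ModelParams) -> None:
    sub = params.subsequent
    probe = [sub.multiplier(t, k) for t in (0, 1, 3, 10) for k in (1, 2, 5)]
    if any(abs(m - 1.0) > 1e-12 for m in probe):
        raise ValueError("oracle requires subsequent-fracture multipliers == 1")
    pfm = params.post_fracture_mortality
    excess_off = (pfm.attribution == 0.0
                  or (np.all(pfm.first_year_excess == 0.0) and pfm.longterm_hr0 == 1.0))
    if not excess_off:
        raise ValueError("oracle requires excess mortality disabled")
    for d in params.drugs.values():
        if np.any(d.persistence < 1.0):
            raise ValueError("oracle requires deterministic (all-ones) persistence")


def _expected_path(age0: int, sex: Sex, osteo: bool, params: ModelParams,
                   pa: _ParamArrays, drug_idx: int | None) -> np.ndarray:
    """Expected (disc cost, disc QALY, life-years, fractures) for one profile.

    ``drug_idx`` selects a treated path (on drug from entry until the forced
    stop, then waning) or ``None`` for never treated.
    """
    p = params
    T = HORIZON_AGE - age0
    disc = (1.0 + p.econ.discount_rate) ** (-(np.arange(T) + 0.5))
    first = pa.mult[:, 0]
    subs = pa.mult[:, 1]

    surv = 1.0
    nh = 0.0  # P(in nursing home | alive)
    pi = np.zeros(4)  # most-severe-site-so-far distribution; index 3 = no history
    pi[_NO_SITE] = 1.0
    out = np.zeros(4)

    for t in range(T):
        age = age0 + t
        band = band_index(age)
        q = float(pa.qx[sex, age - 50])

        # per-site event probabilities this cycle
        eff = np.ones(3)
        if drug_idx is not None:
            if t < pa.max_dur:
                eff = pa.rr[drug_idx].copy()
            else:
                ys_mid = (t - pa.max_dur) + 0.5
                kind = pa.waning[drug_idx]
                if kind == int(WaningKind.LINEAR_OVER_TREATMENT_DURATION):
                    frac = max(0.0, 1.0 - ys_mid / pa.max_dur)
                elif kind == int(WaningKind.LINEAR_OVER_ONE_YEAR):
                    frac = max(0.0, 1.0 - ys_mid)
                else:
                    frac = 1.0 if ys_mid < 1.0 else 0.0
                eff = 1.0 - (1.0 - pa.rr[drug_idx]) * frac
        rate = pa.inc[sex, :, band] * (pa.ts[sex, :, band] if osteo else 1.0) * eff
        p_site = -np.expm1(-rate)

        # most-severe-event distribution (sites sampled independently)
        pe = np.zeros(4)
        pe[0] = p_site[0]
        pe[1] = (1 - p_site[0]) * p_site[1]
        pe[2] = (1 - p_site[0]) * (1 - p_site[1]) * p_site[2]
        pe[3] = 1.0 - pe[:3].sum()

        # expected utility multiplier given history distribution
        subs_by_m = np.array([subs[0], subs[1], subs[2], 1.0])
        e_mult = pe[:3] @ first + pe[3] * float(pi @ subs_by_m)

        # costs: fracture events + nursing home + treatment
        nh = nh + (1.0 - nh) * p_site[0] * pa.nh_prob
        c = float(p_site @ pa.frac_cost[sex]) + nh * pa.nh_annual
        if drug_idx is not None and t < pa.max_dur:
            c += pa.year_cost[drug_idx, t]

        credit = 1.0 - 0.5 * q
        u_now = float(pa.u_age[age - 50])
        out[0] += surv * c * disc[t]
        out[1] += surv * u_now * e_mult * credit * disc[t]
        out[2] += surv * credit
        out[3] += surv * p_site.sum()

        # advance the most-severe chain: m' = min(m, e)
        new_pi = np.zeros(4)
        for m in range(4):
            for e in range(4):
                new_pi[min(m, e)] += pi[m] * pe[e]
        pi = new_pi
        surv *= 1.0 - q

    return out


def cohort_expected_value(roster: PopulationRoster, flags: np.ndarray,
                          params: ModelParams, arm: str) -> dict[str, float]:
    """Exact expected per-person outcomes for one arm on simplified settings.

    Raises ``ValueError`` when called with history-dependent settings (any
    subsequent-fracture multiplier above 1, active excess mortality, or
    stochastic persistence).
    """
    _require_history_independent(params)
    if arm not in ("screening", "no_screening"):
        raise ValueError(f"unknown arm {arm!r}")
    pa = _ParamArrays(params)
    shares = np.array([params.mix.shares[n] for n in pa.drug_names])
    sens, spec = params.test.sensitivity, params.test.specificity
    p_dxa, p_init = params.cascade.p_dxa_uptake, params.cascade.p_treat_init

    profiles: dict[tuple[int, int, bool], int] = {}
    for a, s, f in zip(roster.ages, roster.sexes, np.asarray(flags, dtype=bool)):
        key = (int(a), int(s), bool(f))
        profiles[key] = profiles.get(key, 0) + 1

    total = np.zeros(4)
    cache: dict[tuple, np.ndarray] = {}
    for (age0, sex, osteo), count in profiles.items():
        def path(drug_idx):
            key = (age0, sex, osteo, drug_idx)
            if key not in cache:
                cache[key] = _expected_path(age0, Sex(sex), osteo, params, pa, drug_idx)
            return cache[key]

        untreated = path(None)
        if arm == "no_screening":
            person = untreated
        else:
            p_flag = sens if osteo else (1.0 - spec)
            upfront = params.test.unit_cost + p_flag * p_dxa * params.cascade.dxa_cost
            if osteo:
                w_treat = sens * p_dxa * p_init
                treated = sum(shares[d] * path(d) for d in range(len(shares)))
                person = (1.0 - w_treat) * untreated + w_treat * treated
            else:
                person = untreated.copy()
            person = person + np.array([upfront, 0.0, 0.0, 0.0])
        total += count * person

    total /= roster.n
    return {"cost": float(total[0]), "qaly": float(total[1]),
            "life_years": float(total[2]), "fractures": float(total[3])}
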