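"""Individual-level annual-cycle microsimulation of fractures, costs and QALYs.

Each simulated person enters at their roster age, passes (in the screening
arm) through the decision-tree cascade, and is then advanced one year at a
time until death or age 105. Within a cycle, in order:

1. fracture events are sampled independently per site (hip, vertebral, NHNV)
   from age/sex incidence x T-score relative risk x fracture-history
   multiplier x residual treatment effect;
2. death is sampled from background mortality plus attribution-scaled excess
   (additive first-year excess in the cycle of a hip/vertebral fracture, a
   decaying hazard ratio on background mortality thereafter);
3. costs accrue: first-year fracture costs per event, permanent nursing-home
   costs after 10% of hip fractures, and drug/monitoring/adverse-event costs
   while on treatment;
4. utility accrues as baseline utility x the most severe applicable
   post-fracture multiplier (first-year in an event cycle, subsequent-year
   otherwise); death mid-cycle earns half a cycle of utility and life-years;
5. costs and QALYs are discounted at the cycle midpoint; life-years are not
   discounted;
6. age, fracture-history clocks and treatment clocks advance; medication
   discontinuation is evaluated at year boundaries from the persistence
   table, with a forced stop at the maximum treatment duration.

Both arms of a comparison consume identical pre-drawn uniform streams
(common random numbers): treatment moves event thresholds, never the draws,
so the paired incremental estimates have far smaller Monte-Carlo error than
the arm means. A vectorised cohort path (:func:`run_cohort`) and a scalar
per-person path (:func:`simulate_individual`) consume the same streams in
the same order and agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cascade import CascadeArrays, screen_cohort
from .params import (
    AGE_BANDS,
    DrugProfile,
    FractureSite,
    HORIZON_AGE,
    ModelParams,
    Sex,
    TreatmentMix,
    WaningKind,
    band_index,
    baseline_utility_by_age,
    rate_to_prob,
)
from .rng import rng_for
from .synth import PopulationRoster

__all__ = [
    "IndividualState",
    "Accumulators",
    "ArmOutcome",
    "CohortResult",
    "CRNStreams",
    "draw_streams",
    "treatment_rr",
    "update_persistence",
    "annual_fracture_prob",
    "annual_death_prob",
    "simulate_year",
    "simulate_individual",
    "run_cohort",
]

_MAX_CYCLES = HORIZON_AGE - 50  # 55 annual cycles cover every entry age
_NO_SITE = 3  # sentinel for "no fracture history"


# ---------------------------------------------------------------------------
# state containers

@dataclass
class IndividualState:
    """Mutable per-person state between cycles."""

    age: int
    sex: Sex
    osteoporotic: bool
    alive: bool = True
    prior_fractures: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    years_since_last_fracture: float = np.inf
    years_since_last_hv: float = np.inf  # hip/vertebral only (drives excess mortality)
    most_severe_hist: int = _NO_SITE
    events_this_cycle: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    on_treatment: bool = False
    drug: Optional[str] = None
    years_on_treatment: int = 0
    years_since_stop: float = np.inf
    in_nursing_home: bool = False
    cycle: int = 0


@dataclass
class Accumulators:
    """Per-person lifetime totals."""

    disc_cost: float = 0.0
    disc_qaly: float = 0.0
    life_years: float = 0.0
    fracture_count: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))


@dataclass(frozen=True)
class ArmOutcome:
    """Cohort means with Monte-Carlo SEs for one strategy arm.

    Per-person arrays are kept so a paired comparison can compute exact
    per-individual differences.
    """

    n: int
    cohort_id: str
    cost: np.ndarray
    qaly: np.ndarray
    life_years: np.ndarray
    fractures: np.ndarray  # shape (3, n)

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    @property
    def mean_life_years(self) -> float:
        return float(self.life_years.mean())

    @property
    def mean_fractures(self) -> float:
        return float(self.fractures.sum(axis=0).mean())

    def se(self, name: str) -> float:
        arr = {"cost": self.cost, "qaly": self.qaly, "life_years": self.life_years,
               "fractures": self.fractures.sum(axis=0)}[name]
        return float(arr.std(ddof=1) / np.sqrt(self.n)) if self.n > 1 else 0.0


@dataclass(frozen=True)
class CohortResult:
    screening: ArmOutcome
    no_screening: ArmOutcome


@dataclass(frozen=True)
class CRNStreams:
    """Pre-drawn uniforms shared by both arms of a paired simulation."""

    fracture: np.ndarray  # (T, 3, n)
    death: np.ndarray  # (T, n)
    nursing: np.ndarray  # (T, n)
    persistence: np.ndarray  # (T, n)
    cascade: np.ndarray  # (4, n)

    @property
    def n(self) -> int:
        return self.death.shape[1]

    def person(self, i: int) -> "CRNStreams":
        return CRNStreams(
            fracture=self.fracture[:, :, i : i + 1],
            death=self.death[:, i : i + 1],
            nursing=self.nursing[:, i : i + 1],
            persistence=self.persistence[:, i : i + 1],
            cascade=self.cascade[:, i : i + 1],
        )


def draw_streams(n: int, seed: int, n_cycles: int = _MAX_CYCLES,
                 chunk: int = 0) -> CRNStreams:
    """Draw all uniforms for a paired cohort run from labelled child streams.

    ``chunk`` selects an independent stream block; :func:`run_cohort` splits
    very large cohorts into fixed-size blocks so the pre-drawn uniforms stay
    within memory.
    """
    suffix = "" if chunk == 0 else f"-chunk{chunk}"
    nat = rng_for(seed, "natural-history" + suffix)
    return CRNStreams(
        fracture=nat.random((n_cycles, 3, n)),
        death=nat.random((n_cycles, n)),
        nursing=nat.random((n_cycles, n)),
        persistence=nat.random((n_cycles, n)),
        cascade=rng_for(seed, "cascade" + suffix).random((4, n)),
    )


# ---------------------------------------------------------------------------
# scalar operations (the documented per-person API; the vector path mirrors them)

def treatment_rr(state: IndividualState, site: FractureSite, drug: DrugProfile) -> float:
    """Effective relative fracture risk given treatment status and waning.

    On treatment the drug's full RR applies. After discontinuation the
    residual effect declines according to the drug's waning rule — linearly
    over the completed treatment duration, linearly over one year, or as a
    one-year step — and never rebounds above 1.
    """
    if state.drug is None:
        raise ValueError("treatment_rr called for a person with no assigned drug")
    rr = float(drug.rr[site])
    if state.on_treatment:
        return rr
    ys = state.years_since_stop
    if drug.waning == WaningKind.LINEAR_OVER_TREATMENT_DURATION:
        dur = max(state.years_on_treatment, 1e-12)
        frac = max(0.0, 1.0 - ys / dur)
    elif drug.waning == WaningKind.LINEAR_OVER_ONE_YEAR:
        frac = max(0.0, 1.0 - ys)
    else:  # STEP_AT_ONE_YEAR
        frac = 1.0 if ys < 1.0 else 0.0
    return min(1.0, 1.0 - (1.0 - rr) * frac)


def _apply_persistence(state: IndividualState, drug: DrugProfile, mix: TreatmentMix,
                       u: float) -> IndividualState:
    """Year-boundary treatment-clock update (shared by scalar and public API)."""
    if state.on_treatment:
        state.years_on_treatment += 1
        hazard = drug.discontinuation_hazard(state.years_on_treatment)
        if u < hazard or state.years_on_treatment >= mix.max_duration_years:
            state.on_treatment = False
            state.years_since_stop = 0.0
    elif state.drug is not None:
        state.years_since_stop += 1.0
    return state


def update_persistence(state: IndividualState, drug: DrugProfile, mix: TreatmentMix,
                       rng: np.random.Generator) -> IndividualState:
    """Evaluate discontinuation at the current year boundary.

    The conditional stop probability at the end of treatment year ``k`` is
    ``1 - S(k)/S(k-1)`` from the drug's persistence table (``S(0) = 1``),
    with a forced stop at the maximum treatment duration.
    """
    return _apply_persistence(state, drug, mix, float(rng.random()))


def annual_fracture_prob(state: IndividualState, site: FractureSite,
                         params: ModelParams) -> float:
    """One-cycle fracture probability at the given site.

    Baseline incidence x (T-score RR if osteoporotic) x subsequent-fracture
    multiplier x residual treatment effect, converted from a rate.
    """
    rate = params.incidence.rate(state.sex, site, state.age)
    if state.osteoporotic:
        rate *= params.tscore_rr.rr(state.sex, site, state.age)
    rate *= params.subsequent.multiplier(state.years_since_last_fracture,
                                         int(state.prior_fractures.sum()))
    if state.drug is not None:
        rate *= treatment_rr(state, site, params.drugs[state.drug])
    return rate_to_prob(rate, 1.0)


def annual_death_prob(state: IndividualState, params: ModelParams) -> float:
    """One-cycle death probability: background qx plus attributed fracture excess.

    In the cycle of a hip/vertebral fracture the excess is the additive
    first-year excess probability; in later cycles it is background mortality
    scaled by the decaying long-term hazard ratio minus one. Both are scaled
    by the attribution fraction; NHNV fractures contribute nothing.
    """
    pfm = params.post_fracture_mortality
    q = params.life_tables[state.sex].q(state.age)
    excess = 0.0
    if state.events_this_cycle[FractureSite.HIP]:
        excess = float(pfm.first_year_excess[state.sex, 0])
    elif state.events_this_cycle[FractureSite.VERTEBRAL]:
        excess = float(pfm.first_year_excess[state.sex, 1])
    elif np.isfinite(state.years_since_last_hv):
        excess = q * (pfm.longterm_excess_rr(state.sex, state.years_since_last_hv) - 1.0)
    return min(1.0, q + pfm.attribution * excess)


def _drug_year_cost(drug: DrugProfile, year_index: int, params: ModelParams) -> float:
    """Cost of one treated year (drug + monitoring + adverse events)."""
    c = params.costs
    cost = (drug.annual_cost
            + drug.physician_visits_per_year * c.physician_visit_cost
            + drug.pharmacy_visits_per_year * c.pharmacy_visit_cost
            + drug.dxa_per_year * c.dxa_cost)
    episode = c.physician_visit_cost + drug.ae_ppi_cost_per_episode
    if year_index == 0:
        cost += (drug.ae_gp_visits_first_6mo + drug.ae_gp_visits_per_subsequent_6mo) * episode
    else:
        cost += 2.0 * drug.ae_gp_visits_per_subsequent_6mo * episode
    return cost


def simulate_year(state: IndividualState, params: ModelParams,
                  rng) -> tuple[float, float, float]:
    """Advance one annual cycle; return (discounted cost, discounted QALY, life-years).

    ``rng`` must expose ``random()``; exactly six uniforms are consumed per
    cycle (three fracture sites, death, nursing-home admission, persistence)
    so that paired simulations stay aligned whatever happens.
    """
    if not state.alive:
        raise ValueError("simulate_year called on a dead individual")
    u_frac = [float(rng.random()) for _ in range(3)]
    u_death = float(rng.random())
    u_nh = float(rng.random())
    u_persist = float(rng.random())

    # mid-cycle clock for post-discontinuation waning
    mid = state if state.on_treatment or state.drug is None else replace(
        state, years_since_stop=state.years_since_stop + 0.5,
        prior_fractures=state.prior_fractures)

    # (1) fracture events
    ev = np.zeros(3, dtype=bool)
    for s in FractureSite:
        ev[s] = u_frac[s] < annual_fracture_prob(mid, s, params)
    state.events_this_cycle = ev

    # (2) death
    q = annual_death_prob(state, params)
    died = u_death < q

    # (3) costs
    c = params.costs
    cost = float(ev @ c.fracture_first_year[state.sex])
    if ev[FractureSite.HIP] and not state.in_nursing_home:
        if u_nh < c.nursing_home_prob_after_hip:
            state.in_nursing_home = True
    if state.in_nursing_home:
        cost += 365.0 * c.nursing_home_daily_cost
    if state.on_treatment:
        cost += _drug_year_cost(params.drugs[state.drug], state.years_on_treatment, params)

    # (4) utility, with the most severe applicable multiplier
    u_base = _utility_at(state.age, params)
    if ev.any():
        sev = int(np.argmax(ev))  # sites ordered hip > vertebral > nhnv
        mult = float(params.utilities.post_fracture_multiplier[sev, 0])
    elif state.most_severe_hist != _NO_SITE:
        mult = float(params.utilities.post_fracture_multiplier[state.most_severe_hist, 1])
    else:
        mult = 1.0
    credit = 0.5 if died else 1.0

    # (5) mid-cycle discounting
    df = (1.0 + params.econ.discount_rate) ** (-(state.cycle + 0.5))
    disc_cost = cost * df
    disc_qaly = u_base * mult * credit * df
    life_years = credit

    # (6) advance clocks
    if ev.any():
        state.most_severe_hist = min(state.most_severe_hist, sev)
        state.years_since_last_fracture = 0.0
        if ev[FractureSite.HIP] or ev[FractureSite.VERTEBRAL]:
            state.years_since_last_hv = 0.0
    state.prior_fractures = state.prior_fractures + ev.astype(np.int64)
    state.years_since_last_fracture += 1.0
    state.years_since_last_hv += 1.0
    if state.drug is not None:
        _apply_persistence(state, params.drugs[state.drug], params.mix, u_persist)
    state.age += 1
    state.cycle += 1
    state.alive = not died
    return disc_cost, disc_qaly, life_years


def _utility_at(age: int, params: ModelParams) -> float:
    knots = sorted(params.utilities.baseline_knots.items())
    xs = [a for a, _ in knots]
    ys = [v for _, v in knots]
    return float(np.interp(age, xs, ys))


class _Replay:
    """Replays a single person's CRN stream through the ``rng.random()`` protocol."""

    def __init__(self, streams: CRNStreams):
        order = []
        for t in range(streams.death.shape[0]):
            order.extend(streams.fracture[t, :, 0])
            order.extend([streams.death[t, 0], streams.nursing[t, 0],
                          streams.persistence[t, 0]])
        self._vals = iter(order)

    def random(self) -> float:
        return next(self._vals)


def simulate_individual(entry: tuple[int, Sex, bool], params: ModelParams, arm: str,
                        crn_streams: CRNStreams) -> Accumulators:
    """Simulate one person from entry to death or the horizon under one arm.

    ``arm`` is ``"screening"`` or ``"no_screening"``. The same ``crn_streams``
    must be passed for both arms to realise the common-random-numbers pairing;
    upfront cascade costs are charged undiscounted at entry.
    """
    age, sex, osteo = entry
    state = IndividualState(age=int(age), sex=Sex(sex), osteoporotic=bool(osteo))
    acc = Accumulators()
    if arm == "screening":
        res = screen_cohort(np.array([osteo]), params.test, params.cascade,
                            params.mix, crn_streams.cascade)
        acc.disc_cost += float(res.upfront_cost[0])
        if res.treated[0]:
            state.on_treatment = True
            state.drug = list(params.mix.shares)[int(res.drug[0])]
    elif arm != "no_screening":
        raise ValueError(f"unknown arm {arm!r}")
    rng = _Replay(crn_streams)
    while state.alive and state.age < params.econ.horizon_age:
        cost, qaly, ly = simulate_year(state, params, rng)
        acc.disc_cost += cost
        acc.disc_qaly += qaly
        acc.life_years += ly
    acc.fracture_count = state.prior_fractures
    return acc


# ---------------------------------------------------------------------------
# vectorised cohort path

class _ParamArrays:
    """Pre-indexed numpy views of the parameter bundle for the cohort loop."""

    def __init__(self, params: ModelParams):
        p = params
        self.inc = p.incidence.values
        self.ts = p.tscore_rr.values
        ages = np.arange(50, HORIZON_AGE)
        self.band_of_age = np.array([band_index(a) for a in ages])
        self.qx = np.stack([p.life_tables[Sex.FEMALE].qx, p.life_tables[Sex.MALE].qx])
        self.u_age = baseline_utility_by_age(p.utilities)
        self.frac_cost = p.costs.fracture_first_year
        self.mult = p.utilities.post_fracture_multiplier
        self.nh_annual = 365.0 * p.costs.nursing_home_daily_cost
        self.nh_prob = p.costs.nursing_home_prob_after_hip
        self.fy_excess = p.post_fracture_mortality.first_year_excess
        self.attribution = p.post_fracture_mortality.attribution
        self.drug_names = list(p.mix.shares)
        drugs = [p.drugs[name] for name in self.drug_names]
        self.rr = np.stack([d.rr for d in drugs])  # (D, 3)
        self.waning = np.array([int(d.waning) for d in drugs])
        max_dur = p.mix.max_duration_years
        self.max_dur = max_dur
        self.year_cost = np.array([[_drug_year_cost(d, k, p) for k in range(max_dur)]
                                   for d in drugs])
        self.hazard = np.zeros((len(drugs), max_dur + 2))
        for di, d in enumerate(drugs):
            for k in range(1, max_dur + 1):
                self.hazard[di, k] = d.discontinuation_hazard(k)


def _simulate_arm(roster: PopulationRoster, flags: np.ndarray, params: ModelParams,
                  streams: CRNStreams, screening: bool,
                  pa: Optional[_ParamArrays] = None) -> ArmOutcome:
    pa = pa or _ParamArrays(params)
    p = params
    n = roster.n
    T = streams.death.shape[0]
    sex = roster.sexes
    age = roster.ages.copy()
    osteo = np.asarray(flags, dtype=bool)
    alive = np.ones(n, dtype=bool)

    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    fracs = np.zeros((3, n), dtype=np.int64)

    on_tx = np.zeros(n, dtype=bool)
    drug = np.full(n, -1, dtype=np.int64)
    years_on = np.zeros(n, dtype=np.int64)
    ys_stop = np.full(n, np.inf)
    most_severe = np.full(n, _NO_SITE, dtype=np.int64)
    ys_last = np.full(n, np.inf)
    ys_last_hv = np.full(n, np.inf)
    n_prior = np.zeros(n, dtype=np.int64)
    in_nh = np.zeros(n, dtype=bool)

    if screening:
        cas = screen_cohort(osteo, p.test, p.cascade, p.mix, streams.cascade)
        cost += cas.upfront_cost  # t = 0, undiscounted
        on_tx = cas.treated.copy()
        drug = np.where(cas.treated, cas.drug, -1)

    sub = p.subsequent
    hr_decay = p.post_fracture_mortality
    disc = (1.0 + p.econ.discount_rate) ** (-(np.arange(T) + 0.5))

    for t in range(T):
        act = alive & (age < p.econ.horizon_age)
        if not act.any():
            break
        idx_age = age - 50

        # residual treatment effect per site: (3, n)
        eff = np.ones((3, n))
        stopped = (~on_tx) & (drug >= 0)
        for di in range(len(pa.drug_names)):
            m_on = act & on_tx & (drug == di)
            if m_on.any():
                eff[:, m_on] = pa.rr[di][:, None]
            m_off = act & stopped & (drug == di)
            if m_off.any():
                ys_mid = ys_stop[m_off] + 0.5
                if pa.waning[di] == int(WaningKind.LINEAR_OVER_TREATMENT_DURATION):
                    frac = np.clip(1.0 - ys_mid / np.maximum(years_on[m_off], 1e-12), 0.0, 1.0)
                elif pa.waning[di] == int(WaningKind.LINEAR_OVER_ONE_YEAR):
                    frac = np.clip(1.0 - ys_mid, 0.0, 1.0)
                else:
                    frac = (ys_mid < 1.0).astype(float)
                eff[:, m_off] = 1.0 - (1.0 - pa.rr[di][:, None]) * frac[None, :]

        # (1) fracture events
        band = pa.band_of_age[np.clip(idx_age, 0, len(pa.band_of_age) - 1)]
        hist_mult = sub.multiplier_vec(ys_last, n_prior)
        ev = np.zeros((3, n), dtype=bool)
        for s in range(3):
            rate = pa.inc[sex, s, band] * np.where(osteo, pa.ts[sex, s, band], 1.0)
            rate = rate * hist_mult * eff[s]
            prob = -np.expm1(-rate)
            ev[s] = act & (streams.fracture[t, s] < prob)

        # (2) death
        q = pa.qx[sex, np.clip(idx_age, 0, pa.qx.shape[1] - 1)]
        excess = np.zeros(n)
        prior_hv = np.isfinite(ys_last_hv)
        m = prior_hv & ~(ev[0] | ev[1])
        excess[m] = q[m] * (hr_decay.longterm_excess_rr_vec(ys_last_hv[m]) - 1.0)
        excess[ev[1]] = pa.fy_excess[sex[ev[1]], 1]
        excess[ev[0]] = pa.fy_excess[sex[ev[0]], 0]
        q_tot = np.minimum(1.0, q + pa.attribution * excess)
        died = act & (streams.death[t] < q_tot)

        # (3) costs
        c_cycle = np.zeros(n)
        for s in range(3):
            c_cycle[ev[s]] += pa.frac_cost[sex[ev[s]], s]
        new_nh = ev[0] & ~in_nh & (streams.nursing[t] < pa.nh_prob)
        in_nh |= new_nh
        c_cycle[act & in_nh] += pa.nh_annual
        for di in range(len(pa.drug_names)):
            m_on = act & on_tx & (drug == di)
            if m_on.any():
                c_cycle[m_on] += pa.year_cost[di, np.clip(years_on[m_on], 0, pa.max_dur - 1)]

        # (4) utility
        any_ev = ev.any(axis=0)
        sev_now = np.where(ev[0], 0, np.where(ev[1], 1, np.where(ev[2], 2, _NO_SITE)))
        mult = np.ones(n)
        m_hist = ~any_ev & (most_severe != _NO_SITE)
        mult[m_hist] = pa.mult[most_severe[m_hist], 1]
        mult[any_ev] = pa.mult[sev_now[any_ev], 0]
        credit = np.where(died, 0.5, 1.0)

        # (5) discounted accrual
        cost += act * c_cycle * disc[t]
        u_now = pa.u_age[np.clip(idx_age, 0, len(pa.u_age) - 1)]
        qaly += act * u_now * mult * credit * disc[t]
        ly += act * credit
        fracs += ev

        # (6) advance clocks
        most_severe = np.minimum(most_severe, sev_now)
        ys_last = np.where(any_ev, 0.0, ys_last) + 1.0
        ys_last_hv = np.where(ev[0] | ev[1], 0.0, ys_last_hv) + 1.0
        n_prior += ev.sum(axis=0)

        m_on = act & on_tx
        years_on[m_on] += 1
        k = np.clip(years_on, 0, pa.max_dur + 1)
        hz = pa.hazard[np.clip(drug, 0, None), k]
        stop_now = m_on & ((streams.persistence[t] < hz) | (years_on >= pa.max_dur))
        m_stopped_before = act & stopped
        ys_stop[m_stopped_before] += 1.0
        on_tx &= ~stop_now
        ys_stop[stop_now] = 0.0

        age[act] += 1
        alive &= ~died

    cohort_id = _cohort_id(roster, flags)
    return ArmOutcome(n=n, cohort_id=cohort_id, cost=cost, qaly=qaly,
                      life_years=ly, fractures=fracs)


def _cohort_id(roster: PopulationRoster, flags: np.ndarray) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(roster.ages).tobytes())
    h.update(np.ascontiguousarray(roster.sexes).tobytes())
    h.update(np.ascontiguousarray(np.asarray(flags, dtype=bool)).tobytes())
    return h.hexdigest()[:16]


#: cohorts above this size are simulated in blocks to bound stream memory
_CHUNK = 125_000


def run_cohort(roster: PopulationRoster, flags: np.ndarray, params: ModelParams,
               seed: int) -> CohortResult:
    """Simulate the whole roster under both arms with paired random streams.

    Deterministic given (roster, flags, params, seed). With screening effects
    disabled (e.g. zero DXA uptake and zero AI cost) the two arms are
    bit-identical. Cohorts above 125 000 are simulated in fixed-size blocks
    with independent child streams so memory stays bounded.
    """
    if roster.n == 0:
        raise ValueError("roster must be nonempty")
    pa = _ParamArrays(params)
    flags = np.asarray(flags, dtype=bool)
    parts: list[tuple[ArmOutcome, ArmOutcome]] = []
    for j, lo in enumerate(range(0, roster.n, _CHUNK)):
        hi = min(lo + _CHUNK, roster.n)
        sub = PopulationRoster(ages=roster.ages[lo:hi], sexes=roster.sexes[lo:hi])
        streams = draw_streams(hi - lo, seed, chunk=j)
        scr = _simulate_arm(sub, flags[lo:hi], params, streams, screening=True, pa=pa)
        ns = _simulate_arm(sub, flags[lo:hi], params, streams, screening=False, pa=pa)
        parts.append((scr, ns))
    if len(parts) == 1:
        scr, ns = parts[0]
        cid = _cohort_id(roster, flags)
        scr = ArmOutcome(n=roster.n, cohort_id=cid, cost=scr.cost, qaly=scr.qaly,
                         life_years=scr.life_years, fractures=scr.fractures)
        ns = ArmOutcome(n=roster.n, cohort_id=cid, cost=ns.cost, qaly=ns.qaly,
                        life_years=ns.life_years, fractures=ns.fractures)
        return CohortResult(screening=scr, no_screening=ns)
    cid = _cohort_id(roster, flags)

    def cat(arms: list[ArmOutcome]) -> ArmOutcome:
        return ArmOutcome(
            n=roster.n, cohort_id=cid,
            cost=np.concatenate([a.cost for a in arms]),
            qaly=np.concatenate([a.qaly for a in arms]),
            life_years=np.concatenate([a.life_years for a in arms]),
            fractures=np.concatenate([a.fractures for a in arms], axis=1),
        )

    return CohortResult(screening=cat([p[0] for p in parts]),
                        no_screening=cat([p[1] for p in parts]))
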