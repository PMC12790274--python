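"""Deterministic (one-way) and probabilistic sensitivity analysis, plus CEAC.

One-way scenarios edit the parameter bundle through dotted config paths
(with ``*`` wildcards) and re-run the paired cohort with the same roster and
master seed as the base case, so scenario-to-scenario differences reflect
the parameter change rather than Monte-Carlo noise.

The probabilistic sensitivity analysis draws fracture incidence and utility
multipliers from beta distributions, costs from (zero-truncated) normals,
and treatment relative risks from log-normals, moment-matched to the base
values; where published confidence intervals exist (the utility
multipliers) the spread comes from them, elsewhere a configurable 10%
coefficient of variation is used.
"""

from __future__ import annotations

import copy
import fnmatch
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .config import apply_overrides, params_from_dict, params_to_dict
from .engine import run_cohort
from .outcomes import IncrementalResult, incremental
from .params import ModelParams, Sex
from .rng import child_seed_seq, rng_for
from .synth import PopulationRoster, assign_osteoporosis

__all__ = ["ScenarioSpec", "packaged_scenarios", "apply_scenario", "one_way_table",
           "draw_psa_params", "run_psa", "PSASample", "ceac", "psa_child_seeds"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic sensitivity scenario.

    ``edits`` is a sequence of (dotted path glob, op, value) applied to the
    config mapping; ops are ``set`` (assign), ``mul`` (multiply) and
    ``scale_decrement`` (replace x by ``1 - (1-x)*value``, used for utility
    multipliers and drug RRs so bounds are respected). ``sex``/``min_age``
    restrict the simulated roster instead of editing parameters.
    """

    label: str
    group: str
    edits: tuple[tuple[str, str, float], ...] = ()
    sex: Optional[Sex] = None
    min_age: Optional[int] = None


def _flatten(node: Any, prefix: str, out: list[tuple[str, Any]]) -> None:
    if isinstance(node, dict):
        for k, v in node.items():
            _flatten(v, f"{prefix}.{k}" if prefix else str(k), out)
    elif isinstance(node, list):
        for i, v in enumerate(node):
            _flatten(v, f"{prefix}.{i}", out)
    else:
        out.append((prefix, node))


def apply_scenario(params: ModelParams, spec: ScenarioSpec) -> ModelParams:
    """Return a new parameter bundle with the scenario's edits applied."""
    cfg = params_to_dict(params)
    leaves: list[tuple[str, Any]] = []
    _flatten(cfg, "", leaves)
    overrides: dict[str, Any] = {}
    for pattern, op, value in spec.edits:
        matched = [path for path, _ in leaves if fnmatch.fnmatch(path, pattern)]
        if not matched:
            raise ValueError(f"scenario {spec.label!r}: path {pattern!r} matches nothing")
        current = dict(leaves)
        for path in matched:
            old = current[path]
            if op == "set":
                overrides[path] = value
            elif op == "mul":
                overrides[path] = old * value
            elif op == "scale_decrement":
                overrides[path] = 1.0 - (1.0 - old) * value
            else:
                raise ValueError(f"unknown scenario op {op!r}")
    return params_from_dict(apply_overrides(cfg, overrides))


def packaged_scenarios() -> list[ScenarioSpec]:
    """The packaged one-way scenario set for the fixed-prevalence base case."""
    out: list[ScenarioSpec] = []
    for v in (0.40, 0.50, 0.60, 0.70, 0.80):
        label = f"dxa_uptake_{int(v*100)}" + ("_base" if v == 0.60 else "")
        out.append(ScenarioSpec(label, "dxa_uptake",
                                (("cascade.p_dxa_uptake", "set", v),)))
    for v in (0.30, 0.40, 0.50, 0.60, 0.70):
        label = f"treat_init_{int(v*100)}" + ("_base" if v == 0.50 else "")
        out.append(ScenarioSpec(label, "treat_init",
                                (("cascade.p_treat_init", "set", v),)))
    for tag, v in (("low", 0.5), ("high", 1.5)):
        out.append(ScenarioSpec(f"ai_cost_{tag}", "ai_cost",
                                (("screening.ai_cost", "mul", v),)))
    for tag, v in (("low", 0.8), ("high", 1.2)):
        out.append(ScenarioSpec(f"incidence_{tag}", "incidence",
                                (("incidence.*", "mul", v),)))
        out.append(ScenarioSpec(f"fracture_cost_{tag}", "fracture_cost",
                                (("costs.fracture_first_year.*", "mul", v),)))
        # +-20% on the utility decrement (1 - multiplier)
        out.append(ScenarioSpec(
            f"disutility_{'high' if v > 1 else 'low'}", "disutility",
            (("utilities.post_fracture_multiplier.*", "scale_decrement", v),)))
        out.append(ScenarioSpec(f"drug_cost_{tag}", "drug_cost",
                                (("drugs.*.annual_cost", "mul", v),)))
        # +-20% on drug efficacy (the risk reduction 1 - RR)
        out.append(ScenarioSpec(
            f"efficacy_{'high' if v > 1 else 'low'}", "efficacy",
            (("drugs.*.rr.*", "scale_decrement", v),)))
    for tag, v in (("low", 0.5), ("high", 1.5)):
        out.append(ScenarioSpec(
            f"excess_mortality_{tag}", "excess_mortality",
            (("mortality.post_fracture.first_year_excess.*", "mul", v),
             ("mortality.post_fracture.longterm_hr0", "scale_decrement", v))))
    out.append(ScenarioSpec("alendronate_only", "drug_choice",
                            (("mix.shares.alendronate", "set", 1.0),
                             ("mix.shares.denosumab", "set", 0.0))))
    out.append(ScenarioSpec("denosumab_only", "drug_choice",
                            (("mix.shares.alendronate", "set", 0.0),
                             ("mix.shares.denosumab", "set", 1.0))))
    out.append(ScenarioSpec("age_70_plus", "age_subgroup", (), min_age=70))
    for v in (0.075, 0.122, 0.15):
        label = f"male_prevalence_{v*100:g}".replace(".", "p")
        out.append(ScenarioSpec(label + ("_base" if v == 0.075 else ""),
                                "male_prevalence",
                                (("prevalence.fixed.men", "set", v),)))
    return out


def one_way_table(base: ModelParams, scenarios: Sequence[ScenarioSpec],
                  roster: PopulationRoster, seed: int) -> pd.DataFrame:
    """Run each scenario with the base roster and paired seeds; one row per scenario.

    Osteoporosis flags are re-drawn from the scenario's prevalence with the
    same seed, so prevalence scenarios flip the marginal individuals rather
    than resampling everyone.
    """
    rows = []
    specs = [ScenarioSpec("base_case", "base")] + list(scenarios)
    for spec in specs:
        p = apply_scenario(base, spec) if spec.edits else base
        r = roster
        if spec.sex is not None:
            r = r.subset(r.sexes == int(spec.sex))
        if spec.min_age is not None:
            r = r.subset(r.ages >= spec.min_age)
        flags = assign_osteoporosis(r, p.prevalence, seed)
        res = run_cohort(r, flags, p, seed)
        inc = incremental(res.screening, res.no_screening)
        rows.append({"label": spec.label, "group": spec.group,
                     "delta_cost": inc.delta_cost, "delta_qaly": inc.delta_qaly,
                     "delta_ly": inc.delta_ly,
                     "fractures_averted": inc.fractures_averted,
                     "icer": inc.icer if inc.icer is not None else np.nan,
                     "dominance": inc.label, "n": r.n})
    df = pd.DataFrame(rows)
    base_icer = float(df.loc[df.label == "base_case", "icer"].iloc[0])
    spans = df.groupby("group")["icer"].agg(lambda s: np.nanmax(np.abs(s - base_icer)))
    df["icer_range"] = df["group"].map(spans)
    order = df[df.group != "base"].sort_values(["icer_range", "label"],
                                               ascending=[False, True]).index
    return pd.concat([df[df.group == "base"], df.loc[order]], ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _beta_draw(rng: np.random.Generator, mean: float, sd: float, upper: float = 1.0) -> float:
    """Beta draw moment-matched to (mean, sd) on [0, upper]."""
    if sd <= 0 or mean <= 0:
        return mean
    m, s = mean / upper, sd / upper
    s = min(s, 0.99 * np.sqrt(m * (1.0 - m)))  # keep within beta support
    k = m * (1.0 - m) / (s * s) - 1.0
    return upper * float(rng.beta(m * k, (1.0 - m) * k))


def draw_psa_params(base: ModelParams, seed: int,
                    dispersion_scale: float = 1.0, cv: float = 0.10) -> ModelParams:
    """One outer PSA draw of the parameter bundle.

    Beta for incidence and utility multipliers (CI-matched spread where
    intervals are packaged, ``cv`` x mean otherwise), truncated normal for
    costs, log-normal (median = base) for treatment RRs. Scaling
    ``dispersion_scale`` to 0 collapses every distribution to its base
    value. Cascade probabilities stay fixed at base case. Deterministic
    given ``seed``.
    """
    if dispersion_scale == 0.0:
        return base
    rng = rng_for(seed, "psa-params")
    scale = dispersion_scale

    inc = base.incidence.values.copy()
    for i in np.ndindex(inc.shape):
        inc[i] = _beta_draw(rng, inc[i], scale * cv * inc[i])

    u = base.utilities
    mult = u.post_fracture_multiplier.copy()
    for j in range(3):
        for ph in range(2):
            m = mult[j, ph]
            if u.multiplier_ci is not None:
                sd = (u.multiplier_ci[j, ph, 1] - u.multiplier_ci[j, ph, 0]) / 3.92
            else:
                sd = cv * m
            mult[j, ph] = _beta_draw(rng, m, scale * sd, upper=1.1)

    def norm(x: float) -> float:
        return max(0.0, float(rng.normal(x, scale * cv * x))) if x > 0 else x

    fc = base.costs.fracture_first_year.copy()
    for i in np.ndindex(fc.shape):
        fc[i] = norm(fc[i])
    costs = base.costs.__class__(
        fracture_first_year=fc, male_uplift=base.costs.male_uplift,
        nursing_home_prob_after_hip=base.costs.nursing_home_prob_after_hip,
        nursing_home_daily_cost=norm(base.costs.nursing_home_daily_cost),
        physician_visit_cost=norm(base.costs.physician_visit_cost),
        pharmacy_visit_cost=norm(base.costs.pharmacy_visit_cost),
        dxa_cost=norm(base.costs.dxa_cost),
    )

    sigma = scale * np.sqrt(np.log1p(cv * cv))
    drugs = {}
    for name in base.mix.shares:
        d = base.drugs[name]
        rr = np.minimum(1.0, d.rr * np.exp(sigma * rng.standard_normal(3)))
        drugs[name] = d.__class__(**{**d.__dict__, "rr": rr,
                                     "annual_cost": norm(d.annual_cost)})
    for name, d in base.drugs.items():
        drugs.setdefault(name, d)

    return base.with_(
        incidence=base.incidence.__class__(values=inc, bands=base.incidence.bands),
        utilities=u.__class__(baseline_knots=dict(u.baseline_knots),
                              post_fracture_multiplier=mult,
                              multiplier_ci=u.multiplier_ci),
        costs=costs, drugs=drugs,
    )


@dataclass(frozen=True)
class PSASample:
    """One outer PSA draw: perturbed parameters' paired incremental result."""

    index: int
    delta_cost: float
    delta_qaly: float
    delta_ly: float = 0.0
    fractures_averted: float = 0.0


def psa_child_seeds(seed: int, n_outer: int) -> list[tuple[int, int]]:
    """Stable (parameter-draw seed, cohort seed) pairs for each outer draw."""
    state = child_seed_seq(seed, "psa").generate_state(2 * n_outer, dtype=np.uint32)
    mask = (1 << 31) - 1
    return [(int(state[2 * i]) & mask, int(state[2 * i + 1]) & mask)
            for i in range(n_outer)]


def run_psa(roster: PopulationRoster, flags: np.ndarray, base: ModelParams,
            n_outer: int, seed: int, dispersion_scale: float = 1.0,
            cv: float = 0.10) -> list[PSASample]:
    """Outer parameter draws around paired inner cohorts.

    Each outer draw perturbs the parameters, re-runs both arms on the given
    roster with its own cohort seed, and records the incremental result.
    Deterministic given ``seed``.
    """
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    samples = []
    for i, (param_seed, cohort_seed) in enumerate(psa_child_seeds(seed, n_outer)):
        p = draw_psa_params(base, param_seed, dispersion_scale=dispersion_scale, cv=cv)
        res = run_cohort(roster, flags, p, cohort_seed)
        inc = incremental(res.screening, res.no_screening)
        samples.append(PSASample(index=i, delta_cost=inc.delta_cost,
                                 delta_qaly=inc.delta_qaly, delta_ly=inc.delta_ly,
                                 fractures_averted=inc.fractures_averted))
    return samples


def ceac(samples: Sequence[PSASample], wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(NMB >= 0) per WTP grid point."""
    if not samples:
        raise ValueError("ceac requires at least one PSA sample")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    rows = [{"wtp": float(w), "prob_cost_effective": float(np.mean(w * dq - dc >= 0.0))}
            for w in wtp_grid]
    return pd.DataFrame(rows)
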