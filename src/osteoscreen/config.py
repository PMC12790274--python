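"""Packaged default parameters and config-file handling.

The defaults encode the published South Korean inputs: the AI test's
operating point, the care-cascade probabilities, age/sex-stratified fracture
incidence and T-score relative risks, first-year fracture costs, utilities,
drug profiles, prevalence and economic settings. Inputs the sources do not
print (life tables, population structure, post-fracture mortality,
subsequent-fracture multipliers, the PPI unit cost) come from the
:mod:`~osteoscreen.synth` stand-ins and are listed in ``ModelParams.standins``.

A config file is a plain nested YAML/JSON mapping with the same shape as
:data:`DEFAULT_CONFIG`; unknown keys are rejected, unspecified keys fall back
to the packaged defaults, and dotted-path overrides are applied last.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from . import synth
from .params import (
    CascadeParams,
    CostParams,
    DrugProfile,
    EconSettings,
    IncidenceTable,
    ModelParams,
    PopulationSpec,
    PostFractureMortality,
    PrevalenceSpec,
    ScreeningTest,
    Sex,
    SubsequentFractureModel,
    TreatmentMix,
    TscoreRiskTable,
    UtilityParams,
    WaningKind,
    validate,
)

__all__ = ["DEFAULT_CONFIG", "default_params", "load_config", "params_from_dict",
           "params_to_dict", "dump_default_config", "config_hash", "ConfigError",
           "STANDIN_INPUTS", "apply_overrides"]


class ConfigError(ValueError):
    """Raised when a config file fails to parse or validate."""


_SEXKEY = {"women": Sex.FEMALE, "men": Sex.MALE}
_SITES = ("hip", "vertebral", "nhnv")

#: Inputs whose packaged values are synthetic stand-ins, not published tables.
STANDIN_INPUTS: tuple[str, ...] = (
    "life_tables (Gompertz-Makeham stand-in for national life tables)",
    "population age/sex structure (stand-in weights)",
    "post-fracture excess mortality magnitudes (stand-in)",
    "subsequent-fracture risk multipliers (stand-in)",
    "PPI cost per adverse-event episode (stand-in)",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "screening": {
        "sensitivity": 0.8616,
        "specificity": 0.7419,
        "ai_cost": 15_000.0,  # 30% of a DXA
    },
    "cascade": {
        "p_dxa_uptake": 0.60,
        "p_treat_init": 0.50,
        "dxa_cost": 50_000.0,
    },
    # annual incidence rates (events/person-year), bands 50-59/60-69/70-79/80+
    "incidence": {
        "women": {
            "hip": [0.0003, 0.0007, 0.0030, 0.0136],
            "vertebral": [0.0021, 0.0070, 0.0215, 0.0456],
            "nhnv": [0.0053, 0.0092, 0.0123, 0.0165],
        },
        "men": {
            "hip": [0.0001, 0.0003, 0.0013, 0.0061],
            "vertebral": [0.0007, 0.0025, 0.0076, 0.0161],
            "nhnv": [0.0016, 0.0027, 0.0037, 0.0055],
        },
    },
    # relative fracture risk for BMD T-score <= -2.5 vs general population
    "tscore_rr": {
        "women": {
            "hip": [5.659, 3.390, 2.250, 1.570],
            "vertebral": [2.680, 2.176, 1.772, 1.514],
            "nhnv": [2.250, 1.902, 1.610, 1.416],
        },
        "men": {
            "hip": [9.817, 5.887, 4.334, 2.307],
            "vertebral": [3.542, 2.990, 2.702, 2.144],
            "nhnv": [2.815, 2.457, 2.264, 1.879],
        },
    },
    "costs": {
        # first-year direct cost of a fracture, KRW 2025 (male ~= 1.13 x female)
        "fracture_first_year": {
            "women": {"hip": 17_444_178.0, "vertebral": 5_281_372.0, "nhnv": 6_494_541.0},
            "men": {"hip": 19_718_093.0, "vertebral": 5_969_819.0, "nhnv": 7_341_129.0},
        },
        "nursing_home_prob_after_hip": 0.10,
        "nursing_home_daily_cost": 8103.0,
        "physician_visit_cost": 17_942.0,
        "pharmacy_visit_cost": 8748.0,
        "dxa_cost": 50_000.0,
    },
    "utilities": {
        "baseline": {50: 0.940, 55: 0.930, 60: 0.910, 65: 0.880, 70: 0.850,
                     75: 0.790, 80: 0.750, 85: 0.820, 90: 0.900},
        "post_fracture_multiplier": {
            "hip": {"first_year": 0.55, "subsequent": 0.86},
            "vertebral": {"first_year": 0.68, "subsequent": 0.85},
            "nhnv": {"first_year": 0.79, "subsequent": 0.95},
        },
        "post_fracture_multiplier_ci": {
            "hip": {"first_year": [0.53, 0.57], "subsequent": [0.84, 0.89]},
            "vertebral": {"first_year": [0.65, 0.70], "subsequent": [0.82, 0.87]},
            "nhnv": {"first_year": [0.65, 0.93], "subsequent": [0.81, 1.09]},
        },
    },
    "drugs": {
        "alendronate": {
            "rr": {"hip": 0.67, "vertebral": 0.45, "nhnv": 0.81},
            "annual_cost": 244_512.0,
            # still on drug at end of years 1..5 (constant from year 2 on)
            "persistence": [0.732, 0.336, 0.336, 0.336, 0.336],
            "waning": "linear_over_treatment_duration",
            "physician_visits_per_year": 4.0,
            "pharmacy_visits_per_year": 4.0,
            "dxa_per_year": 1.0,
            "ae_gp_visits_first_6mo": 0.041,
            "ae_gp_visits_per_subsequent_6mo": 0.021,
            "ae_ppi_cost_per_episode": 10_000.0,  # stand-in unit cost
        },
        "denosumab": {
            "rr": {"hip": 0.60, "vertebral": 0.32, "nhnv": 0.80},
            "annual_cost": 247_520.0,
            # 0.67 at year 1 declining to 0.35 from year 3 on (year 2 interpolated)
            "persistence": [0.67, 0.51, 0.35, 0.35, 0.35],
            "waning": "linear_over_one_year",
            "physician_visits_per_year": 2.0,
            "pharmacy_visits_per_year": 2.0,
            "dxa_per_year": 0.0,
            "ae_gp_visits_first_6mo": 0.0,
            "ae_gp_visits_per_subsequent_6mo": 0.0,
            "ae_ppi_cost_per_episode": 0.0,
        },
    },
    "mix": {
        "shares": {"alendronate": 0.672, "denosumab": 0.328},
        "max_duration_years": 5,
    },
    "prevalence": {
        "mode": "fixed",
        "fixed": {"women": 0.373, "men": 0.075},
        # bands 50-59 / 60-69 / 70+
        "age_specific": {"women": [0.154, 0.366, 0.685], "men": [0.035, 0.075, 0.18]},
    },
    "subsequent_fracture": {
        "recent_rr": 2.0, "mid_rr": 1.5, "late_rr": 1.2,
        "recent_years": 2, "mid_years": 5,
        "per_extra_fracture": 0.2, "cap": 4.0,
    },
    "mortality": {
        "gompertz_makeham": {
            "women": {"makeham": 3.0e-4, "gompertz_scale": 1.474e-3,
                      "gompertz_shape": 0.105, "reference_age": 50.0},
            "men": {"makeham": 6.0e-4, "gompertz_scale": 3.239e-3,
                    "gompertz_shape": 0.095, "reference_age": 50.0},
        },
        "post_fracture": {
            "first_year_excess": {
                "women": {"hip": 0.10, "vertebral": 0.04},
                "men": {"hip": 0.15, "vertebral": 0.06},
            },
            "longterm_hr0": 1.8,
            "longterm_decay_years": 10.0,
            "attribution": 0.25,
        },
    },
    "econ": {
        "discount_rate": 0.045,
        "horizon_age": 105,
        "cycle_length": 1.0,
        "wtp_thresholds": [30_000_000.0, 50_000_000.0],
    },
    "population": {
        "sex_shares": {"women": 0.53, "men": 0.47},
        "age_band_weights": dict(synth.DEFAULT_AGE_BAND_WEIGHTS),
    },
}


def _table(d: Mapping[str, Mapping[str, list[float]]]) -> np.ndarray:
    out = np.empty((2, 3, 4))
    for skey, sex in _SEXKEY.items():
        for j, site in enumerate(_SITES):
            out[sex, j, :] = d[skey][site]
    return out


def params_from_dict(cfg: Mapping[str, Any]) -> ModelParams:
    """Build a :class:`ModelParams` from a full config mapping (no defaults applied)."""
    scr = cfg["screening"]
    test = ScreeningTest(sensitivity=float(scr["sensitivity"]),
                         specificity=float(scr["specificity"]),
                         unit_cost=float(scr["ai_cost"]))
    cas = cfg["cascade"]
    cascade = CascadeParams(p_dxa_uptake=float(cas["p_dxa_uptake"]),
                            p_treat_init=float(cas["p_treat_init"]),
                            dxa_cost=float(cas["dxa_cost"]))
    incidence = IncidenceTable(values=_table(cfg["incidence"]))
    tscore = TscoreRiskTable(values=_table(cfg["tscore_rr"]))

    cc = cfg["costs"]
    frac_cost = np.empty((2, 3))
    for skey, sex in _SEXKEY.items():
        for j, site in enumerate(_SITES):
            frac_cost[sex, j] = cc["fracture_first_year"][skey][site]
    costs = CostParams(
        fracture_first_year=frac_cost,
        nursing_home_prob_after_hip=float(cc["nursing_home_prob_after_hip"]),
        nursing_home_daily_cost=float(cc["nursing_home_daily_cost"]),
        physician_visit_cost=float(cc["physician_visit_cost"]),
        pharmacy_visit_cost=float(cc["pharmacy_visit_cost"]),
        dxa_cost=float(cc["dxa_cost"]),
    )

    uu = cfg["utilities"]
    mult = np.empty((3, 2))
    for j, site in enumerate(_SITES):
        mult[j, 0] = uu["post_fracture_multiplier"][site]["first_year"]
        mult[j, 1] = uu["post_fracture_multiplier"][site]["subsequent"]
    ci = None
    if uu.get("post_fracture_multiplier_ci"):
        ci = np.empty((3, 2, 2))
        for j, site in enumerate(_SITES):
            ci[j, 0, :] = uu["post_fracture_multiplier_ci"][site]["first_year"]
            ci[j, 1, :] = uu["post_fracture_multiplier_ci"][site]["subsequent"]
    utilities = UtilityParams(
        baseline_knots={int(k): float(v) for k, v in uu["baseline"].items()},
        post_fracture_multiplier=mult,
        multiplier_ci=ci,
    )

    drugs: dict[str, DrugProfile] = {}
    for name, d in cfg["drugs"].items():
        drugs[name] = DrugProfile(
            name=name,
            rr=np.array([d["rr"][s] for s in _SITES], dtype=float),
            annual_cost=float(d["annual_cost"]),
            persistence=np.array(d["persistence"], dtype=float),
            waning=WaningKind[str(d["waning"]).upper()],
            physician_visits_per_year=float(d["physician_visits_per_year"]),
            pharmacy_visits_per_year=float(d["pharmacy_visits_per_year"]),
            dxa_per_year=float(d["dxa_per_year"]),
            ae_gp_visits_first_6mo=float(d["ae_gp_visits_first_6mo"]),
            ae_gp_visits_per_subsequent_6mo=float(d["ae_gp_visits_per_subsequent_6mo"]),
            ae_ppi_cost_per_episode=float(d["ae_ppi_cost_per_episode"]),
        )

    mm = cfg["mix"]
    mix = TreatmentMix(shares={k: float(v) for k, v in mm["shares"].items()},
                       max_duration_years=int(mm["max_duration_years"]))

    pv = cfg["prevalence"]
    prevalence = PrevalenceSpec(
        mode=str(pv["mode"]),
        fixed={sex: float(pv["fixed"][skey]) for skey, sex in _SEXKEY.items()},
        age_specific={sex: tuple(float(x) for x in pv["age_specific"][skey])
                      for skey, sex in _SEXKEY.items()},
    )

    sf = cfg["subsequent_fracture"]
    subsequent = SubsequentFractureModel(
        recent_rr=float(sf["recent_rr"]), mid_rr=float(sf["mid_rr"]),
        late_rr=float(sf["late_rr"]), recent_years=int(sf["recent_years"]),
        mid_years=int(sf["mid_years"]),
        per_extra_fracture=float(sf["per_extra_fracture"]), cap=float(sf["cap"]),
    )

    mo = cfg["mortality"]
    life_tables = {}
    for skey, sex in _SEXKEY.items():
        g = mo["gompertz_makeham"][skey]
        gm = synth.GompertzMakehamParams(
            makeham=float(g["makeham"]), gompertz_scale=float(g["gompertz_scale"]),
            gompertz_shape=float(g["gompertz_shape"]),
            reference_age=float(g["reference_age"]),
        )
        life_tables[sex] = synth.make_life_table(sex, gm)
    pf = mo["post_fracture"]
    fy = np.array([[pf["first_year_excess"]["women"]["hip"],
                    pf["first_year_excess"]["women"]["vertebral"]],
                   [pf["first_year_excess"]["men"]["hip"],
                    pf["first_year_excess"]["men"]["vertebral"]]])
    pfm = PostFractureMortality(first_year_excess=fy,
                                longterm_hr0=float(pf["longterm_hr0"]),
                                longterm_decay_years=float(pf["longterm_decay_years"]),
                                attribution=float(pf["attribution"]))

    ec = cfg["econ"]
    econ = EconSettings(discount_rate=float(ec["discount_rate"]),
                        horizon_age=int(ec["horizon_age"]),
                        cycle_length=float(ec["cycle_length"]),
                        wtp_thresholds=tuple(float(x) for x in ec["wtp_thresholds"]))

    pp = cfg["population"]
    population = PopulationSpec(
        sex_shares={sex: float(pp["sex_shares"][skey]) for skey, sex in _SEXKEY.items()},
        age_band_weights={int(k): float(v) for k, v in pp["age_band_weights"].items()},
    )

    return ModelParams(test=test, cascade=cascade, incidence=incidence,
                       tscore_rr=tscore, subsequent=subsequent,
                       life_tables=life_tables, post_fracture_mortality=pfm,
                       drugs=drugs, mix=mix, costs=costs, utilities=utilities,
                       prevalence=prevalence, econ=econ, population=population,
                       standins=STANDIN_INPUTS)


def params_to_dict(params: ModelParams) -> dict[str, Any]:
    """Inverse of :func:`params_from_dict` (plain types, config-file shape)."""
    inv_sex = {v: k for k, v in _SEXKEY.items()}

    def table(arr: np.ndarray) -> dict:
        return {inv_sex[sex]: {site: [float(x) for x in arr[sex, j]]
                               for j, site in enumerate(_SITES)}
                for sex in Sex}

    u = params.utilities
    ci = {}
    if u.multiplier_ci is not None:
        ci = {"post_fracture_multiplier_ci": {
            site: {"first_year": [float(x) for x in u.multiplier_ci[j, 0]],
                   "subsequent": [float(x) for x in u.multiplier_ci[j, 1]]}
            for j, site in enumerate(_SITES)}}
    gm_cfg = DEFAULT_CONFIG["mortality"]["gompertz_makeham"]
    return {
        "screening": {"sensitivity": params.test.sensitivity,
                      "specificity": params.test.specificity,
                      "ai_cost": params.test.unit_cost},
        "cascade": {"p_dxa_uptake": params.cascade.p_dxa_uptake,
                    "p_treat_init": params.cascade.p_treat_init,
                    "dxa_cost": params.cascade.dxa_cost},
        "incidence": table(params.incidence.values),
        "tscore_rr": table(params.tscore_rr.values),
        "costs": {
            "fracture_first_year": {
                inv_sex[sex]: {site: float(params.costs.fracture_first_year[sex, j])
                               for j, site in enumerate(_SITES)} for sex in Sex},
            "nursing_home_prob_after_hip": params.costs.nursing_home_prob_after_hip,
            "nursing_home_daily_cost": params.costs.nursing_home_daily_cost,
            "physician_visit_cost": params.costs.physician_visit_cost,
            "pharmacy_visit_cost": params.costs.pharmacy_visit_cost,
            "dxa_cost": params.costs.dxa_cost,
        },
        "utilities": {
            "baseline": dict(sorted(u.baseline_knots.items())),
            "post_fracture_multiplier": {
                site: {"first_year": float(u.post_fracture_multiplier[j, 0]),
                       "subsequent": float(u.post_fracture_multiplier[j, 1])}
                for j, site in enumerate(_SITES)},
            **ci,
        },
        "drugs": {
            name: {
                "rr": {site: float(d.rr[j]) for j, site in enumerate(_SITES)},
                "annual_cost": d.annual_cost,
                "persistence": [float(x) for x in d.persistence],
                "waning": d.waning.name.lower(),
                "physician_visits_per_year": d.physician_visits_per_year,
                "pharmacy_visits_per_year": d.pharmacy_visits_per_year,
                "dxa_per_year": d.dxa_per_year,
                "ae_gp_visits_first_6mo": d.ae_gp_visits_first_6mo,
                "ae_gp_visits_per_subsequent_6mo": d.ae_gp_visits_per_subsequent_6mo,
                "ae_ppi_cost_per_episode": d.ae_ppi_cost_per_episode,
            } for name, d in params.drugs.items()},
        "mix": {"shares": dict(params.mix.shares),
                "max_duration_years": params.mix.max_duration_years},
        "prevalence": {
            "mode": params.prevalence.mode,
            "fixed": {inv_sex[s]: float(v) for s, v in params.prevalence.fixed.items()},
            "age_specific": {inv_sex[s]: [float(x) for x in v]
                             for s, v in params.prevalence.age_specific.items()},
        },
        "subsequent_fracture": {
            "recent_rr": params.subsequent.recent_rr, "mid_rr": params.subsequent.mid_rr,
            "late_rr": params.subsequent.late_rr,
            "recent_years": params.subsequent.recent_years,
            "mid_years": params.subsequent.mid_years,
            "per_extra_fracture": params.subsequent.per_extra_fracture,
            "cap": params.subsequent.cap,
        },
        "mortality": {
            "gompertz_makeham": copy.deepcopy(gm_cfg),
            "post_fracture": {
                "first_year_excess": {
                    inv_sex[s]: {"hip": float(params.post_fracture_mortality.first_year_excess[s, 0]),
                                 "vertebral": float(params.post_fracture_mortality.first_year_excess[s, 1])}
                    for s in Sex},
                "longterm_hr0": params.post_fracture_mortality.longterm_hr0,
                "longterm_decay_years": params.post_fracture_mortality.longterm_decay_years,
                "attribution": params.post_fracture_mortality.attribution,
            },
        },
        "econ": {"discount_rate": params.econ.discount_rate,
                 "horizon_age": params.econ.horizon_age,
                 "cycle_length": params.econ.cycle_length,
                 "wtp_thresholds": [float(x) for x in params.econ.wtp_thresholds]},
        "population": {
            "sex_shares": {inv_sex[s]: float(v) for s, v in params.population.sex_shares.items()},
            "age_band_weights": {int(k): float(v)
                                 for k, v in sorted(params.population.age_band_weights.items())},
        },
    }


def _merge(base: dict, user: Mapping, path: str, errors: list[str],
           open_maps: frozenset = frozenset({
               "utilities.baseline", "population.age_band_weights", "drugs",
               "mix.shares",
           })) -> dict:
    """Deep merge ``user`` onto ``base``, rejecting keys absent from the schema.

    Mappings listed in ``open_maps`` accept new keys (e.g. extra utility knots
    or a third drug); everywhere else unknown keys are config errors.
    """
    out = copy.deepcopy(base)
    for key, val in user.items():
        k: Any = key
        # JSON renders integer keys (utility knots, age-band edges) as strings
        if isinstance(k, str) and k.isdigit() and int(k) in out:
            k = int(k)
        if k not in out:
            if path in open_maps:
                out[k] = copy.deepcopy(val)
                continue
            errors.append(f"unknown config key: {path + '.' if path else ''}{key}")
            continue
        sub = path + "." + str(k) if path else str(k)
        if isinstance(out[k], dict) and isinstance(val, Mapping):
            # drug entries merge against the alendronate schema when new
            out[k] = _merge(out[k], val, sub if path != "drugs" else "drugs." + str(k),
                            errors, open_maps)
        else:
            out[k] = copy.deepcopy(val)
    return out


def apply_overrides(cfg: dict, overrides: Mapping[str, Any]) -> dict:
    """Apply dotted-path overrides (e.g. ``cascade.p_dxa_uptake=0.8``) last."""
    def step(node: Any, part: str, dotted: str) -> Any:
        if isinstance(node, list):
            if not part.isdigit() or int(part) >= len(node):
                raise ConfigError(f"override path not found: {dotted}")
            return int(part)
        key: Any = part
        if key not in node and part.isdigit() and int(part) in node:
            key = int(part)
        if key not in node:
            raise ConfigError(f"override path not found: {dotted}")
        return key

    out = copy.deepcopy(cfg)
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        node = out
        for p in parts[:-1]:
            node = node[step(node, p, dotted)]
        node[step(node, parts[-1], dotted)] = value
    return out


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> ModelParams:
    """Load a YAML/JSON config, merge onto packaged defaults, validate.

    An absent or empty file yields the packaged base case. Raises
    :class:`ConfigError` listing offending keys on schema violations.
    """
    user: Mapping[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            user = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse config {path}: {exc}") from exc
        if not isinstance(user, Mapping):
            raise ConfigError(f"config {path} must be a mapping at top level")
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user, "", errors)
    if errors:
        raise ConfigError("; ".join(errors))
    if overrides:
        cfg = apply_overrides(cfg, overrides)
    params = params_from_dict(cfg)
    violations = validate(params)
    if violations:
        raise ConfigError("config fails validation: " + "; ".join(violations))
    return params


def default_params() -> ModelParams:
    """The packaged base case."""
    return params_from_dict(DEFAULT_CONFIG)


def dump_default_config(path: str | Path) -> None:
    """Write the packaged base-case config as YAML for editing."""
    Path(path).write_text(yaml.safe_dump(copy.deepcopy(DEFAULT_CONFIG), sort_keys=False))


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable hash of a config mapping (insensitive to key order)."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
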