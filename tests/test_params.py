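"""Parameter types, packaged defaults, scalar conversions and validation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import osteoscreen as osc
from osteoscreen.config import ConfigError, DEFAULT_CONFIG, load_config, params_to_dict
from osteoscreen.params import (
    AGE_BANDS,
    EconSettings,
    FractureSite,
    Sex,
    band_index,
    baseline_utility,
    discount_factor,
    rate_to_prob,
    validate,
)


def test_packaged_defaults_validate(base_params):
    assert validate(base_params) == []


# every numeric cell of the packaged incidence / relative-risk tables
WOMEN_INCIDENCE = {
    "hip": [0.0003, 0.0007, 0.0030, 0.0136],
    "vertebral": [0.0021, 0.0070, 0.0215, 0.0456],
    "nhnv": [0.0053, 0.0092, 0.0123, 0.0165],
}
MEN_INCIDENCE = {
    "hip": [0.0001, 0.0003, 0.0013, 0.0061],
    "vertebral": [0.0007, 0.0025, 0.0076, 0.0161],
    "nhnv": [0.0016, 0.0027, 0.0037, 0.0055],
}
WOMEN_TSCORE = {
    "hip": [5.659, 3.390, 2.250, 1.570],
    "vertebral": [2.680, 2.176, 1.772, 1.514],
    "nhnv": [2.250, 1.902, 1.610, 1.416],
}
MEN_TSCORE = {
    "hip": [9.817, 5.887, 4.334, 2.307],
    "vertebral": [3.542, 2.990, 2.702, 2.144],
    "nhnv": [2.815, 2.457, 2.264, 1.879],
}


@pytest.mark.parametrize("sex,table,attr", [
    (Sex.FEMALE, WOMEN_INCIDENCE, "incidence"),
    (Sex.MALE, MEN_INCIDENCE, "incidence"),
    (Sex.FEMALE, WOMEN_TSCORE, "tscore_rr"),
    (Sex.MALE, MEN_TSCORE, "tscore_rr"),
])
def test_packaged_tables_match_published_values(base_params, sex, table, attr):
    values = getattr(base_params, attr).values
    for site, expected in zip(FractureSite, table.values()):
        np.testing.assert_allclose(values[sex, site], expected, rtol=0, atol=0)


def test_packaged_scalar_defaults(base_params):
    p = base_params
    assert p.test.sensitivity == 0.8616
    assert p.test.specificity == 0.7419
    assert p.test.unit_cost == 15_000
    assert p.cascade.p_dxa_uptake == 0.60
    assert p.cascade.p_treat_init == 0.50
    assert p.cascade.dxa_cost == 50_000
    assert p.econ.discount_rate == 0.045
    assert p.mix.shares == {"alendronate": 0.672, "denosumab": 0.328}
    assert p.mix.max_duration_years == 5
    np.testing.assert_allclose(p.costs.fracture_first_year,
                               [[17_444_178, 5_281_372, 6_494_541],
                                [19_718_093, 5_969_819, 7_341_129]])
    # male fracture costs sit ~13% above female, per site
    ratio = p.costs.fracture_first_year[Sex.MALE] / p.costs.fracture_first_year[Sex.FEMALE]
    np.testing.assert_allclose(ratio, 1.13, atol=0.005)
    np.testing.assert_allclose(p.drugs["alendronate"].rr, [0.67, 0.45, 0.81])
    np.testing.assert_allclose(p.drugs["denosumab"].rr, [0.60, 0.32, 0.80])
    assert p.drugs["alendronate"].annual_cost == 244_512
    assert p.drugs["denosumab"].annual_cost == 247_520
    np.testing.assert_allclose(p.utilities.post_fracture_multiplier,
                               [[0.55, 0.86], [0.68, 0.85], [0.79, 0.95]])
    assert p.prevalence.fixed == {Sex.FEMALE: 0.373, Sex.MALE: 0.075}
    assert p.prevalence.age_specific[Sex.MALE] == (0.035, 0.075, 0.18)
    assert p.prevalence.age_specific[Sex.FEMALE] == (0.154, 0.366, 0.685)


def test_age_bands_partition_model_range():
    assert AGE_BANDS[0].lower == 50 and AGE_BANDS[-1].upper == 105
    for a, b in zip(AGE_BANDS, AGE_BANDS[1:]):
        assert a.upper == b.lower
    assert band_index(79.9) == 2 and band_index(80) == 3


class TestRateToProb:
    @pytest.mark.parametrize("rate,expected", [
        (0.0, 0.0),
        (0.0136, 0.013508),
        (10.0, 0.9999546),
    ])
    def test_closed_form(self, rate, expected):
        assert rate_to_prob(rate, 1.0) == pytest.approx(expected, abs=1e-6)
        assert rate_to_prob(rate, 1.0) < 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.1, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(r1=st.floats(0, 5), r2=st.floats(0, 5), dt=st.floats(0.1, 5))
    def test_monotone_in_rate(self, r1, r2, dt):
        lo, hi = sorted((r1, r2))
        assert rate_to_prob(lo, dt) <= rate_to_prob(hi, dt)

    @settings(derandomize=True, max_examples=50)
    @given(r=st.floats(0, 3), a=st.floats(0.1, 3), b=st.floats(0.1, 3))
    def test_interval_composition(self, r, a, b):
        # surviving a+b years == surviving a then b years
        combined = rate_to_prob(r, a + b)
        split = 1 - (1 - rate_to_prob(r, a)) * (1 - rate_to_prob(r, b))
        assert combined == pytest.approx(split, rel=1e-9, abs=1e-12)


class TestBaselineUtility:
    @pytest.mark.parametrize("age,expected", [
        (70, 0.850),  # tabulated knot
        (52.5, 0.935),  # interpolated between 0.940 and 0.930
        (100, 0.900),  # plateau beyond the last knot
    ])
    def test_interpolation(self, base_params, age, expected):
        assert baseline_utility(age, base_params.utilities) == pytest.approx(expected)

    def test_below_first_knot_rejected(self, base_params):
        with pytest.raises(ValueError):
            baseline_utility(49, base_params.utilities)


class TestDiscountFactor:
    def test_examples(self, base_params):
        e = base_params.econ
        assert discount_factor(0.0, e) == 1.0
        assert discount_factor(10.0, e) == pytest.approx(0.64393, abs=1e-5)
        assert discount_factor(7.3, EconSettings(discount_rate=0.0)) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(t1=st.floats(0, 50), t2=st.floats(0, 50))
    def test_multiplicative_over_time(self, t1, t2):
        e = EconSettings(discount_rate=0.045)
        assert discount_factor(t1 + t2, e) == pytest.approx(
            discount_factor(t1, e) * discount_factor(t2, e), rel=1e-12)


class TestLoadConfig:
    def test_empty_config_equals_base_case(self, tmp_path, base_params):
        f = tmp_path / "empty.yaml"
        f.write_text("")
        p = load_config(f)
        assert p.test.sensitivity == 0.8616
        assert p.test.specificity == 0.7419
        assert p.econ.discount_rate == 0.045
        assert params_to_dict(p) == params_to_dict(base_params)

    def test_override_changes_only_that_field(self, base_params):
        p = load_config(None, overrides={"cascade.p_dxa_uptake": 0.8})
        assert p.cascade.p_dxa_uptake == 0.8
        d1, d2 = params_to_dict(p), params_to_dict(base_params)
        d1["cascade"]["p_dxa_uptake"] = d2["cascade"]["p_dxa_uptake"]
        assert d1 == d2

    def test_out_of_range_sensitivity_rejected(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text("screening:\n  sensitivity: 1.2\n")
        with pytest.raises(ConfigError, match="sensitivity"):
            load_config(f)

    def test_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text("screening:\n  sensitivty: 0.9\n")
        with pytest.raises(ConfigError, match="unknown config key"):
            load_config(f)

    def test_yaml_syntax_error_reported(self, tmp_path):
        f = tmp_path / "broken.yaml"
        f.write_text("screening: [unclosed\n")
        with pytest.raises(ConfigError, match="parse"):
            load_config(f)


class TestValidate:
    def test_nonincreasing_persistence_flagged(self, base_params):
        d = base_params.drugs["alendronate"]
        bad = d.__class__(**{**d.__dict__,
                             "persistence": np.array([0.5, 0.6, 0.6, 0.6, 0.6])})
        p = base_params.with_(drugs={**base_params.drugs, "alendronate": bad})
        assert any("persistence" in v and "non-increasing" in v for v in validate(p))

    def test_shares_must_sum_to_one(self, base_params):
        mix = base_params.mix.__class__(shares={"alendronate": 0.7, "denosumab": 0.4})
        p = base_params.with_(mix=mix)
        assert any("sum to 1" in v for v in validate(p))

    @pytest.mark.parametrize("mutate,expected_fragment", [
        (lambda p: p.with_(test=dataclasses.replace(p.test, specificity=-0.1)),
         "specificity"),
        (lambda p: p.with_(cascade=dataclasses.replace(p.cascade, p_treat_init=1.5)),
         "p_treat_init"),
        (lambda p: p.with_(econ=dataclasses.replace(p.econ, discount_rate=-0.01)),
         "discount_rate"),
        (lambda p: p.with_(post_fracture_mortality=dataclasses.replace(
            p.post_fracture_mortality, attribution=2.0)), "attribution"),
    ])
    def test_broken_invariants_are_reported(self, base_params, mutate, expected_fragment):
        violations = validate(mutate(base_params))
        assert violations and any(expected_fragment in v for v in violations)
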