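import numpy as np
import pytest

import osteoscreen as osc


@pytest.fixture(scope="session")
def base_params():
    return osc.default_params()


@pytest.fixture(scope="session")
def small_cohort(base_params):
    """A 5 000-person roster with osteoporosis flags (fixed prevalence)."""
    roster = osc.make_population(5_000, base_params.population, seed=11)
    flags = osc.assign_osteoporosis(roster, base_params.prevalence, seed=11)
    return roster, flags


def history_independent(params):
    """Restriction of the model under which the cohort recursion is exact."""
    from osteoscreen.params import SubsequentFractureModel

    pfm = params.post_fracture_mortality
    drugs = {name: d.__class__(**{**d.__dict__, "persistence": np.ones(5)})
             for name, d in params.drugs.items()}
    return params.with_(
        subsequent=SubsequentFractureModel(recent_rr=1.0, mid_rr=1.0, late_rr=1.0,
                                           per_extra_fracture=0.0, cap=1.0),
        post_fracture_mortality=pfm.__class__(
            first_year_excess=np.zeros((2, 2)), longterm_hr0=1.0,
            longterm_decay_years=pfm.longterm_decay_years, attribution=0.0),
        drugs=drugs,
    )
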