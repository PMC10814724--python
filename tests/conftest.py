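import pytest

import kdecho as k


@pytest.fixture(scope="session")
def default_cohort():
    """One default 4-group x 5-day cohort (180 rows), seed 1."""
    return k.generate_cohort(k.default_config(seed=1))


@pytest.fixture(scope="session")
def derived_cohort(default_cohort):
    return k.derive_table(default_cohort)


@pytest.fixture(scope="session")
def population_model():
    """Reference model fitted on a large day-0 normative sample.

    With n = 20,000 the fitted intercept/slope/residual SD are the
    population values of the default configuration to well within the
    tolerances of any analytic check, so scored Z-values behave like
    true-parameter Z-scores.
    """
    cfg = k.default_config(seed=424242)
    baseline = k.derive_table(k.generate_baseline(cfg, n=20000))
    return k.fit_normative(baseline, "coronary_inner_d_mm", mode="regression")
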