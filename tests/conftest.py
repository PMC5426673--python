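import dataclasses

import pytest
from hypothesis import settings

from adipocut.cohort import DEFAULT_CONFIG, generate_cohort
from adipocut.regression import FitResult, compute_aic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions (41 M + 40 F)."""
    return generate_cohort(dataclasses.replace(DEFAULT_CONFIG, seed=20170511))


def make_fit(slope, intercept, n, see, predictor="WHtR", outcome="fat_pct", sex="M", adj_r2=0.75):
    """Assemble a FitResult with internally consistent rss/see/aic."""
    rss = see**2 * (n - 2)
    return FitResult(
        predictor=predictor,
        outcome=outcome,
        sex=sex,
        n=n,
        slope=slope,
        intercept=intercept,
        rss=rss,
        see=see,
        adj_r2=adj_r2,
        aic=compute_aic(n, rss),
    )
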